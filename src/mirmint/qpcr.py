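"""Relative quantification by the comparative-Ct (2**-ddCt) method and
cross-platform concordance.

Each replicate's target Ct is normalized against a reference gene
(dCt = Ct_target - Ct_reference); ddCt is taken against the control
group's mean dCt, so control RQs center on 1.  Group differences are
tested on the replicate dCt values (variance-stabilized scale) with an
equal-variance Student t-test.  Technical replicates of pooled RNA are
the testing unit; with pooled samples no biological-replicate inference
is possible, which is a documented limitation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class QpcrMeasurement:
    """Per-replicate (target, reference) Ct pairs for case and control."""

    target: str
    reference: str
    ct_target_control: np.ndarray
    ct_reference_control: np.ndarray
    ct_target_case: np.ndarray
    ct_reference_case: np.ndarray

    def __post_init__(self) -> None:
        for attr in (
            "ct_target_control",
            "ct_reference_control",
            "ct_target_case",
            "ct_reference_case",
        ):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float))
        if len(self.ct_target_control) != len(self.ct_reference_control):
            raise ValueError("control target/reference replicate counts differ")
        if len(self.ct_target_case) != len(self.ct_reference_case):
            raise ValueError("case target/reference replicate counts differ")
        if len(self.ct_target_control) < 2 or len(self.ct_target_case) < 2:
            raise ValueError("need at least two replicates per group")
        for attr in (
            "ct_target_control",
            "ct_reference_control",
            "ct_target_case",
            "ct_reference_case",
        ):
            if not np.isfinite(getattr(self, attr)).all():
                raise ValueError("Ct values must be finite")


@dataclass
class QpcrResult:
    target: str
    reference: str
    rq_control: np.ndarray
    rq_case: np.ndarray
    mean_control: float
    sem_control: float
    mean_case: float
    sem_case: float
    ddct: float
    p: float


def delta_delta_ct(m: QpcrMeasurement) -> QpcrResult:
    """Comparative-Ct relative quantification.

    dCt = Ct_target - Ct_reference per replicate; ddCt (per replicate)
    is dCt minus the control-group mean dCt; RQ = 2**-ddCt.  Control
    replicates are normalized against the same control mean so their
    mean RQ centers on 1.  The reported p is a two-sided equal-variance
    Student t on the replicate dCt values.
    """
    dct_control = m.ct_target_control - m.ct_reference_control
    dct_case = m.ct_target_case - m.ct_reference_case
    ref = dct_control.mean()
    rq_control = np.power(2.0, -(dct_control - ref))
    rq_case = np.power(2.0, -(dct_case - ref))
    t_res = sps.ttest_ind(dct_case, dct_control, equal_var=True)
    return QpcrResult(
        target=m.target,
        reference=m.reference,
        rq_control=rq_control,
        rq_case=rq_case,
        mean_control=float(rq_control.mean()),
        sem_control=float(sps.sem(rq_control)),
        mean_case=float(rq_case.mean()),
        sem_case=float(sps.sem(rq_case)),
        ddct=float(dct_case.mean() - ref),
        p=float(t_res.pvalue),
    )


@dataclass
class ConcordanceResult:
    r: float
    p: float
    n: int
    sign_agreement: float


def platform_concordance(
    qpcr_log2fc: dict[str, float], array_log2fc: dict[str, float]
) -> ConcordanceResult:
    """Pearson correlation of paired per-gene log2 fold changes.

    Pairs are formed over the shared gene ids; requires at least 3
    pairs and nonzero variance in both vectors.  Also reports the
    fraction of pairs whose fold changes agree in sign.
    """
    ids = sorted(set(qpcr_log2fc) & set(array_log2fc))
    if len(ids) < 3:
        raise ValueError("need at least 3 shared genes")
    x = np.array([qpcr_log2fc[i] for i in ids], dtype=float)
    y = np.array([array_log2fc[i] for i in ids], dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance in one platform's fold changes")
    r, p = sps.pearsonr(x, y)
    sign_agreement = float(np.mean(np.sign(x) == np.sign(y)))
    return ConcordanceResult(r=float(r), p=float(p), n=len(ids), sign_agreement=sign_agreement)
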