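"""Ct-array processing and miRNA differential expression.

The pipeline follows standard practice for two-group TaqMan OpenArray
rodent panels: cycle-threshold (Ct) values above a detection threshold
are censored to a ceiling of 40 cycles (the "Undetermined" encoding),
miRNAs undetermined in too many samples are dropped, the Ct matrix is
quantile normalized, re-censored at a stricter threshold, re-filtered,
and each surviving miRNA is tested with an equal-variance two-sample
Student t-test on the normalized Ct values, with Benjamini-Hochberg
control of the false discovery rate.

Fold change is the relative quantity RQ = 2**(-ddCt) where
ddCt = mean Ct(case) - mean Ct(control).  Lower Ct means more template,
so ddCt < 0 (RQ > 1) is upregulation in the case group.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .multitest import bh_adjust

logger = logging.getLogger(__name__)

#: Ct ceiling encoding "Undetermined" (no amplification within the run).
DEFAULT_CEILING = 40.0


@dataclass
class CtMatrix:
    """miRNA x sample matrix of Ct values with a two-group design.

    Parameters
    ----------
    values
        DataFrame of Ct cycles, features in rows, samples in columns.
        Undetermined reactions carry the distinguished ``ceiling`` value.
    groups
        Sample -> condition label, aligned with ``values.columns``;
        exactly two distinct labels.
    ceiling
        Ct value standing for "Undetermined" (default 40).
    """

    values: pd.DataFrame
    groups: pd.Series
    ceiling: float = DEFAULT_CEILING

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.groups = pd.Series(self.groups)
        if list(self.groups.index) != list(self.values.columns):
            self.groups.index = self.values.columns
        labels = self.group_names
        if len(labels) != 2:
            raise ValueError(f"expected exactly two group labels, got {labels}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("Ct matrix contains non-finite values")
        if (arr <= 0).any() or (arr > self.ceiling).any():
            raise ValueError(f"determined Ct values must lie in (0, {self.ceiling}]")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def group_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def undetermined_mask(self) -> pd.DataFrame:
        """Boolean mask of cells at the ceiling ("Undetermined")."""
        return self.values >= self.ceiling

    def samples_in(self, label: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == label]


@dataclass
class MirnaDeParams:
    """Thresholds of the Ct-array DE pipeline.

    Defaults are the field-standard choices for OpenArray panels: first
    censor pass at Ct>35, second at Ct>30 after normalization, removal
    when Undetermined in >=4 samples, BH-adjusted p <= 0.05 and a
    two-sided fold-change threshold of 2 (RQ > 2 or RQ < 0.5).
    """

    first_pass_threshold: float = 35.0
    second_pass_threshold: float = 30.0
    ceiling: float = DEFAULT_CEILING
    max_undetermined: int = 4
    alpha: float = 0.05
    fc_threshold: float = 2.0
    #: control-group label; None = group of the first sample column
    control: str | None = None

    def __post_init__(self) -> None:
        if not (self.second_pass_threshold < self.first_pass_threshold < self.ceiling):
            raise ValueError("need second_pass < first_pass < ceiling")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.fc_threshold <= 1.0:
            raise ValueError("fc_threshold must exceed 1")


def censor_high_ct(ct: CtMatrix, threshold: float, ceiling: float | None = None) -> CtMatrix:
    """Set every Ct value strictly above ``threshold`` to the ceiling.

    Values equal to the threshold are kept (the rule is "> threshold").
    Idempotent: censored cells sit at the ceiling, which is > threshold,
    and are simply re-censored to the same value.
    """
    if ceiling is None:
        ceiling = ct.ceiling
    if threshold >= ceiling:
        raise ValueError("threshold must be below the ceiling")
    vals = ct.values.where(ct.values <= threshold, other=float(ceiling))
    return CtMatrix(vals, ct.groups.copy(), ceiling=float(ceiling))


def drop_undetermined_features(
    ct: CtMatrix, max_undetermined: int
) -> tuple[CtMatrix, list[str]]:
    """Remove miRNAs undetermined in ``max_undetermined`` or more samples.

    Returns the filtered matrix (row order preserved) and the removed ids.
    """
    counts = ct.undetermined_mask().sum(axis=1)
    keep = counts < max_undetermined
    removed = list(ct.values.index[~keep])
    if not keep.any():
        logger.warning("all %d features removed by the undetermined filter", len(keep))
    out = CtMatrix(ct.values.loc[keep], ct.groups.copy(), ceiling=ct.ceiling)
    return out, removed


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force all sample columns onto one common distribution.

    The reference distribution is the across-column mean of the sorted
    columns; each value is replaced by the reference value at its rank.
    Ties within a column receive the mean of the reference values at
    their tied ranks, so the operation is idempotent and permutation
    columns map to identical multisets.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least two samples")
    arr = matrix.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("matrix contains non-finite values")
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = ref
        # average reference values across tied input values
        s = pd.Series(assigned).groupby(col).transform("mean")
        out[:, j] = s.to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _pooled_t(case: np.ndarray, ctrl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Equal-variance two-sample t per row; NaN p where pooled var is 0."""
    n1, n2 = ctrl.shape[1], case.shape[1]
    m1, m2 = ctrl.mean(axis=1), case.mean(axis=1)
    v1 = ctrl.var(axis=1, ddof=1)
    v2 = case.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m2 - m1) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p[~np.isfinite(t)] = np.nan
    return t, p


@dataclass
class MirnaDeResult:
    """Output of :func:`run_mirna_pipeline`.

    ``table`` columns: mean_ctrl, mean_case, ddct, rq, raw_p, adj_p,
    direction, called.  ``stage_counts`` records the surviving feature
    count after each processing stage.
    """

    table: pd.DataFrame
    stage_counts: dict[str, int]
    removed: dict[str, list[str]] = field(default_factory=dict)

    @property
    def called_up(self) -> list[str]:
        t = self.table
        return list(t.index[t["called"] & (t["direction"] == "up")])

    @property
    def called_down(self) -> list[str]:
        t = self.table
        return list(t.index[t["called"] & (t["direction"] == "down")])


def run_mirna_pipeline(ct: CtMatrix, params: MirnaDeParams | None = None) -> MirnaDeResult:
    """Full Ct-array DE pipeline.

    Stages, in order: censor(>first_pass -> ceiling), drop undetermined
    (>= max_undetermined samples), quantile normalize, censor
    (>second_pass -> ceiling), drop again, per-miRNA equal-variance
    Student t on normalized Ct, BH adjustment, RQ = 2**(-ddCt), call if
    adj_p <= alpha and (RQ > fc or RQ < 1/fc).

    Features with zero pooled variance get NaN p-values and are never
    callable (logged).
    """
    params = params or MirnaDeParams()
    stage_counts = {"input": ct.values.shape[0]}
    removed: dict[str, list[str]] = {}

    m = censor_high_ct(ct, params.first_pass_threshold, params.ceiling)
    m, removed["first_pass"] = drop_undetermined_features(m, params.max_undetermined)
    stage_counts["first_pass"] = m.values.shape[0]

    norm = quantile_normalize(m.values)
    m = CtMatrix(norm, m.groups, ceiling=params.ceiling)
    m = censor_high_ct(m, params.second_pass_threshold, params.ceiling)
    m, removed["second_pass"] = drop_undetermined_features(m, params.max_undetermined)
    stage_counts["second_pass"] = m.values.shape[0]

    control = params.control if params.control is not None else m.groups.iloc[0]
    if control not in m.group_names:
        raise ValueError(f"control label {control!r} not among groups {m.group_names}")
    case = next(g for g in m.group_names if g != control)
    ctrl_cols = m.samples_in(control)
    case_cols = m.samples_in(case)
    if len(ctrl_cols) < 2 or len(case_cols) < 2:
        raise ValueError("each group needs at least two samples")

    a = m.values[ctrl_cols].to_numpy()
    b = m.values[case_cols].to_numpy()
    _, raw_p = _pooled_t(b, a)
    n_undef = int(np.isnan(raw_p).sum())
    if n_undef:
        logger.warning("%d features had zero within-group variance; p undefined", n_undef)
    adj_p = bh_adjust(raw_p)

    mean_ctrl = a.mean(axis=1)
    mean_case = b.mean(axis=1)
    ddct = mean_case - mean_ctrl
    rq = np.power(2.0, -ddct)

    called = (
        np.isfinite(adj_p)
        & (adj_p <= params.alpha)
        & ((rq > params.fc_threshold) | (rq < 1.0 / params.fc_threshold))
    )
    direction = np.where(called, np.where(rq > 1.0, "up", "down"), "none")

    table = pd.DataFrame(
        {
            "mean_ctrl": mean_ctrl,
            "mean_case": mean_case,
            "ddct": ddct,
            "rq": rq,
            "raw_p": raw_p,
            "adj_p": adj_p,
            "direction": direction,
            "called": called,
        },
        index=m.values.index,
    )
    table.index.name = "id"
    stage_counts["called"] = int(called.sum())
    return MirnaDeResult(table=table, stage_counts=stage_counts, removed=removed)
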