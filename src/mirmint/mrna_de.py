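"""Microarray filtering and empirical-Bayes moderated-t differential expression.

The stage mirrors the classic two-colour/one-colour array workflow for a
two-group design: detection-flag filtering (keep probes present or
marginal in at least one sample), a per-condition coefficient-of-variation
filter on linear-scale intensities, quantile normalization, and a
moderated t-test in which each gene's variance is shrunk toward an
empirical-Bayes prior estimated from all genes (Smyth 2004 closed-form
moment estimators), gaining d0 prior degrees of freedom.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .mirna_de import quantile_normalize
from .multitest import bh_adjust

logger = logging.getLogger(__name__)

PRESENT, MARGINAL, ABSENT = "P", "M", "A"
FLAG_TOKENS = {PRESENT, MARGINAL, ABSENT}


@dataclass
class ExpressionMatrix:
    """Gene x sample log2-intensity matrix with detection flags.

    ``flags`` has the same shape as ``values`` with tokens P (present),
    M (marginal), A (absent).  ``groups`` maps samples to one of two
    condition labels.
    """

    values: pd.DataFrame
    flags: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.flags.shape != self.values.shape:
            raise ValueError("flags must have the same shape as values")
        if not self.flags.index.equals(self.values.index) or not self.flags.columns.equals(
            self.values.columns
        ):
            raise ValueError("flags must share the labels of values")
        bad = set(np.unique(self.flags.to_numpy())) - FLAG_TOKENS
        if bad:
            raise ValueError(f"unknown flag tokens {sorted(bad)}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        self.groups = pd.Series(self.groups)
        if list(self.groups.index) != list(self.values.columns):
            self.groups.index = self.values.columns
        if len(self.group_names) != 2:
            raise ValueError("expected exactly two group labels")

    @property
    def group_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def samples_in(self, label: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == label]

    def subset(self, keep) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[keep], self.flags.loc[keep], self.groups.copy())


@dataclass
class MrnaDeParams:
    alpha: float = 0.05
    fc_threshold: float = 1.5
    cv_max: float = 0.50
    control: str | None = None
    #: force the prior degrees of freedom (0 = ordinary t, inf = full
    #: shrinkage); None = estimate from the data.
    d0_override: float | None = None

    def __post_init__(self) -> None:
        if self.cv_max <= 0:
            raise ValueError("cv_max must be positive")
        if self.fc_threshold <= 1.0:
            raise ValueError("fc_threshold must exceed 1")


@dataclass
class ModeratedTState:
    """Empirical-Bayes variance model fitted across genes.

    s2 is the per-gene pooled sample variance with d residual degrees of
    freedom; (d0, s0sq) are the prior df and prior variance; s2_post is
    the posterior (shrunken) variance (d0*s0sq + d*s2)/(d0 + d).
    """

    s2: pd.Series
    d: int
    d0: float
    s0sq: float
    s2_post: pd.Series
    t: pd.Series
    df_total: float


def flag_filter(expr: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """Keep probes flagged present or marginal in at least one sample."""
    keep = expr.flags.isin([PRESENT, MARGINAL]).any(axis=1)
    removed = list(expr.values.index[~keep])
    return expr.subset(keep), removed


def cv_filter(
    expr: ExpressionMatrix, cv_max: float = 0.50
) -> tuple[ExpressionMatrix, list[str]]:
    """Keep genes whose linear-scale CV is below ``cv_max`` in both conditions.

    CV = sd/mean of the linear (2**log2) intensities per condition; the
    comparison is strict (<).  Genes with a nonpositive linear mean are
    removed (CV undefined).
    """
    linear = np.power(2.0, expr.values)
    keep = pd.Series(True, index=expr.values.index)
    for label in expr.group_names:
        cols = expr.samples_in(label)
        if len(cols) < 2:
            raise ValueError(f"group {label!r} needs at least two samples")
        sub = linear[cols]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        ok = mean > 0
        if not ok.all():
            logger.warning("%d genes with nonpositive mean removed", int((~ok).sum()))
        cv = sd.where(ok) / mean.where(ok)
        keep &= ok & (cv < cv_max)
    removed = list(expr.values.index[~keep])
    return expr.subset(keep), removed


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton, monotone decreasing)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Moment-match the scaled-F model of gene variances (Smyth 2004).

    With z_g = log(s2_g), e_g = z_g - digamma(d/2) + log(d/2) has mean
    log(s0sq) + digamma(d0/2) - log(d0/2) and excess variance
    trigamma(d0/2) over trigamma(d/2); matching the sample mean and
    variance of e_g yields closed-form (d0, s0sq).  When the excess
    variance is nonpositive d0 = inf (all genes share one variance).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 >= 0)
    if ok.sum() < 3:
        raise ValueError("too few valid variances to fit a prior")
    x = s2[ok]
    med = np.median(x)
    if med == 0:
        raise ValueError("more than half of the variances are exactly zero")
    x = np.maximum(x, 1e-5 * med)  # guard the log against exact zeros
    z = np.log(x)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - float(special.polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess dispersion: one common variance across genes
        d0 = np.inf
        s0sq = float(x.mean())
    return d0, s0sq


def moderated_t_test(
    expr: ExpressionMatrix, params: MrnaDeParams | None = None
) -> tuple[pd.DataFrame, ModeratedTState]:
    """Per-gene moderated t-test on a filtered, normalized matrix.

    Returns a DE table (columns mean_ctrl, mean_case, log2fc, t, raw_p,
    adj_p, direction, called) and the fitted variance model.  Calling
    requires adj_p < alpha and a linear-scale fold change >= fc_threshold.
    """
    params = params or MrnaDeParams()
    control = params.control if params.control is not None else expr.groups.iloc[0]
    if control not in expr.group_names:
        raise ValueError(f"control label {control!r} not among groups")
    case = next(g for g in expr.group_names if g != control)
    a = expr.values[expr.samples_in(control)].to_numpy()
    b = expr.values[expr.samples_in(case)].to_numpy()
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two samples")

    d = n1 + n2 - 2
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d
    log2fc = b.mean(axis=1) - a.mean(axis=1)

    if params.d0_override is not None:
        d0 = float(params.d0_override)
        if np.isinf(d0) or d0 > 0:
            try:
                _, s0sq = estimate_variance_prior(s2, d)
            except ValueError:
                s0sq = float(np.nanmean(s2))
        else:
            s0sq = float(np.nanmean(s2))
    else:
        try:
            d0, s0sq = estimate_variance_prior(s2, d)
        except ValueError as exc:
            logger.warning("prior estimation failed (%s); falling back to d0=0", exc)
            d0, s0sq = 0.0, float(np.nanmean(s2))

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
    else:
        s2_post = (d0 * s0sq + d * s2) / (d0 + d)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / se
    df_total = d0 + d
    raw_p = 2.0 * sps.t.sf(np.abs(t), df_total)
    raw_p[~np.isfinite(t)] = np.nan
    adj_p = bh_adjust(raw_p)

    linear_fc = np.power(2.0, np.abs(log2fc))
    called = np.isfinite(adj_p) & (adj_p < params.alpha) & (linear_fc >= params.fc_threshold)
    direction = np.where(called, np.where(log2fc > 0, "up", "down"), "none")

    idx = expr.values.index
    table = pd.DataFrame(
        {
            "mean_ctrl": a.mean(axis=1),
            "mean_case": b.mean(axis=1),
            "log2fc": log2fc,
            "t": t,
            "raw_p": raw_p,
            "adj_p": adj_p,
            "direction": direction,
            "called": called,
        },
        index=idx,
    )
    table.index.name = "id"
    state = ModeratedTState(
        s2=pd.Series(s2, index=idx),
        d=d,
        d0=d0,
        s0sq=s0sq,
        s2_post=pd.Series(s2_post, index=idx),
        t=pd.Series(t, index=idx),
        df_total=df_total,
    )
    return table, state


def call_degs(de: pd.DataFrame, params: MrnaDeParams | None = None) -> tuple[list[str], list[str]]:
    """Split called genes into up- and downregulated id lists."""
    if de.empty:
        return [], []
    called = de["called"].astype(bool)
    up = list(de.index[called & (de["log2fc"] > 0)])
    down = list(de.index[called & (de["log2fc"] < 0)])
    return up, down


def build_background(expr: ExpressionMatrix, percentile: float = 10.0) -> list[str]:
    """Expressed-gene background: mean normalized expression at or above
    the given percentile of the per-gene mean distribution.

    Ties at the cutoff are retained.
    """
    if not 0.0 <= percentile < 100.0:
        raise ValueError("percentile must lie in [0, 100)")
    means = expr.values.mean(axis=1)
    cut = np.percentile(means.to_numpy(), percentile)
    return list(means.index[means >= cut])


@dataclass
class MrnaDeResult:
    table: pd.DataFrame
    state: ModeratedTState
    stage_counts: dict[str, int]
    removed: dict[str, list[str]] = field(default_factory=dict)
    up: list[str] = field(default_factory=list)
    down: list[str] = field(default_factory=list)
    background: list[str] = field(default_factory=list)


def run_mrna_pipeline(
    expr: ExpressionMatrix,
    params: MrnaDeParams | None = None,
    background_percentile: float = 10.0,
) -> MrnaDeResult:
    """flag filter -> CV filter -> quantile normalize -> moderated t.

    Also derives the expressed-gene background (from the normalized
    matrix after flag filtering, before the CV filter, so weakly varying
    genes still count as expressed).
    """
    params = params or MrnaDeParams()
    stage_counts = {"input": expr.values.shape[0]}
    removed: dict[str, list[str]] = {}

    expr_f, removed["flags"] = flag_filter(expr)
    stage_counts["flag_filter"] = expr_f.values.shape[0]
    expr_cv, removed["cv"] = cv_filter(expr_f, params.cv_max)
    stage_counts["cv_filter"] = expr_cv.values.shape[0]

    norm_all = quantile_normalize(expr_f.values)
    background = build_background(
        ExpressionMatrix(norm_all, expr_f.flags, expr_f.groups), background_percentile
    )

    norm = quantile_normalize(expr_cv.values)
    expr_n = ExpressionMatrix(norm, expr_cv.flags, expr_cv.groups)
    table, state = moderated_t_test(expr_n, params)
    up, down = call_degs(table, params)
    stage_counts["called"] = len(up) + len(down)
    return MrnaDeResult(
        table=table,
        state=state,
        stage_counts=stage_counts,
        removed=removed,
        up=up,
        down=down,
        background=background,
    )
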