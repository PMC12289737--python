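"""Hypergeometric over-representation with a custom expressed-gene background.

Given a query gene list (e.g. upregulated DEGs or a miRNA target
union), a named gene-set collection, and a background of expressed
genes, each set is scored with the upper-tail hypergeometric
probability of observing at least the realized overlap, together with
the odds ratio of the 2x2 overlap table; p-values are BH-adjusted
within the collection.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .multitest import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional source label per set."""

    sets: dict[str, set[str]]
    sources: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, s in self.sets.items():
            if not s:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class EnrichmentResult:
    """2x2 overlap of a query with one gene set inside a background.

    k = overlap, K = set size in background, n = query size in
    background, N = background size; p is the hypergeometric upper tail
    P(X >= k); the odds ratio uses a Haldane-Anscombe 0.5 correction
    when any table cell is zero.
    """

    name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    odds_ratio: float
    adj_p: float = float("nan")
    significant: bool = False
    overlap_genes: tuple[str, ...] = ()


def hypergeom_overrep(
    query: set[str], gene_set: set[str], background: set[str], name: str = "set"
) -> EnrichmentResult:
    """Upper-tail hypergeometric test of query/set overlap in a background.

    Both the query and the gene set are intersected with the background
    first.  An empty query (after intersection) returns k=0, p=1.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background is empty")
    q = set(query) & bg
    s = set(gene_set) & bg
    N, K, n = len(bg), len(s), len(q)
    overlap = sorted(q & s)
    k = len(overlap)
    if n == 0 or K == 0:
        p = 1.0
    else:
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        p = min(p, 1.0)
    a, b, c, d = k, n - k, K - k, N - K - n + k
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    odds_ratio = (a * d) / (b * c)
    return EnrichmentResult(
        name=name, k=k, K=K, n=n, N=N, p=p, odds_ratio=float(odds_ratio),
        overlap_genes=tuple(overlap),
    )


def enrich_collection(
    query: set[str],
    collection: GeneSetCollection,
    background: set[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every set of the collection; BH across the collection.

    Sets empty after background intersection are skipped with a warning.
    Results are sorted by p (ties by name for determinism).
    """
    bg = set(background)
    results: list[EnrichmentResult] = []
    for name, s in collection:
        if not (set(s) & bg):
            logger.warning("gene set %r empty after background intersection; skipped", name)
            continue
        results.append(hypergeom_overrep(query, s, bg, name=name))
    if not results:
        return []
    adj = bh_adjust([r.p for r in results])
    for r, ap in zip(results, adj):
        r.adj_p = float(ap)
        r.significant = bool(ap < alpha)
    results.sort(key=lambda r: (r.p, r.name))
    return results


def demirna_target_union(demirnas: set[str], target_map: dict[str, set[str]]) -> set[str]:
    """Union of predicted target sets over a list of miRNAs.

    miRNAs absent from the map are skipped with a warning.
    """
    union: set[str] = set()
    for m in sorted(demirnas):
        if m not in target_map:
            logger.warning("miRNA %r missing from the target map; skipped", m)
            continue
        union |= set(target_map[m])
    return union
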