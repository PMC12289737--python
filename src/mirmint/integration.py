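"""miRNA-mRNA integration: inverse-overlap tests, knowledge-graph relation
discovery, direction cross-tabulation and chi-square.

miRNAs repress their targets, so an upregulated miRNA is expected to
surface among the targets of downregulated genes and vice versa.  The
module (a) intersects DEmiRNA target unions with oppositely regulated
DEGs and scores the overlaps hypergeometrically, (b) finds miRNA->gene
relations in a typed directed regulatory graph either as direct edges
("shortest path") or allowing one intervening regulator node
("shortest path plus one"), and (c) cross-tabulates the direction pairs
of the unique relations and tests independence with a 2x2 chi-square
(Yates continuity correction on by default).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
from scipy import stats as sps

from .enrichment import EnrichmentResult, demirna_target_union, hypergeom_overrep

logger = logging.getLogger(__name__)

TargetMap = dict[str, set[str]]

SHORTEST = "shortest"
SHORTEST_PLUS_ONE = "shortest_plus_one"


@dataclass(frozen=True)
class RelationRecord:
    """One unique miRNA->gene regulatory relation.

    path_length 1 is a direct edge; path_length 2 goes through exactly
    one intermediate node (the lexicographically smallest when several
    connect the pair).
    """

    mirna: str
    mirna_direction: str
    gene: str
    gene_direction: str
    path_length: int
    intermediate: str | None = None

    def __post_init__(self) -> None:
        if (self.path_length == 2) != (self.intermediate is not None):
            raise ValueError("intermediate present iff path_length == 2")


@dataclass
class ContingencyTable2x2:
    """Observed direction pairs; rows miRNA up/down, cols gene up/down."""

    observed: np.ndarray  # shape (2, 2)
    row_labels: tuple[str, str] = ("mirna_up", "mirna_down")
    col_labels: tuple[str, str] = ("gene_up", "gene_down")

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        if self.observed.shape != (2, 2):
            raise ValueError("need a 2x2 table")

    @property
    def total(self) -> float:
        return float(self.observed.sum())

    def percentages(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("empty table")
        return 100.0 * self.observed / self.total


@dataclass
class ChiSquareResult:
    statistic: float
    p: float
    df: int
    expected: np.ndarray
    continuity_correction: bool


def inverse_overlap(
    degs_up: set[str],
    degs_down: set[str],
    demirnas_up: set[str],
    demirnas_down: set[str],
    target_map: TargetMap,
    background: set[str],
) -> dict[str, EnrichmentResult]:
    """Inverse-correlation intersection of DEmiRNA targets with DEGs.

    Tests (a) targets of upregulated miRNAs against downregulated DEGs
    and (b) targets of downregulated miRNAs against upregulated DEGs,
    each hypergeometrically against the expressed-gene background.
    Overlap gene lists ride on each result.
    """
    if degs_up & degs_down or demirnas_up & demirnas_down:
        raise ValueError("direction sets must be disjoint")
    t_up = demirna_target_union(demirnas_up, target_map)
    t_down = demirna_target_union(demirnas_down, target_map)
    return {
        "mirna_up_targets_vs_degs_down": hypergeom_overrep(
            t_up, degs_down, background, name="mirna_up_targets_vs_degs_down"
        ),
        "mirna_down_targets_vs_degs_up": hypergeom_overrep(
            t_down, degs_up, background, name="mirna_down_targets_vs_degs_up"
        ),
    }


def find_relations(
    graph: nx.DiGraph,
    demirnas: Mapping[str, str],
    degs: Mapping[str, str],
    mode: str = SHORTEST,
) -> list[RelationRecord]:
    """Unique miRNA->gene relations over directed edges.

    ``demirnas`` and ``degs`` map node ids to direction labels
    ("up"/"down").  mode="shortest" accepts only direct edges;
    mode="shortest_plus_one" accepts each pair's shortest path when its
    length is at most 2 (one intermediate; the lexicographically
    smallest is reported).  Output is sorted by (miRNA id, gene id) and
    independent of graph insertion order.  Query ids absent from the
    graph are skipped with a warning.
    """
    if mode not in (SHORTEST, SHORTEST_PLUS_ONE):
        raise ValueError(f"unknown mode {mode!r}")
    records: list[RelationRecord] = []
    for m in sorted(demirnas):
        if m not in graph:
            logger.warning("miRNA %r not in graph; skipped", m)
            continue
        succ = set(graph.successors(m))
        for g in sorted(degs):
            if g == m:
                continue
            if g not in graph:
                logger.warning("gene %r not in graph; skipped", g)
                continue
            if g in succ:
                records.append(
                    RelationRecord(m, demirnas[m], g, degs[g], path_length=1)
                )
            elif mode == SHORTEST_PLUS_ONE:
                inter = sorted(succ & set(graph.predecessors(g)) - {m, g})
                if inter:
                    records.append(
                        RelationRecord(
                            m, demirnas[m], g, degs[g], path_length=2, intermediate=inter[0]
                        )
                    )
    return records


def direction_table(relations: list[RelationRecord]) -> ContingencyTable2x2:
    """Cross-tabulate unique relations by (miRNA direction, gene direction)."""
    if not relations:
        raise ValueError("no relations to tabulate")
    obs = np.zeros((2, 2))
    rows = {"up": 0, "down": 1}
    cols = {"up": 0, "down": 1}
    seen: set[tuple[str, str]] = set()
    for r in relations:
        key = (r.mirna, r.gene)
        if key in seen:
            continue
        seen.add(key)
        obs[rows[r.mirna_direction], cols[r.gene_direction]] += 1
    return ContingencyTable2x2(obs)


def chi_square_2x2(
    table: ContingencyTable2x2, continuity_correction: bool = True
) -> ChiSquareResult:
    """Pearson chi-square of independence on a 2x2 table, df = 1.

    With the Yates correction, X2 = sum(max(|O-E| - 0.5, 0)^2 / E).
    Warns when any expected count is below 5.
    """
    obs = table.observed
    total = obs.sum()
    if total <= 0:
        raise ValueError("empty table")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero row or column margin")
    expected = np.outer(rows, cols) / total
    if (expected < 5).any():
        logger.warning("expected count below 5; chi-square approximation is weak")
    c = 0.5 if continuity_correction else 0.0
    dev = np.maximum(np.abs(obs - expected) - c, 0.0)
    stat = float((dev**2 / expected).sum())
    p = float(sps.chi2.sf(stat, df=1))
    return ChiSquareResult(
        statistic=stat, p=p, df=1, expected=expected,
        continuity_correction=continuity_correction,
    )


def relation_degree(relations: list[RelationRecord]) -> dict[str, int]:
    """Per-miRNA count of unique relations (hub score)."""
    counts: dict[str, int] = {}
    seen: set[tuple[str, str]] = set()
    for r in relations:
        key = (r.mirna, r.gene)
        if key in seen:
            continue
        seen.add(key)
        counts[r.mirna] = counts.get(r.mirna, 0) + 1
    return counts
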