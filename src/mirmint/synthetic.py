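"""Synthetic two-group expression study generator with known ground truth.

Emulates a 3-vs-3 mouse-strain comparison profiled on two platforms:

* a Ct array (qPCR panel) — per-miRNA baseline Ct drawn uniformly,
  Gaussian replicate noise, planted two-sided dCt shifts in the case
  group, and a deterministic detection limit above which the reaction
  is "Undetermined" (encoded at the Ct ceiling of 40);
* a microarray — Gaussian log2 intensities (log-normal on the linear
  scale) around per-gene baselines, planted two-sided log2 fold
  changes, and present/absent detection flags assigned to the dimmest
  fraction of genes;
* a miRNA->target map with background density plus deliberate targeting
  of oppositely regulated planted genes (an upregulated miRNA
  preferentially targets downregulated genes — the repression
  expectation every downstream integration stage must recover);
* a typed directed knowledge graph containing intermediate regulator
  nodes, wired direction-consistently so that inverse regulation is
  visible at path lengths 1 and 2.

One global seed governs everything; per-component substreams are
derived deterministically, so identical config => identical outputs.
Lower Ct means higher abundance: a planted Ct effect < 0 is an
upregulated miRNA.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .mirna_de import CtMatrix, DEFAULT_CEILING
from .mrna_de import ExpressionMatrix, PRESENT, ABSENT

CONTROL, CASE = "control", "case"


@dataclass
class SimulationConfig:
    """Study conditions of the simulated experiment.

    Defaults mirror the profiled design: a 750-assay rodent miRNA panel
    and ~20k genes, 3 animals per strain, ~10% of features perturbed
    with a 2-cycle Ct shift (fourfold) for miRNAs and a twofold change
    for genes, realistic replicate noise, detection limit at Ct 35, and
    a sparse target map that preferentially links planted miRNAs to
    oppositely planted genes.
    """

    n_mirnas: int = 750
    n_genes: int = 20000
    n_per_group: int = 3
    frac_de: float = 0.1
    effect_ct: float = -2.0
    effect_log2fc: float = 1.0
    noise_sd_ct: float = 0.3
    noise_sd_log2: float = 0.25
    detect_limit_ct: float = 35.0
    baseline_ct_range: tuple[float, float] = (18.0, 34.0)
    #: planted miRNA effects are drawn from miRNAs with baseline Ct at or
    #: below this value: differential expression of species sitting at the
    #: detection limit is not recoverable by any analysis, and real DE
    #: calls come from the reliably detected fraction of the panel.
    plant_max_baseline_ct: float = 27.0
    flag_absent_quantile: float = 0.1
    target_map_density: float = 0.02
    p_target_true: float = 0.9
    n_intermediates: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_de", "flag_absent_quantile", "target_map_density", "p_target_true"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for name in ("effect_ct", "effect_log2fc", "noise_sd_ct", "noise_sd_log2",
                     "detect_limit_ct", "plant_max_baseline_ct"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        lo, hi = self.baseline_ct_range
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ValueError("baseline_ct_range must be a finite (lo, hi) with lo < hi")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline_ct_range"] = list(self.baseline_ct_range)
        return d


@dataclass
class GroundTruth:
    """Planted ids, directions, effects, and true target pairs."""

    de_mirnas_up: set[str] = field(default_factory=set)
    de_mirnas_down: set[str] = field(default_factory=set)
    de_genes_up: set[str] = field(default_factory=set)
    de_genes_down: set[str] = field(default_factory=set)
    true_target_pairs: set[tuple[str, str]] = field(default_factory=set)
    planted_effects: dict[str, float] = field(default_factory=dict)
    mirna_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.de_mirnas_up & self.de_mirnas_down:
            raise ValueError("up/down miRNA sets must be disjoint")
        if self.de_genes_up & self.de_genes_down:
            raise ValueError("up/down gene sets must be disjoint")

    def merged(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            de_mirnas_up=self.de_mirnas_up | other.de_mirnas_up,
            de_mirnas_down=self.de_mirnas_down | other.de_mirnas_down,
            de_genes_up=self.de_genes_up | other.de_genes_up,
            de_genes_down=self.de_genes_down | other.de_genes_down,
            true_target_pairs=self.true_target_pairs | other.true_target_pairs,
            planted_effects={**self.planted_effects, **other.planted_effects},
            mirna_ids=self.mirna_ids or other.mirna_ids,
            gene_ids=self.gene_ids or other.gene_ids,
        )


def _rng(config: SimulationConfig, component: int) -> np.random.Generator:
    # deterministic per-component substream of the single global seed
    return np.random.default_rng([int(config.seed), component])


def _sample_ids(config: SimulationConfig) -> tuple[list[str], pd.Series]:
    names = [f"{CONTROL}_{i + 1}" for i in range(config.n_per_group)] + [
        f"{CASE}_{i + 1}" for i in range(config.n_per_group)
    ]
    groups = pd.Series(
        [CONTROL] * config.n_per_group + [CASE] * config.n_per_group, index=names
    )
    return names, groups


def _plant(rng: np.random.Generator, n: int, frac: float, effect: float,
           eligible: np.ndarray | None = None):
    """Pick planted feature indices; first half get +effect, rest -effect.

    ``eligible`` restricts the candidate indices (e.g. to well-detected
    miRNAs); planting is scaled to the full feature count.
    """
    n_de = int(round(frac * n))
    pool = np.arange(n) if eligible is None else np.asarray(eligible)
    if n_de > len(pool):
        raise ValueError(f"cannot plant {n_de} effects among {len(pool)} eligible features")
    idx = np.sort(rng.choice(pool, size=n_de, replace=False))
    effects = np.zeros(n)
    half = n_de // 2
    effects[idx[:half]] = effect
    effects[idx[half:]] = -effect
    return idx, effects


def simulate_ct_experiment(config: SimulationConfig) -> tuple[CtMatrix, GroundTruth]:
    """Simulate the miRNA Ct array.

    Planted miRNAs are shifted by +-effect_ct in the case group; noisy
    Ct values above detect_limit_ct are recorded Undetermined (ceiling
    40).  effect < 0 (lower case Ct) means upregulated.
    """
    rng = _rng(config, 0)
    n = config.n_mirnas
    ids = [f"mir-{i:04d}" for i in range(n)]
    lo, hi = config.baseline_ct_range
    baseline = rng.uniform(lo, hi, size=n)
    eligible = np.flatnonzero(baseline <= config.plant_max_baseline_ct)
    if len(eligible) == 0:
        eligible = None  # whole range above the planting cap: plant anywhere
    _, effects = _plant(rng, n, config.frac_de, config.effect_ct, eligible=eligible)
    names, groups = _sample_ids(config)
    g = config.n_per_group
    vals = baseline[:, None] + rng.normal(0.0, config.noise_sd_ct, size=(n, 2 * g))
    vals[:, g:] += effects[:, None]
    vals = np.where(vals > config.detect_limit_ct, DEFAULT_CEILING, vals)
    vals = np.clip(vals, 1e-6, DEFAULT_CEILING)
    truth = GroundTruth(
        de_mirnas_up={ids[i] for i in range(n) if effects[i] < 0},
        de_mirnas_down={ids[i] for i in range(n) if effects[i] > 0},
        planted_effects={ids[i]: effects[i] for i in range(n) if effects[i] != 0},
        mirna_ids=ids,
    )
    ct = CtMatrix(pd.DataFrame(vals, index=ids, columns=names), groups)
    return ct, truth


def simulate_microarray(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate the gene microarray.

    log2 intensities are Gaussian around per-gene baselines (N(8, 2));
    planted genes are shifted by +-effect_log2fc in the case group; the
    dimmest flag_absent_quantile of genes (by mean intensity) is
    flagged absent in every sample, all others present.
    """
    rng = _rng(config, 1)
    n = config.n_genes
    ids = [f"gene-{i:05d}" for i in range(n)]
    baseline = rng.normal(8.0, 2.0, size=n)
    # plant only among detectably expressed genes: a gene destined for the
    # absent-flag fraction would be filtered before testing, and real DEG
    # calls come from detected probes
    cut = np.quantile(baseline, config.flag_absent_quantile) + abs(config.effect_log2fc)
    eligible = np.flatnonzero(baseline >= cut)
    if len(eligible) < int(round(config.frac_de * n)):
        eligible = None
    _, effects = _plant(rng, n, config.frac_de, config.effect_log2fc, eligible=eligible)
    names, groups = _sample_ids(config)
    g = config.n_per_group
    vals = baseline[:, None] + rng.normal(0.0, config.noise_sd_log2, size=(n, 2 * g))
    vals[:, g:] += effects[:, None]

    mean = vals.mean(axis=1)
    k = int(round(config.flag_absent_quantile * n))
    absent = np.zeros(n, dtype=bool)
    absent[np.argsort(mean, kind="stable")[:k]] = True
    flags = np.where(np.broadcast_to(absent[:, None], vals.shape), ABSENT, PRESENT)

    truth = GroundTruth(
        de_genes_up={ids[i] for i in range(n) if effects[i] > 0},
        de_genes_down={ids[i] for i in range(n) if effects[i] < 0},
        planted_effects={ids[i]: effects[i] for i in range(n) if effects[i] != 0},
        gene_ids=ids,
    )
    expr = ExpressionMatrix(
        pd.DataFrame(vals, index=ids, columns=names),
        pd.DataFrame(flags, index=ids, columns=names),
        groups,
    )
    return expr, truth


def simulate_target_map(config: SimulationConfig, truth: GroundTruth) -> dict[str, set[str]]:
    """miRNA->target map: background density plus true inverse pairs.

    Each miRNA targets a binomial(n_genes, density) random gene subset;
    additionally every planted miRNA targets each oppositely planted
    gene with probability p_target_true.  True pairs are recorded into
    ``truth.true_target_pairs`` (the passed object is mutated).
    """
    if not truth.mirna_ids or not truth.gene_ids:
        raise ValueError("truth must carry both miRNA and gene ids")
    rng = _rng(config, 2)
    genes = np.array(truth.gene_ids)
    tmap: dict[str, set[str]] = {}
    for m in truth.mirna_ids:
        k = rng.binomial(len(genes), config.target_map_density)
        tmap[m] = set(rng.choice(genes, size=k, replace=False)) if k else set()
    for mirnas, targets in (
        (truth.de_mirnas_up, truth.de_genes_down),
        (truth.de_mirnas_down, truth.de_genes_up),
    ):
        for m in sorted(mirnas):
            gs = sorted(targets)
            hit = rng.random(len(gs)) < config.p_target_true
            for g_id, h in zip(gs, hit):
                if h:
                    tmap[m].add(g_id)
                    truth.true_target_pairs.add((m, g_id))
    return tmap


def simulate_knowledge_graph(
    config: SimulationConfig, truth: GroundTruth, target_map: dict[str, set[str]]
) -> nx.DiGraph:
    """Typed directed regulatory graph with intermediate regulator nodes.

    Nodes are miRNAs, genes and n_intermediates regulators; direct
    miRNA->gene edges come from the target map.  Each regulator relays
    one miRNA to a handful of genes (miRNA->regulator->gene), chosen
    direction-consistently for planted miRNAs (an up miRNA relays to
    down or unplanted genes and vice versa), so some pairs are
    connected only through one intermediate.  Planted nodes carry a
    ``direction`` attribute.
    """
    rng = _rng(config, 3)
    g = nx.DiGraph()
    direction = {**{m: "up" for m in truth.de_mirnas_up},
                 **{m: "down" for m in truth.de_mirnas_down},
                 **{x: "up" for x in truth.de_genes_up},
                 **{x: "down" for x in truth.de_genes_down}}
    for m in truth.mirna_ids:
        g.add_node(m, type="mirna", direction=direction.get(m))
    for x in truth.gene_ids:
        g.add_node(x, type="gene", direction=direction.get(x))
    for m, targets in target_map.items():
        for x in sorted(targets):
            g.add_edge(m, x, interaction="targets")

    genes = np.array(truth.gene_ids)
    up_or_none = np.array(sorted(set(truth.gene_ids) - truth.de_genes_down))
    down_or_none = np.array(sorted(set(truth.gene_ids) - truth.de_genes_up))
    for i in range(config.n_intermediates):
        r = f"reg-{i:03d}"
        g.add_node(r, type="regulator", direction=None)
        m = truth.mirna_ids[int(rng.integers(len(truth.mirna_ids)))]
        if m in truth.de_mirnas_up:
            pool = down_or_none  # up miRNA represses: relay toward down genes
        elif m in truth.de_mirnas_down:
            pool = up_or_none
        else:
            pool = genes
        n_out = int(rng.integers(2, 5))
        outs = rng.choice(pool, size=min(n_out, len(pool)), replace=False)
        g.add_edge(m, r, interaction="regulates")
        for x in outs:
            g.add_edge(r, x, interaction="regulates")
    return g


@dataclass
class StudyData:
    ct: CtMatrix
    expr: ExpressionMatrix
    target_map: dict[str, set[str]]
    graph: nx.DiGraph
    truth: GroundTruth


def simulate_study(config: SimulationConfig) -> StudyData:
    """Generate the full study: both platforms, target map, graph, truth."""
    ct, t_mir = simulate_ct_experiment(config)
    expr, t_gene = simulate_microarray(config)
    truth = t_mir.merged(t_gene)
    tmap = simulate_target_map(config, truth)
    graph = simulate_knowledge_graph(config, truth, tmap)
    return StudyData(ct=ct, expr=expr, target_map=tmap, graph=graph, truth=truth)
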