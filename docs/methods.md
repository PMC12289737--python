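# Methods

`mirmint` implements a two-group miRNA/mRNA differential-expression and
integration workflow of the kind used to compare an autism-model mouse
strain (BTBR) with a control strain (C57BL/6J) in prefrontal cortex:
qPCR-panel (Ct-array) processing for miRNAs, microarray processing for
mRNAs, gene-set over-representation against an expressed-gene
background, inverse miRNA–target intersection, regulatory-graph
relation analysis, and comparative-Ct qPCR validation. A synthetic-data
generator with known ground truth stands in for deposited array data so
that every stage is testable offline.

## Ct-array (miRNA) pipeline

Cycle threshold (Ct) is the PCR cycle at which fluorescence crosses the
detection threshold; lower Ct means more template. A reaction that
never amplifies within the run is "Undetermined" and is encoded at a
ceiling of 40 cycles. The pipeline runs, in order:

1. censor: any Ct > 35 is set to 40 (first pass);
2. filter: any miRNA Undetermined in ≥ 4 of the samples is removed;
3. quantile normalization (ceiling values participate — the censoring
   is re-applied *after* normalization, which implies censored values
   are present in the normalized matrix);
4. re-censor at Ct > 30, re-filter at ≥ 4 Undetermined;
5. per-miRNA equal-variance two-sample Student t-test on the normalized
   Ct values, Benjamini–Hochberg (BH) adjustment;
6. fold change as the relative quantity RQ = 2^−ΔΔCt with
   ΔΔCt = mean Ct(case) − mean Ct(control); a miRNA is called when
   adj p ≤ 0.05 **and** RQ > 2 or RQ < 0.5 (the fold-change threshold
   is two-sided, since both up- and downregulated calls are reported
   under one threshold).

No endogenous control is used at the panel stage: the global quantile
normalization plays that role, so ΔΔCt is computed directly from
normalized group means. Features with zero pooled variance get an
undefined (NaN) p-value, are excluded from the BH family, and are never
callable. "Student's t-test" is taken as the equal-variance (pooled)
form. "≥ 4 samples" is counted against the total sample count, not per
group.

Quantile normalization replaces each column's values with the
across-column mean of sorted columns at the matching ranks; ties within
a column receive the mean of the reference values at the tied ranks,
which makes the operation idempotent.

## Microarray (mRNA) pipeline

1. flag filter: keep probes flagged present (P) or marginal (M) in at
   least one sample;
2. error filter: keep genes whose coefficient of variation — sd/mean of
   the **linear-scale** (2^log2) intensities — is strictly below 0.5 in
   both conditions (CV of log-scale values is not a standard quantity);
3. quantile normalization (no baseline transformation);
4. moderated t-test: per-gene pooled variance s²_g with d = n₁+n₂−2
   residual df is shrunk toward an empirical-Bayes prior,
   s̃²_g = (d₀s₀² + d s²_g)/(d₀+d), and t̃_g = log2FC/(s̃_g·√(1/n₁+1/n₂))
   is referred to a t distribution with d₀+d df. The hyperparameters
   (d₀, s₀²) are estimated by the closed-form moment-matching of the
   scaled-F model of Smyth (2004): with z_g = log s²_g, the mean and
   sample variance of e_g = z_g − ψ(d/2) + log(d/2) are matched to
   their digamma/trigamma expressions and solved for d₀ (trigamma
   inverse by Newton iteration) and then s₀². When the excess
   dispersion of e_g is nonpositive, d₀ = ∞ and s₀² is the mean sample
   variance (all genes share one variance). A test cross-checks d₀,
   s₀² and t̃ against Bioconductor limma to ~1e-6 relative accuracy.
5. calling: BH-adjusted p < 0.05 and linear fold change ≥ 1.5
   (inclusive, applied to 2^|log2FC|).

The expressed-gene background for enrichment is built from the
flag-filtered, normalized matrix **before** the CV filter (a weakly
varying gene is still expressed): genes whose mean normalized
expression is at or above the 10th percentile, ties at the cutoff
retained. Probe→gene collapsing is out of scope; features are treated
as genes.

`d0_override` exposes the two limits (0 = ordinary t, ∞ = full
shrinkage) for diagnostics.

## Enrichment

Over-representation of a query list in a named gene set is scored with
the hypergeometric upper tail P(X ≥ k) for overlap k, set size K, query
size n, background size N, with query and sets intersected with the
background first (one-sided over-representation only). The odds ratio
is the cross-product of the 2×2 overlap table, with a Haldane–Anscombe
0.5 added to every cell when any cell is zero. BH is applied within a
collection, not across collections.

## Integration

Inverse-regulation intersection: since miRNAs repress targets, the
targets of upregulated miRNAs are intersected with downregulated genes
and vice versa, each overlap tested hypergeometrically against the
expressed-gene background.

Graph relations: miRNA→gene relations are discovered over directed
edges only (regulator→miRNA edges are never traversed from a miRNA).
"Shortest path" mode accepts direct edges; "shortest path plus one"
accepts each pair's shortest path when its length is ≤ 2, i.e. at most
one intervening regulator (the lexicographically smallest intermediate
is reported when several connect a pair). Relations are unique per
(miRNA, gene) pair — parallel paths collapse — and the output order is
canonical (miRNA id, then gene id), independent of graph insertion
order.

Direction pairs of the unique relations are cross-tabulated (rows:
miRNA up/down; columns: gene up/down) and tested for independence with
a 2×2 Pearson chi-square, df = 1. The Yates continuity correction
(subtract 0.5 from each |O−E|, floored at 0) is on by default — the
convention for 2×2 tables — and exposed as a flag; the corrected
statistic never exceeds the uncorrected one, which equals
(ad−bc)²·N/(r₁r₂c₁c₂). A warning is emitted when any expected count is
below 5.

## qPCR validation

Comparative-Ct quantification: per replicate, ΔCt = Ct(target) −
Ct(reference gene); ΔΔCt is taken against the control-group mean ΔCt,
so control RQs center on 1; RQ = 2^−ΔΔCt. Group differences are tested
on the replicate ΔCt values (the variance-stabilized scale, rather than
on RQ) with an equal-variance Student t. Technical replicates of pooled
RNA are the testing unit: with pooled samples no biological-replicate
inference is possible, a documented limitation. The reference gene is
user-specified (e.g. L41 for mRNA, RNU19 for miRNA); there is no
automatic reference selection and no primer-efficiency (Pfaffl)
correction.

Cross-platform concordance is the Pearson correlation of paired
per-gene log2 fold changes (two-sided p from the t transform), plus the
sign-agreement fraction.

## Clustering

The heat-map dendrogram uses agglomerative clustering with Euclidean
distance and complete linkage (cluster distance = maximum pairwise
distance, which guarantees monotone merge heights). Tie-breaks are
deterministic — among equally distant pairs, the smallest
(cluster-id, cluster-id) pair merges first — and the leaf order is the
recursive left-first traversal with the smaller cluster id as the left
child. This in-package implementation exists because the deterministic
tie-break and traversal are part of the contract; scipy's linkage is
used as an independent oracle in tests on tie-free data.

## Synthetic data generator

The generator emulates the profiled design: a 750-assay rodent miRNA
panel and ~20,000 genes, 3 animals per group. Defaults:

| parameter | default | meaning |
|---|---|---|
| n_mirnas / n_genes | 750 / 20000 | panel and array sizes |
| n_per_group | 3 | animals per strain |
| frac_de | 0.1 | fraction of features perturbed |
| effect_ct | −2 Ct | planted miRNA shift (two-sided: half +, half −); < 0 ⇒ up |
| effect_log2fc | 1 log2 | planted gene shift (two-sided) |
| noise_sd_ct / noise_sd_log2 | 0.3 Ct / 0.25 log2 | replicate noise |
| detect_limit_ct | 35 Ct | noisy Ct above this is Undetermined (40) |
| baseline_ct_range | U(18, 34) | per-miRNA baseline abundance |
| plant_max_baseline_ct | 27 Ct | planted miRNAs drawn from the well-detected range |
| flag_absent_quantile | 0.1 | dimmest genes flagged absent in all samples |
| target_map_density | 0.02 | background miRNA→gene targeting rate |
| p_target_true | 0.9 | planted miRNA targets each oppositely planted gene |
| n_intermediates | 50 | regulator nodes in the knowledge graph |

Baselines are uniform for Ct (plausible for a panel spanning abundant
to near-detection species) and Gaussian N(8, 2) in log2 for arrays
(log-normal intensities); replicate noise is Gaussian on both scales.
The Undetermined mechanism is a deterministic detection limit applied
to the noisy Ct (not missing-at-random), mirroring qPCR chemistry.
A single global seed governs all draws; per-component substreams are
derived deterministically, so identical config ⇒ identical outputs.

Planted effects are drawn only from the detectable range (miRNAs with
baseline Ct ≤ 27; genes above the absent-flag quantile plus the effect
size): a fold change planted on a species at the detection limit is
censored away before testing and is unrecoverable by any analysis, and
real DE calls arise from the reliably detected fraction of a panel.

Regulator nodes are wired direction-consistently: each regulator relays
one miRNA to a handful of genes, and when the source miRNA is planted,
the relayed genes are drawn from the oppositely planted or unplanted
pool. This keeps the inverse-regulation structure visible at path
length 2 as well as 1, which is what the integration stage is designed
to detect.

What the generator does **not** emulate: probe-level microarray images,
pre-amplification chemistry, inter-plate calibrators, batch effects,
correlated noise between features, or realistic miRNA target-site
biology. Passing tests therefore demonstrate correctness of the
statistical machinery and recoverability of planted structure, not
performance on real array data.

## Problem sizes and numerical choices

The test suite and the acceptance script use scaled-down studies chosen
as the package's own fixtures: null calibration on 750 miRNAs / 600
genes across 20 seeds, miRNA recovery at 300 miRNAs with 20 planted,
integration recovery at 60 miRNAs × 500 genes, mRNA recovery at 4,000
genes, and a 16-gene qPCR concordance panel — large enough for stable
binomial tolerances (3 standard errors) while keeping a full run in
seconds. Degenerate inputs are handled explicitly: zero-variance
features (NaN p, uncallable), empty queries (k=0, p=1), zero table
margins (error), single-column matrices (error), duplicate rows in
clustering (zero-height merges permitted).

## Known limitations

- With 3 vs 3 samples the pooled-variance t has only 4 df; the pooled
  SD is noisy, so even a 2-cycle shift (fourfold) at σ = 0.3 is
  recovered at a BH-adjusted 0.05 threshold only ~80% of the time on a
  300-feature panel. This is a property of the design, not of the
  implementation; the moderated t used on the mRNA side exists
  precisely to mitigate it by borrowing df across genes.
- Quantile normalization redistributes strongly one-sided planted
  shifts on small panels (it forces identical column distributions);
  fold changes are faithfully preserved only when DE is a modest
  fraction of the panel or balanced in direction.
- Pooled-RNA qPCR supports technical-replicate inference only.
- The hypergeometric p is discrete and hence conservative for small
  sets; calibration checks allow for this.
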