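# Methods

This note documents the models, estimators and design choices behind `screg`,
in the order the pipeline runs them, together with what the synthetic
benchmark does and does not establish.

## Synthetic data model

The generator emulates a FACS-purified neonatal retinal endothelial scRNA-seq
experiment with three conditions — wild type (WT), a ligand knockout (KO) that
silences a WNT-driven regulator module and depletes the deep tip-cell
population, and a rescue (KO + WNT agonist) that restores both — across seven
subpopulations (D-tip, S-tip, arterial, venous, two proliferative, pan-EC).

**Counts.** Gene g in cell c is negative binomial with mean
`lib_c · rel_gc / Σ_g rel_gc` and shared dispersion θ = 2 (a standard
stand-in for droplet data; the generator makes no claim to match any real
dataset's noise). Library sizes are lognormal(9.2, 0.35), about 10k counts,
within the 1,200–2,800 cells-per-channel loading range typical of the
platform. The relative mean `rel_gc` composes multiplicatively on the log
scale from:

* a lognormal(0, 1) gene baseline;
* a marker program: each non-pan-EC type carries 40 marker genes boosted by
  log-factor 2.5 in that type. Pan-EC cells are deliberately marker-free —
  in the real tissue they are defined by *absence* of subset markers, and the
  cell-typing stage labels them by fallback;
* regulator activity: each of 20 regulators r has per-cell activity
  `a_rc = a(r, condition, type) + ε`, with ε ~ N(0, 0.75²) per cell. The
  regulator's own transcript scales by `exp(a_rc)` and each of its 30 targets
  by `exp(mode · a_rc)`, modes +1 with probability 0.7 and −1 otherwise, so
  that repression exercises the two-tailed enrichment machinery. Target sets
  are disjoint across regulators and drawn from non-marker genes;
* a mitochondrial block of 13 genes pinned to 5% of each healthy cell's
  expected counts and 15% in a "damaged" 5% of cells, giving the QC filter a
  planted population to remove.

**Calibration of the free parameters.** Neither the marker-program strength
nor the activity jitter has an empirical anchor, so both were set by two
requirements that hold in the real data this emulates: cell-type identity must
dominate total variance (the types are separable by standard graph
clustering), and regulator activity must fluctuate enough between cells that
the WT network is recoverable from 500 metacells. 40 markers/type at ~12×,
with activity jitter 0.75 (comparable to the planted condition effect of 1.0),
satisfies both; weaker markers let the 20 regulator-activity directions take
over the leading principal components, which no clustering can undo.

**Planted scenario.** Regulators 1–6 (the WNT-module analog) are active
(a = 1) in D-tip cells in WT and rescue, silent in KO; regulator 7 (the
leakage-marker analog) is induced everywhere in KO and suppressed by the
rescue; regulators 8–10 respond only to the treatment; 11–20 carry no
condition effect. Compositions: D-tip 0.15 → 0.02 → 0.12 and S-tip
0.10 → 0.07 → 0.07 across WT/KO/rescue, with the remaining types roughly
stable and pan-EC absorbing the balance. Cells are allocated to types by
largest-remainder rounding of these proportions rather than a multinomial
draw: the realized composition then equals the planted one exactly, so the
abundance stage is tested on recovery of the planted shift, not on multinomial
sampling luck (the S-tip shift is near the detection boundary at n = 1,500 and
would otherwise appear or vanish with the draw).

## QC, normalization, clustering

QC keeps cells with depth in [1,000, 50,000], ≥ 500 detected genes and ≤ 20%
mitochondrial counts (all configurable; these are package defaults, not
estimates from any dataset). Normalization is `log(1 + CPM)` for clustering
and signatures, and analytic negative-binomial Pearson residuals
`(x − μ)/sqrt(μ + μ²/θ)` with fixed θ = 100 and clipping at ±√n_cells as the
variance-stabilized representation for metacell neighbor search — a
closed-form substitute for iterative regression-based stabilization, chosen
because it is fully specifiable and oracle-testable.

Clustering is PCA (20 components on per-gene standardized log-CPM) → kNN
graph (k = 15, Euclidean) → shared-nearest-neighbor Jaccard weighting with
pruning below 1/k → greedy modularity (CNM) communities → a connectivity
merge pass. The merge pass addresses the resolution behavior of modularity on
dense kNN graphs, which otherwise fragments large homogeneous populations:
two communities are merged while their summed cross-edge SNN weight exceeds
`0.015 · k · min(sizes)`. Fragments of one population share many
high-overlap neighborhoods across their boundary (weighted connectivity
≳ 0.02 empirically), while genuinely distinct types touch only through sparse
low-Jaccard edges (≲ 0.009); the threshold sits between the two regimes. The
conditions share one batch by construction, so no integration/anchoring step
is included; on real multi-batch data one would be required.

## Metacells

One candidate metacell per cell: its raw counts plus those of its five
nearest neighbors (self excluded; metacell size 6), neighbors found in
Pearson-residual space under `sqrt(1 − ρ_Spearman)`, ties broken by ascending
cell index for determinism. Neighbors may be shared between metacells; the
member map records overlaps. Candidates are randomly subset to at most 500
(seeded) and CPM-normalized. Network inference consumes WT metacells only by
default (the network is reverse-engineered from the unperturbed condition);
the condition is configurable.

## Network inference

**MI estimator.** Plug-in mutual information on equal-frequency (rank) bins
with Miller–Madow bias correction, floored at zero. For generic two-vector
use the bin count defaults to ⌈√n⌉; the metacell-scale network uses 6 bins
(≈ 14 expected counts per 2-D cell at n = 500). Finer binning at this n both
raises the estimator's noise floor an order of magnitude above the signal of
a ρ ≈ 0.3 dependence and over-resolves the sparse margins of low-expression
genes, whose depth-linked zero patterns then register as dependence on every
pair.

**Null and threshold.** The null is built from ≥ 1,000 permuted
regulator–target pairs; a rate-λ exponential is fitted to the top 5% of null
MI values above the 95th percentile u, giving
`cutoff(α) = u + ln(0.05/α)/λ` for α < 0.05 and tail p-values
`0.05·exp(−λ(MI − u))` — significance levels far below 1/n_perm (including
the full-scale 10⁻⁸ profile) remain reachable by extrapolation. Inside a
bootstrap the permutation is applied over the *original* samples and then the
bootstrap's resampling indices: resampling with replacement duplicates rows,
and duplicate alignment inflates the MI of every pair; a null permuted after
resampling loses that alignment and its cutoff collapses (observed: hundreds
of false targets per regulon).

**DPI.** Triangles are processed in lexicographic order; in each
still-complete triangle the weakest edge is removed when its MI is below
(1 − tolerance) times the smaller of the other two, ties broken
lexicographically. The output provably contains no intact triangle violating
the condition.

**Consolidation.** Per regulator class, an edge's bootstrap support count is
tested against Binomial(n_boot, p̄), p̄ the class's mean per-bootstrap edge
frequency, BH-corrected, retained at q < 0.05; class networks are unioned.
Defaults follow a desk profile (50 bootstraps, α = 10⁻⁴, ≥ 10 targets per
regulon) sized for the 2,000-gene reference scenario; the full-scale profile
(200 bootstraps, α = 10⁻⁸, ≥ 50 targets) is a configuration switch.

**Regulons.** Mode = Spearman correlation between regulator and target CPM
across metacells (in [−1, 1]); weight ∝ consolidated-edge MI, normalized to
sum 1 per regulon.

Known limitation: regulators sharing a cell-type-restricted activity (the
planted WNT module in D-tip) also correlate with that type's markers and with
each other's targets, and cross-class edges of this kind survive DPI (DPI
runs within regulator class, and marker genes, not being regulators, form no
triangles). Such regulons carry genuine type-covariate targets beyond the
planted ones; median precision across regulators is the robust summary.

## Signatures and enrichment

Wilcoxon rank-sum signed Z per gene: two-sided p mapped through the inverse
normal CDF and signed by the rank-biserial correlation `2U/(n₁n₂) − 1`. Exact
enumeration of all C(n, n₁) assignments (average-rank ties) when the combined
sample is ≤ 16; otherwise the normal approximation with tie and continuity
corrections — on that path the transform is algebraically the
continuity-corrected z itself and is computed directly, avoiding p-underflow
past |z| ≈ 38. Cluster signatures are cluster-vs-rest; contrast signatures
condition-vs-condition, oriented positive = higher in the first condition;
per-cell signatures are per-gene standardized (scaled) expression.

NES of a regulon in a signature: targets' normal scores
`q_i = Φ⁻¹(rank_i/(G+1))` combined as `Σ w m q / sqrt(Σ w²)` — the two-tail
directional core of regulon-enrichment statistics, standard normal under
random gene assignment (verified by Monte-Carlo). Pleiotropy/shadow
corrections are out of scope. PES divides NES by the extremal configuration
(heaviest weights on the most extreme normal scores), giving a signed
proportion in [−1, 1]; gene-set enrichment is the same statistic with unit
weights and modes. The two-sided "p from |NES|" is used throughout, BH across
sets or regulators.

## Abundance and cell typing

Clusters are labeled with the marker set of maximal NES when that NES is
positive and significant (BH across sets, q < 0.05), otherwise "pan-EC" —
mirroring how pan-endothelial cells are identified by absence of subset
markers. Composition shifts use the Pearson chi-square on the 2 × T
condition-by-type table; per-type inference uses Haberman adjusted
standardized residuals (approximately standard normal under independence,
which raw residuals are not — raw residuals remain available behind a flag),
read from the second condition's row, two-sided, BH across types.

## Rescue classification

With q-values from BH over regulators per contrast (p = 2(1 − Φ(|NES|))):
a regulator significant in KO-vs-WT is **rescued** if its rescue-contrast
activity flips sign or shrinks to ≤ (1 − revert_fraction) of the KO magnitude
(default revert_fraction 0.5), **not_rescued** if it stays within 5% of the
KO magnitude, **partially_rescued** in between; a regulator significant only
in rescue-vs-WT is **treatment_specific**; otherwise **unchanged**. The
numeric bounds are package choices — the biological notion of "reverting
toward wild type" has no canonical cutoff — and are exposed as configuration.
For recovery metrics, a rescue call in the reporting sense is
`rescued ∪ partially_rescued`: both are KO-significant regulators whose
activity is reduced or reverted under treatment; the split between them is a
gradation of the same call. Contrast signatures use the same rank-based
statistic as the rest of the package rather than a count-model GLM; on strong
effects the two agree in sign, and a single statistic keeps every stage
oracle-testable.

## Problem sizes and reproducibility

The reference scenario (2,000 genes; 20 regulators × 30 disjoint targets;
three conditions × 1,500 cells; 500 WT metacells; 50 bootstraps at α = 10⁻⁴)
is the package's default and the size at which all recovery tests and the
acceptance script run; end-to-end it takes about a minute on one CPU. Every
stochastic stage derives its generator from the single top-level seed via
fixed named substreams, so stages are individually re-runnable and re-runs
are byte-identical; all writers emit deterministic column order, row sort and
float formatting.

## What the benchmark does and does not show

Passing recovery tests shows the chain of estimators is correctly implemented
and calibrated, and recovers structure of the planted kind at realistic size
and noise. The generator omits doublets, ambient RNA, batch effects, UMI
saturation, cell-type-specific dispersion, and any form of regulon overlap or
combinatorial regulation; type programs are discrete marker blocks rather
than graded transcriptional continua. Results on real droplet data — where
those features exist and regulator activity is not reflected in the
regulator's own transcript nearly so directly — will be correspondingly
weaker, and the network stage in particular inherits every caveat of
MI-plus-DPI inference on observational data.
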