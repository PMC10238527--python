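# screg — single-cell master-regulator analysis

`screg` implements a master-regulator (MR) analysis pipeline for three-condition
single-cell RNA-seq designs of the form *wild type / knockout / knockout +
treatment*, modeled on neonatal retinal endothelium in which a WNT-pathway
knockout depletes the deep-diving tip-cell (D-tip) population and a WNT
surrogate agonist restores it. It is written for computational biologists who
want the full inference chain — not a wrapper around existing network tools —
with every statistic specified and tested against independent oracles:

1. **QC and clustering** — depth / gene-count / mitochondrial filters; log-CPM
   and analytic Pearson-residual normalization; PCA → shared-nearest-neighbor
   graph → greedy modularity communities.
2. **Metacells** — each cell is summed with its five nearest neighbors under
   the distance `sqrt(1 − ρ)` (ρ = Spearman correlation in variance-stabilized
   expression), randomly subset to 500, CPM-normalized.
3. **Network inference** — per bootstrap, regulator–gene mutual information
   (equal-frequency binning, Miller–Madow correction) thresholded against a
   permutation null with an exponential tail fit; indirect edges removed by the
   data-processing inequality (DPI); edges consolidated across bootstraps by a
   binomial support test (BH q < 0.05), separately per regulator class (TF,
   coTF, signaling, surface) and unioned.
4. **Signatures and activity** — gene-expression signatures are Wilcoxon
   rank-sum Z-scores signed by the rank-biserial correlation
   (`z = Φ⁻¹(1 − p/2) · sign(2U/(n₁n₂) − 1)`); regulon activity is the weighted
   two-tail rank enrichment
   `NES = Σᵢ wᵢ mᵢ qᵢ / sqrt(Σᵢ wᵢ²)`, with `qᵢ = Φ⁻¹(rankᵢ/(G+1))` the
   signature's normal scores, standard normal under random gene assignment;
   `PES = NES / NES_max ∈ [−1, 1]` gives the direction.
5. **Abundance** — condition × cell-type chi-square with Haberman adjusted
   standardized residuals, `r = (O − E)/sqrt(E(1−p_row)(1−p_col))`, per-type
   two-sided p-values and BH correction.
6. **Rescue classification** — per regulator, NES for the KO-vs-WT and
   rescue-vs-WT contrasts; categories `rescued / partially_rescued /
   not_rescued / treatment_specific / unchanged`.

A first-class synthetic-data module generates the three-condition experiment
with planted regulons, cell types and abundance shifts (negative-binomial
counts), plus machine-readable ground truth, so the entire chain is validated
by parameter recovery.

## Worked example

```python
import screg, pandas as pd

# simulate the reference scenario: 2,000 genes, 20 regulators x 30 targets,
# 3 conditions x 1,500 cells
adata, truth = screg.simulate_dataset(screg.SimConfig(seed=0))

filtered = screg.qc_filter(adata)                    # 4,500 -> ~4,490 cells
logcpm   = screg.normalize_log_cpm(filtered)
clusters = screg.cluster_cells(logcpm, seed=0)       # 7 clusters

wt = filtered[(filtered.obs.condition == "WT").to_numpy()].copy()
mc = screg.subset_and_cpm(
    screg.build_metacells(wt, screg.pearson_residuals(wt), k=5),
    cap=500, seed=0)
edges    = screg.bootstrap_consolidate(mc, truth.regulator_classes,
                                       n_boot=50, alpha=1e-4, seed=0)
regulons = screg.assemble_regulons(edges, mc, min_targets=10)

cond = filtered.obs.condition.to_numpy()
genes = list(filtered.var_names)
contrasts = pd.DataFrame({
    "KO_vs_WT":     screg.contrast_signature(logcpm, cond == "KO",
                                             cond == "WT", genes),
    "rescue_vs_WT": screg.contrast_signature(logcpm, cond == "rescue",
                                             cond == "WT", genes)})
calls = screg.mr_calls(screg.activity_matrix(regulons, contrasts))
print(calls.head(8).round(3))
```

prints

```
           nes_ko   q_ko  nes_rescue  q_rescue            category
regulator
Reg01      -8.321  0.000      -3.283     0.003             rescued
Reg02      -7.336  0.000      -3.355     0.002             rescued
Reg03      -7.816  0.000      -4.895     0.000   partially_rescued
Reg04      -8.429  0.000      -3.472     0.002             rescued
Reg05      -7.373  0.000      -1.123     0.436             rescued
Reg06      -7.509  0.000      -3.961     0.000   partially_rescued
Reg07       6.961  0.000       0.028     0.978             rescued
Reg08       0.144  0.885       4.333     0.000  treatment_specific
```

Reg01–Reg06 are the planted WNT-analog module (strongly negative NES in the
knockout contrast, shrunk or reverted under treatment); Reg07 is the planted
leakage-marker analog, *induced* by the knockout (positive NES) and suppressed
back to baseline by the treatment; Reg08 responds to the treatment only.

The same pipeline is available from the shell:

```bash
screg-mr simulate --outdir out --seed 0
screg-mr all      --outdir out --seed 0   # qc -> metacell -> network ->
                                          # activity -> abundance -> mr
```

Each stage writes deterministic TSV/JSON outputs (`qc/qc_report.tsv`,
`metacells/members.tsv`, `network/regulons.json`, `abundance/abundance.tsv`,
`mr/mr_calls.tsv`, …) and a JSON log with its parameters and timings.

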