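# scplate

Analysis pipeline for **plate-based single-cell RNA-seq** (SORT-seq /
CEL-Seq2-style chemistry), built for immune-cell profiling experiments in
which FACS-sorted cells land in barcoded 384-well plates together with ERCC
spike-ins and deliberately empty control wells.  It was written for studies
of gut immune cells across clinical conditions (controls, active celiac
disease, gluten-free diet), but nothing in it is tissue-specific.

The package covers the full desk-side workflow:

* **Demultiplexing & UMI counting** — Read2 carries an 8 nt cell barcode
  followed by an 8 nt UMI, Read1 the cDNA; reads are assigned to wells and
  genes and collapsed to molecule counts (the dedup key is the
  (cell, gene, UMI) triple).
* **Quality control** — four filters: robust per-cell outlier removal at
  3 scaled MADs on log₂ library size (two-sided) and ERCC / mitochondrial
  fractions (upper-sided); a gene-complexity window (300–4000 detected
  genes) that catches sorting aggregates; low-abundance gene removal; and an
  **empty-well noise filter**: spike-ins detected in both cell wells and
  empty wells (cERCCs) normalise each side, and each gene's noise/signal
  ratio — empty-well over cell expression, the cell side averaged over 1000
  permutation subsamples matched in size to the empty-well pool — flags
  ambient-dominated genes, with the threshold placed at the sharp drop of
  the sorted ratio distribution.
* **Spike-in-aware normalization** — per-cell size factors from ERCC totals
  (default), median-of-ratios, or pooled deconvolution, all mean-1.
* **Clustering & annotation** — HVGs → PCA → kNN graph → Leiden, clusters
  annotated against a canonical immune marker panel (CD3 for T cells, SDC1
  for plasma cells, ITGAX/HLA-DRA/CD14 for macrophages/DCs, KIT/TPSB2/CPA3
  for mast cells, MS4A1 for B cells, GNLY/NKG7 for NK, KIT with low CD3 for
  ILCs), plus an optional UMAP for figures.
* **Marker statistics** — Wilcoxon rank-sum (exact by enumeration for small
  tie-free groups) and an empirical-Bayes **moderated t**: per-gene
  variances s²_g on d_g df shrunk toward a fitted prior (d₀, s₀²),
  s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), with t̃ = Δμ/(s̃_g·√(1/n₁+1/n₂)) on
  d₀+d_g df.  Hypergeometric gene-set enrichment with BH correction.
* **Composition testing** — ten 50% subsamples per cluster; per-condition
  cluster percentages; two-sided Student t over the replicate percentages
  for each condition pair.
* **TCR lineage calls** — α/β vs γ/δ from TRAC/TRBC1/TRBC2 vs
  TRGC1/TRGC2/TRDC constant-region expression.
* **Bulk deconvolution** — nonnegative least squares of bulk profiles on
  single-cell cluster signatures, proportions on the simplex.
* **Synthetic plates** — a first-class simulator that generates 384-well
  experiments with planted markers, spike-ins, ambient noise, empty wells,
  aggregates and condition-dependent composition, with full ground truth;
  every stage of the pipeline is validated against it.

## Worked example

```python
from scplate import (default_config, simulate_experiment,
                     compute_size_factors, normalize_counts)
from scplate.qc import run_qc
from scplate.cluster import cluster_cells, annotate_clusters
from scplate.composition import subsample_proportion_test

cfg = default_config(n_plates=3, seed=11, n_ambient_genes=30)
x, truth = simulate_experiment(cfg)
filtered, report = run_qc(x, n_permutations=200, seed=1)
print(report.summary())

nx = normalize_counts(filtered, compute_size_factors(filtered, "spike_total"))
clusters = cluster_cells(nx, seed=2)
print(annotate_clusters(nx, clusters)[["cell_type", "score"]])

comp = subsample_proportion_test(clusters, nx.wells, seed=3)
mc = "C2"  # the mast-cell cluster from the annotation above
print(comp.tests.query("cluster == @mc and cond_a == 'CeD' and cond_b == 'Ctrl'"))
```

prints

```
QC kept 1120/1128 cells and 1557/1573 genes; thresholds: {'nmads': 3.0,
'min_genes': 300, 'max_genes': 4000, 'min_mean': 0.01,
'noise_threshold': 0.912..., 'n_permutations': 200, 'seed': 1}
        cell_type     score
cluster
C0              T  0.893349
C1             PC  0.903670
C2             MC  0.916067
C3          MF-DC  0.906061
C4              T  0.917910
C5              B  0.932203
C6             NK  0.491228
C7            ILC  0.551471
cluster cond_a cond_b  t_statistic      p_value  degenerate
     C2    CeD   Ctrl    -12.46456 2.731423e-10       False
```

Reading the output: QC dropped 8 cells and 16 genes (the planted ambient
genes land above the noise/signal threshold of 0.91); the eight Leiden
clusters annotate to the seven simulated immune types (T cells split into
two clusters); and the composition test flags the simulated mast-cell
depletion in active disease at p ≈ 3×10⁻¹⁰.

The same pipeline runs from the shell:

```bash
scplate run --out demo_run --seed 42        # simulate → … → composition
scplate simulate --out sim --seed 1 --reads # plates + FASTQ pair
scplate qc sim --out sim_qc --permutations 1000 --seed 1
```

Real data enter either as FASTQ pairs plus a barcode whitelist
(`scplate demux`) or as a precomputed MTX + TSV triple
(`mode: matrix` in the pipeline config).

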