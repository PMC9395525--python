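# Methods

This note records the models, parameter choices and numerical conventions
behind `scplate`, and what the synthetic-plate validation does and does not
establish about real data.

## Data model

An `Experiment` is a genes × wells matrix of UMI counts with gene and well
annotation tables and an append-only provenance history.  Genes carry
exactly one class — `ercc` (id prefix `ERCC-`), `mito` (symbol prefix
`MT-`), `tcr_constant` (TRGC1, TRGC2, TRDC, TRAC, TRBC1, TRBC2) or
`endogenous` — with precedence ercc > mito > tcr_constant so spike-ins can
never be mistaken for biology.  Raw counts are never modified in place;
filtering returns new objects and normalization adds layers.  On disk the
exchange format is 1-based coordinate MatrixMarket (genes as rows) plus TSV
tables and a JSON history sidecar.

## Synthetic plates

The simulator generates the statistical structure the analysis assumes:

* **Counts** are negative binomial (gamma–Poisson), mean
  `profile[type, gene] × depth[cell]`, gene-level dispersion 0.3 (a typical
  plate-based overdispersion; spike-ins use 0.05 because synthetic spike-in
  RNA carries no biological variability, only technical noise).  Per-cell
  depth factors are log-normal(0, 0.35), giving the spread that the MAD
  filters are designed to police.
* **Cell types.** Each type shares a heavy-tailed baseline profile
  (log-normal, σ = 1.2 across genes), modulated per type by a
  log-normal(0, 0.25) factor on background genes — real cell types differ
  broadly, not only in a handful of markers — and planted marker genes at a
  configured fold-change (default 8×) over a deliberately low baseline
  (0.25× the average gene), so markers show the on/off contrast canonical
  lineage markers show.  The default panel encodes seven gut immune types
  (T, plasma cells, macrophage/DC, mast cells, B, NK, ILC).
* **Spike-ins** follow a common expected profile at a fixed dilution
  (default 5% of the library), scaled by the same technical depth factor as
  the endogenous genes — that is precisely why spike totals estimate depth.
* **Empty wells** receive `ambient_fraction` (default 0.02) of the
  composition-weighted mean cell profile plus the full spike-in profile.
  The magnitude of ambient contamination is not a measured quantity in the
  protocols this emulates; 2% is a conservative plate-based figure and is a
  config knob, not an assertion.
* **Planted pathologies** (all optional): pure-ambient genes whose
  empty-well signal equals their cell signal, drawn from above-average-
  abundance background genes (ambient RNA is dominated by abundant
  transcripts, and a never-expressed "ambient" gene would be invisible in
  two dozen empty wells); low-library and high-spike-in cells; and
  aggregates formed by summing two independent cell draws, which inflates
  gene complexity.
* **Design.** Wells are laid out on 384-well plates with a configurable
  number of empty controls (default 8/plate); donors are nested in the
  three conditions with 48 intraepithelial wells per donor and the rest
  lamina propria; per-condition type composition defaults to a celiac-like
  shift (T enriched, mast cells and macrophages/DCs depleted in active
  disease).  T cells split 85/15 between α/β and γ/δ lineages via the six
  TCR constant-region genes.
* **Reads.** Read2 is barcode‖UMI, Read1 a random 75-mer of a 500 nt
  transcript generated deterministically by hashing the gene id (no FASTA
  fixtures needed).  PCR duplication adds Poisson(rate) extra copies per
  molecule, so reads/molecule = 1 + rate in expectation.

Everything is bit-reproducible from the config seed.

### What the simulator does *not* emulate

Batch/plate effects, donor-level expression variability, amplification-
length biases, UMI sequencing errors (only uniform substitution is
modelled, off by default), doublets beyond simple sums, and zero-inflation
beyond what the NB produces.  Passing the recovery tests therefore shows
the algorithms are implemented correctly and behave as designed under their
own assumptions — not that those assumptions hold in any particular real
dataset.

## Quality control

* **MAD filter.**  A cell is removed when it deviates more than `nmads`
  (default 3) × 1.4826·MAD from the median on log₂(library+1) (two-sided),
  ERCC fraction (upper side) or mito fraction (upper side).  Fractions are
  filtered on the raw scale, upper side only — unusually *clean* cells are
  not defects.  A zero MAD disables that statistic with a warning.
* **Complexity window.**  Keep cells with 300–4000 detected genes
  (boundaries inclusive; the window excludes values strictly below/above).
  The defaults assume a transcriptome-scale gene universe; on reduced
  synthetic universes the validation recalibrates the upper bound to the
  singlet complexity tail before measuring aggregate recovery.
* **Low-abundance genes.**  All-zero genes are always removed; the mean
  threshold defaults to 0.01, or `auto` places it at the first local
  minimum of a Gaussian KDE of log₂(mean+1) (falling back to 0.01 when the
  density is unimodal).  Spike-ins are exempt.
* **Empty-well noise filter.**  cERCCs are the spike-ins with nonzero total
  in cells *and* in empty wells.  For gene g and cERCC e, the cell-side
  value averages mean(g)/mean(e) over `n_permutations` (default 1000)
  random cell subsamples the size of the empty-well pool; the empty-side
  value is mean(g)/mean(e) over empty wells; the gene's noise/signal ratio
  is the mean over cERCCs of empty/cell.  The ratio-of-means form is used
  because a per-cell g/e ratio is undefined whenever a cell's spike count
  is zero, which is routine at spike-in sparsity (the per-cell variant is
  available behind a flag).  Zero cell-side with positive empty-side gives
  +∞ (removed); zero on both sides gives 0 (kept).  Subsampling is without
  replacement, keyed to sorted cell ids so results are independent of
  column order.
* **Sharp-drop threshold.**  Sorted descending on a log scale, the ratio
  distribution of a contaminated plate shows a plateau of ambient-dominated
  genes, a drop, and the bulk of well-measured genes.  The threshold is the
  geometric mean across the largest log-gap, accepted only when the gap
  spans ≥ 0.3 decades and dominates neighbouring gaps 4×; otherwise the
  99th percentile is used and flagged.  Zero ratios are excluded from the
  curve (they sit below any positive threshold and carry no information
  about the drop's location).

Filter order is cells (MAD, complexity) then genes (abundance, noise), so
gene statistics are computed on surviving cells; empty wells are dropped
after QC and play no further role.

## Normalization

Size factors are mean-1 per-cell scalars; three estimators:

* `spike_total` (default): factor ∝ ERCC total.  Preferred when spike-ins
  were added at fixed dilution, since it is content-independent.
* `median_ratio`: median over genes of count/geometric-mean reference;
  genes with a zero anywhere drop out of the reference, so this estimator
  degrades on sparse data.
* `pooled`: overlapping pools of cells (sizes {21, 41, 61}, capped at
  n−1) on a ring ordered by library size; pool factors by median ratio
  against the average cell; per-cell factors by least squares on the pool
  membership system with a mean-anchor row; non-positive solutions fall
  back to library size with a warning.

Endogenous genes and spike-ins are scaled by separate factor sets (spike
factors always come from spike totals), and a log₂(x+1) layer is stored for
clustering and testing.  Validation uses denser, lower-dispersion plates
(e.g. 250–1000 genes, libraries 4k–24k, dispersion 0.15 down to 0.005) than
the default fixture so the measured error is the estimator's, not the
irreducible count noise; at plate-realistic sparsity the content-based
estimators are visibly noisier, which is the known motivation for pooling.

## Clustering and annotation

Log layer → top 2000 genes by dispersion (variance/mean) rank → per-gene
standardization clipped at ±10 → PCA (30 components, full SVD, fixed sign
convention) → kNN graph (k = 15, Euclidean in PC space) → Leiden at
resolution 0.8 with a fixed seed.  Cells are processed in sorted-id order
and labels are relabelled C0, C1, … by decreasing size, so the assignment
is deterministic and invariant to row/column order.  Annotation scores each
cluster per type as mean expressing-cell fraction over "high" markers minus
the same over "low" markers; argmax wins, exact ties give "unassigned".
UMAP (seeded) is provided for figures only — no downstream computation may
consume the coordinates.

When TCR constant-region expression is simulated, T cells genuinely split
into α/β and γ/δ subclusters; recovery fixtures that score against the
seven type labels therefore omit those six genes.

## Marker statistics

* **Rank-sum.**  Cluster-vs-rest on the log layer, gated by min expressing
  fraction 0.1 and |log₂FC| ≥ 0.25.  Groups of ≤ 8 cells each with no ties
  use the exact permutation null; otherwise the tie-corrected normal
  approximation with continuity correction.  Family-wise (Bonferroni)
  adjustment over tested genes by default, BH optional.
* **Moderated t.**  Pooled per-gene variances s²_g on d_g df; the prior
  (d₀, s₀²) is fitted by method of moments on log s²_g (digamma/trigamma
  matching, Newton inversion of the trigamma); posterior
  s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g); t̃ on d₀+d_g df; BH adjustment.
  d₀ = 0 reduces exactly to the ordinary pooled t and d₀ = ∞ to the fully
  shrunk statistic; equal sample variances force the d₀ = ∞ branch.  The
  implementation is verified against the Bioconductor empirical-Bayes
  reference on a shared fixture (agreement to ~1e-4 relative).
  Cluster-vs-rest contrasts by default; all-pairs behind a flag.
* **Enrichment.**  One-sided hypergeometric upper tail per set, sets
  intersected with the universe first, BH across sets, significance at
  adjusted p < 10⁻³.  Gene sets are accepted in GMT format.

## Composition, TCR, panels

The subsampling test draws, per replicate, a without-replacement 50%
subsample from each cluster and computes each condition's cluster
percentages from its subsampled cells (summing to 100 across clusters);
each cluster × condition pair is compared by a two-sided Student t over the
10 replicate percentages (Welch behind a flag; no multiplicity correction
by default, BH optional).  The replicates share cells, so the test is
anti-conservative relative to a donor-level analysis; this is a property of
the procedure itself, reproduced deliberately, and the suite characterises
rather than "fixes" it.  Constant-and-equal replicate percentages give
p = 1; constant-and-unequal are flagged degenerate with p reported below
1e-15.  At fraction 1.0 the subsample is the full dataset, removing
sampling noise — there, identical cluster membership across conditions
yields p = 1 exactly.  Draws are keyed to sorted cell ids, making results
independent of cell order.

TCR lineage: ab_score = Σ normalized TRAC/TRBC1/TRBC2, gd_score = Σ
TRGC1/TRGC2/TRDC; the larger score calls the lineage, equality (including
all-zero) is unassigned.  The call compares two sums of the same cell's
values, so it is invariant to rescaling the cell.

Gene-panel aggregation (GWAS panels, cytokine heatmaps) reports mean log
expression per group, with optional per-gene z-scaling across groups for
display; missing panel genes are listed, not fatal.

## Deconvolution

Signatures are mean normalized expression over the union of the top 50
rank-sum markers per type (types need ≥ 3 cells).  Per bulk sample the
package solves min‖S·w − b‖² with w ≥ 0 on the genes shared between
signature and bulk, on the linear scale (log-space mixing is biased), then
rescales w to the simplex; the unscaled residual is reported.  This is a
single-reference NNLS; multi-reference ensemble weighting is intentionally
out of scope and the divergence is recorded in the result metadata.

## Pipeline

Stages run in the fixed order simulate/load → (demux) → QC → normalize →
cluster (→ embed) → markers → composition (→ deconvolve).  Stage seeds are
derived from the global seed by hashing the stage name, so adding a stage
never shifts another's randomness.  Every artifact is checksummed into
`manifest.json`; a stage failure halts with the stage name and keeps
completed artifacts.  The demo configuration simulates six 384-well plates
(~2,250 cells, ~2,850 genes) with every planted pathology switched on and
completes in well under a minute on one CPU; numeric artifacts are
byte-identical across reruns with the same config and seed (the history and
manifest carry timestamps and are exempt).

## Known limitations

* Gene assignment in the demultiplexer is exact 31-mer lookup against the
  synthetic transcriptome; it replaces genome alignment only for simulated
  reads.  Real data should enter as a count matrix.
* No ambient-RNA *subtraction*: contaminated genes are removed, not
  corrected.
* No batch correction, trajectory inference or label transfer.
* The sharp-drop threshold assumes a bimodal ratio distribution; on plates
  where ambient contamination grades continuously into signal it falls
  back to a percentile and should be reviewed manually.
* The composition test inherits the pseudo-replication of its published
  design; treat its p-values as descriptive, not calibrated.
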