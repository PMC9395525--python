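"""Synthetic 384-well plate generator.

Emulates the statistical structure a plate-based (SORT-seq/CEL-Seq2-style)
immune-cell experiment produces, so every downstream stage can be tested
without any external download:

* several immune cell types with planted marker genes at configured
  fold-changes, counts drawn negative-binomially with per-cell log-normal
  library-size (depth) factors;
* ERCC spike-ins at a fixed dilution, independent of cell type but scaled by
  the same technical depth factor;
* mitochondrial genes contributing a configurable fraction of the library;
* empty-well controls receiving ambient counts (a small fraction of the mean
  cell profile) plus the full spike-in profile;
* optional planted pathologies: pure-ambient genes (empty-well signal equal
  to cell signal), low-library and high-spike-in cells, and two-cell
  aggregate artifacts with inflated gene complexity;
* TCR constant-region expression in T cells split between alpha/beta and
  gamma/delta lineages;
* donors nested in the three conditions (Ctrl, CeD, GFD) with
  condition-dependent composition, and a fixed number of intraepithelial
  (IEL) wells per donor.

Everything is reproducible bit-for-bit from ``SimConfig.seed``.
"""

from __future__ import annotations

import gzip
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .experiment import Experiment

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_experiment",
    "simulate_reads",
    "default_config",
    "default_composition",
    "plate_barcodes",
    "transcript_sequence",
    "write_transcriptome",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# configuration

#: canonical immune panel: marker symbols planted per type (fold-change 8)
DEFAULT_TYPE_MARKERS: dict[str, list[str]] = {
    "T": ["CD3D", "CD3E", "CD2", "IL7R", "TRBC2"],
    "PC": ["SDC1", "CD19", "MZB1", "JCHAIN", "XBP1"],
    "MF-DC": ["ITGAX", "HLA-DRA", "CD14", "LYZ", "AIF1"],
    "MC": ["KIT", "TPSB2", "CPA3", "TPSAB1", "MS4A2"],
    "B": ["MS4A1", "CD79A", "CD79B", "BANK1", "CD37"],
    "NK": ["GNLY", "NKG7", "KLRD1", "PRF1", "KLRF1"],
    "ILC": ["KIT", "IL1R1", "RORC", "KLRB1", "AREG"],
}


def default_composition(types=None) -> dict[str, dict[str, float]]:
    """Condition → type → probability; encodes a celiac-like shift.

    Active disease (CeD) enriches T cells and depletes mast cells and
    macrophage/dendritic cells relative to controls; the gluten-free-diet
    (GFD) group sits between.
    """
    comp = {
        "Ctrl": {"T": 0.38, "PC": 0.18, "MF-DC": 0.14, "MC": 0.16,
                 "B": 0.06, "NK": 0.05, "ILC": 0.03},
        "CeD": {"T": 0.55, "PC": 0.20, "MF-DC": 0.07, "MC": 0.05,
                "B": 0.05, "NK": 0.05, "ILC": 0.03},
        "GFD": {"T": 0.46, "PC": 0.18, "MF-DC": 0.09, "MC": 0.14,
                "B": 0.05, "NK": 0.05, "ILC": 0.03},
    }
    if types is not None:
        comp = {
            cond: _renormalize({t: p for t, p in d.items() if t in types})
            for cond, d in comp.items()
        }
    return comp


def _renormalize(d: dict[str, float]) -> dict[str, float]:
    s = sum(d.values())
    return {k: v / s for k, v in d.items()}


@dataclass
class SimConfig:
    """Parameters of one synthetic experiment.

    The defaults describe the study design this simulator emulates: 384-well
    plates with a handful of reserved empty-control wells, 48 IEL wells per
    donor, donors split over three conditions, spike-ins at a fixed dilution
    and an ambient background a small fraction of the mean cell profile.
    """

    n_plates: int = 1
    wells_per_plate: int = 384
    n_empty_wells_per_plate: int = 8
    iel_wells_per_donor: int = 48
    donors_per_condition: dict = field(
        default_factory=lambda: {"Ctrl": 2, "CeD": 2, "GFD": 2})
    # type → (baseline mean scale, markers [(symbol, fold)])
    type_markers: dict = field(
        default_factory=lambda: {
            t: [(g, 8.0) for g in gs] for t, gs in DEFAULT_TYPE_MARKERS.items()
        })
    composition: dict = field(default_factory=default_composition)
    n_background_genes: int = 1500
    n_ercc: int = 24
    n_mito: int = 10
    mean_library_size: float = 3000.0
    marker_baseline_factor: float = 0.25  # marker mean outside own type, × avg
    type_profile_sigma: float = 0.25      # per-type background modulation
    ercc_dilution_scale: float = 1.0   # 1.0 models the 1:50,000 dilution
    ercc_library_fraction: float = 0.05
    mito_fraction_mean: float = 0.05
    ambient_fraction: float = 0.02
    aggregate_rate: float = 0.0
    dispersion: float = 0.3
    ercc_dispersion: float = 0.05  # spike-ins carry no biological variability
    depth_sigma: float = 0.35          # log-normal(0, sigma) depth factors
    n_ambient_genes: int = 0
    n_low_library_cells: int = 0
    low_library_scale: float = 0.1
    n_high_ercc_cells: int = 0
    high_ercc_scale: float = 5.0
    gamma_delta_fraction: float = 0.15
    include_tcr: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_empty_wells_per_plate > self.wells_per_plate:
            raise ConfigError("more empty wells than wells per plate")
        if self.wells_per_plate > 384:
            raise ConfigError("wells_per_plate exceeds 384")
        types = set(self.type_markers)
        for cond, comp in self.composition.items():
            if abs(sum(comp.values()) - 1.0) > 1e-9:
                raise ConfigError(f"composition for {cond} does not sum to 1")
            if set(comp) - types:
                raise ConfigError(f"composition for {cond} names unknown types")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def default_config(**overrides) -> SimConfig:
    """The standard 7-type immune fixture used throughout the test suite."""
    return SimConfig(**overrides)


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated experiment."""

    true_type: pd.Series          # per non-empty cell_id
    true_condition: pd.Series
    true_donor: pd.Series
    true_tcr: pd.Series           # alpha_beta / gamma_delta / none
    planted_markers: dict         # type → list of gene symbols
    ambient_genes: list           # genes whose empty-well signal == cell signal
    low_library_cells: list
    high_ercc_cells: list
    aggregate_cells: list
    depth_factors: pd.Series      # per non-empty cell_id, true technical depth
    per_read_origin: pd.DataFrame | None = None

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cells = pd.DataFrame(
            {
                "true_type": self.true_type,
                "true_condition": self.true_condition,
                "true_donor": self.true_donor,
                "true_tcr": self.true_tcr,
                "depth_factor": self.depth_factors,
                "is_aggregate": self.true_type.index.isin(self.aggregate_cells),
            }
        )
        cells.to_csv(out / "truth_cells.tsv", sep="\t", index_label="cell_id")
        pd.Series(self.ambient_genes, name="gene_id").to_csv(
            out / "truth_ambient_genes.tsv", sep="\t", index=False)
        rows = [(t, g) for t, gs in self.planted_markers.items() for g in gs]
        pd.DataFrame(rows, columns=["type", "gene_id"]).to_csv(
            out / "truth_markers.tsv", sep="\t", index=False)
        if self.per_read_origin is not None:
            self.per_read_origin.to_csv(
                out / "truth_reads.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# plate scaffolding

_BASES = np.array(list("ACGT"))


def plate_barcodes(n: int = 384) -> list[str]:
    """Deterministic whitelist of distinct 8-mer cell barcodes."""
    rng = np.random.default_rng(880384)  # fixed: barcodes are plate design
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = "".join(rng.choice(_BASES, size=8))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _well_names(n: int) -> list[str]:
    rows = "ABCDEFGHIJKLMNOP"
    return [f"{rows[i // 24]}{i % 24 + 1}" for i in range(n)]


# ---------------------------------------------------------------------------
# main generator


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion
             ) -> np.ndarray:
    """Negative binomial via gamma-Poisson; dispersion 0 degenerates to Poisson.

    ``dispersion`` may be a scalar or a per-gene array.
    """
    mean = np.clip(np.asarray(mean, float), 0.0, None)
    disp = np.broadcast_to(np.asarray(dispersion, float), mean.shape).copy()
    out = np.empty(mean.shape, dtype=np.int64)
    pois = disp <= 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    nb = ~pois
    if nb.any():
        lam = rng.gamma(1.0 / disp[nb], scale=mean[nb] * disp[nb])
        out[nb] = rng.poisson(lam)
    return out


def simulate_experiment(cfg: SimConfig) -> tuple[Experiment, SimTruth]:
    """Generate one experiment and its ground truth.

    Counts are negative binomial with per-cell depth factors; spike-ins share
    a common expected profile scaled by the same depth factor; empty wells
    receive ``ambient_fraction`` of the mean cell profile plus the full
    spike-in profile; aggregate artifacts are sums of two random cells.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    types = list(cfg.type_markers)

    # ---- gene universe -------------------------------------------------
    marker_symbols: list[str] = []
    planted: dict[str, list[str]] = {}
    for t, markers in cfg.type_markers.items():
        planted[t] = []
        for sym, _fold in markers:
            planted[t].append(sym)
            if sym not in marker_symbols:
                marker_symbols.append(sym)
    background = [f"GENE{i + 1:04d}" for i in range(cfg.n_background_genes)]
    mito = [f"MT-G{i + 1}" for i in range(cfg.n_mito)]
    tcr = ["TRAC", "TRBC1", "TRBC2", "TRGC1", "TRGC2", "TRDC"] if cfg.include_tcr else []
    marker_symbols = [m for m in marker_symbols if m not in tcr]
    ercc = [f"ERCC-{i + 1:05d}" for i in range(cfg.n_ercc)]
    symbols = marker_symbols + background + mito + tcr + ercc
    gene_ids = symbols
    genes = pd.DataFrame({"gene_id": gene_ids, "symbol": symbols})

    n_marker, n_bg, n_mito, n_tcr = (
        len(marker_symbols), len(background), len(mito), len(tcr))
    n_endo = n_marker + n_bg + n_mito + n_tcr
    n_genes = n_endo + cfg.n_ercc

    # ---- expected profiles --------------------------------------------
    # baseline endogenous means: heavy-tailed, then scaled to the target
    # library split between endogenous / mito / ERCC fractions
    base = rng.lognormal(mean=0.0, sigma=1.2, size=n_marker + n_bg)
    # planted markers sit low outside their own type so the fold-change
    # yields a clear on/off contrast, as lineage markers do in real data
    if n_marker:
        base[:n_marker] = cfg.marker_baseline_factor * base[n_marker:].mean()
    endo_budget = cfg.mean_library_size * (
        1.0 - cfg.mito_fraction_mean
        - cfg.ercc_library_fraction * cfg.ercc_dilution_scale)
    base *= endo_budget / base.sum()

    mito_means = rng.lognormal(0.0, 0.5, size=n_mito)
    mito_means *= cfg.mean_library_size * cfg.mito_fraction_mean / mito_means.sum()

    ercc_means = rng.lognormal(0.0, 1.0, size=cfg.n_ercc)
    ercc_means *= (cfg.mean_library_size * cfg.ercc_library_fraction
                   * cfg.ercc_dilution_scale / ercc_means.sum())

    # per-type mean matrix over endogenous genes (markers get the fold-change)
    sym_index = {s: i for i, s in enumerate(symbols)}
    mu = np.tile(base, (len(types), 1))          # types × (marker+bg)
    if cfg.type_profile_sigma > 0 and n_bg:
        # broad per-type expression differences beyond the planted markers,
        # as real cell types show; markers keep their exact fold-change
        mod = rng.lognormal(0.0, cfg.type_profile_sigma,
                            size=(len(types), n_bg))
        mu[:, n_marker:] *= mod
    for ti, t in enumerate(types):
        for sym, fold in cfg.type_markers[t]:
            j = sym_index.get(sym)
            if j is not None and j < n_marker + n_bg:
                mu[ti, j] *= fold

    # TCR constant-region means: only T cells express them appreciably
    tcr_ab = np.array([8.0, 6.0, 6.0, 0.05, 0.05, 0.05])  # TRAC,TRBC1,TRBC2,...
    tcr_gd = np.array([0.05, 0.05, 0.05, 6.0, 4.0, 6.0])

    # ---- well layout ----------------------------------------------------
    wells_rows = []
    donors = []
    for cond, n_d in cfg.donors_per_condition.items():
        donors += [(f"{cond}_D{i + 1}", cond) for i in range(n_d)]
    if not donors:
        raise ConfigError("at least one donor required")
    barcodes = plate_barcodes(cfg.wells_per_plate)
    well_pos = _well_names(cfg.wells_per_plate)
    donor_well_counter: dict[str, int] = {d: 0 for d, _ in donors}

    di = 0
    for p in range(cfg.n_plates):
        plate_id = f"P{p + 1}"
        empty_idx = set(
            rng.choice(cfg.wells_per_plate, size=cfg.n_empty_wells_per_plate,
                       replace=False))
        for w in range(cfg.wells_per_plate):
            cell_id = f"{plate_id}_{well_pos[w]}"
            if w in empty_idx:
                wells_rows.append(
                    (cell_id, plate_id, well_pos[w], barcodes[w], "", "Ctrl",
                     "LP", True))
                continue
            donor_id, cond = donors[di % len(donors)]
            di += 1
            k = donor_well_counter[donor_id]
            donor_well_counter[donor_id] += 1
            tissue = "IEL" if k < cfg.iel_wells_per_donor else "LP"
            wells_rows.append(
                (cell_id, plate_id, well_pos[w], barcodes[w], donor_id, cond,
                 tissue, False))
    wells = pd.DataFrame(
        wells_rows,
        columns=["cell_id", "plate_id", "well", "barcode", "donor_id",
                 "condition", "tissue", "is_empty_well"])
    is_empty = wells["is_empty_well"].to_numpy()
    cell_ids = wells["cell_id"].to_numpy()
    n_wells = len(wells)
    occ = np.flatnonzero(~is_empty)

    # ---- per-cell structure ---------------------------------------------
    type_of = np.full(n_wells, "", dtype=object)
    tcr_of = np.full(n_wells, "none", dtype=object)
    for i in occ:
        comp = cfg.composition[wells.at[i, "condition"]]
        ts, ps = zip(*comp.items())
        type_of[i] = ts[rng.choice(len(ts), p=np.asarray(ps))]
        if type_of[i] == "T" and cfg.include_tcr:
            tcr_of[i] = ("gamma_delta"
                         if rng.random() < cfg.gamma_delta_fraction
                         else "alpha_beta")

    depth = np.ones(n_wells)
    depth[occ] = rng.lognormal(0.0, cfg.depth_sigma, size=len(occ))

    low_cells = list(rng.choice(cell_ids[occ],
                                size=min(cfg.n_low_library_cells, len(occ)),
                                replace=False))
    remaining = np.setdiff1d(cell_ids[occ], low_cells)
    high_ercc_cells = list(rng.choice(remaining,
                                      size=min(cfg.n_high_ercc_cells, len(remaining)),
                                      replace=False))
    low_set, high_set = set(low_cells), set(high_ercc_cells)

    agg_mask = np.zeros(n_wells, bool)
    if cfg.aggregate_rate > 0:
        candidates = [i for i in occ if cell_ids[i] not in low_set | high_set]
        agg_pick = rng.random(len(candidates)) < cfg.aggregate_rate
        agg_mask[np.asarray(candidates)[agg_pick]] = True

    ambient_genes: list[str] = []
    if cfg.n_ambient_genes:
        # ambient contamination comes from abundant transcripts: plant pure-
        # ambient genes among above-average-expression background genes so
        # their empty-well signal is actually observable
        bg_base = base[n_marker:]
        abundant = [g for g, b in zip(background, bg_base)
                    if b >= np.mean(bg_base)]
        pool = abundant if len(abundant) >= cfg.n_ambient_genes else background
        ambient_genes = list(
            rng.choice(pool, size=min(cfg.n_ambient_genes, len(pool)),
                       replace=False))
    ambient_idx = np.array([sym_index[g] for g in ambient_genes], dtype=int)

    # ---- draw counts ----------------------------------------------------
    counts = np.zeros((n_genes, n_wells), dtype=np.int64)
    type_idx = {t: i for i, t in enumerate(types)}
    # grand mean endogenous profile across types, composition-weighted
    w_t = np.zeros(len(types))
    for comp in cfg.composition.values():
        for t, p_ in comp.items():
            w_t[type_idx[t]] += p_
    w_t /= w_t.sum()
    mean_profile = w_t @ mu

    def cell_expected(i: int) -> np.ndarray:
        """Expected counts for occupied well i over all genes."""
        d = depth[i]
        if cell_ids[i] in low_set:
            d = d * cfg.low_library_scale
        m = np.empty(n_genes)
        prof = mu[type_idx[type_of[i]]].copy()
        if len(ambient_idx):
            prof[ambient_idx] = mean_profile[ambient_idx]
        m[: n_marker + n_bg] = prof * d
        m[n_marker + n_bg: n_marker + n_bg + n_mito] = mito_means * d
        if n_tcr:
            v = {"alpha_beta": tcr_ab, "gamma_delta": tcr_gd}.get(
                tcr_of[i], np.full(6, 0.02))
            m[n_endo - n_tcr: n_endo] = v * d
        e = ercc_means * depth[i]   # spike-ins see depth but not cell content
        if cell_ids[i] in high_set:
            e = e * cfg.high_ercc_scale
        m[n_endo:] = e
        return m

    disp_vec = np.full(n_genes, cfg.dispersion)
    disp_vec[n_endo:] = cfg.ercc_dispersion
    for i in range(n_wells):
        if is_empty[i]:
            m = np.empty(n_genes)
            amb = mean_profile * cfg.ambient_fraction
            if len(ambient_idx):
                amb[ambient_idx] = mean_profile[ambient_idx]
            m[: n_marker + n_bg] = amb
            m[n_marker + n_bg: n_marker + n_bg + n_mito] = (
                mito_means * cfg.ambient_fraction)
            if n_tcr:
                m[n_endo - n_tcr: n_endo] = 0.02 * cfg.ambient_fraction
            m[n_endo:] = ercc_means
            counts[:, i] = _nb_draw(rng, m, disp_vec)
        else:
            counts[:, i] = _nb_draw(rng, cell_expected(i), disp_vec)

    # aggregates: add an independent draw of another random occupied well
    for i in np.flatnonzero(agg_mask):
        j = int(rng.choice(occ))
        counts[:, i] += _nb_draw(rng, cell_expected(j), disp_vec)

    x = Experiment(counts=sp.csr_matrix(counts), genes=genes, wells=wells)
    x.log_op("simulate_experiment", seed=cfg.seed, n_plates=cfg.n_plates,
             wells_per_plate=cfg.wells_per_plate,
             ambient_fraction=cfg.ambient_fraction)

    occ_ids = cell_ids[occ]
    truth = SimTruth(
        true_type=pd.Series(type_of[occ], index=occ_ids, name="true_type"),
        true_condition=pd.Series(
            wells["condition"].to_numpy()[occ], index=occ_ids),
        true_donor=pd.Series(wells["donor_id"].to_numpy()[occ], index=occ_ids),
        true_tcr=pd.Series(tcr_of[occ], index=occ_ids, name="true_tcr"),
        planted_markers=planted,
        ambient_genes=ambient_genes,
        low_library_cells=low_cells,
        high_ercc_cells=high_ercc_cells,
        aggregate_cells=list(cell_ids[agg_mask]),
        depth_factors=pd.Series(depth[occ], index=occ_ids, name="depth"),
    )
    return x, truth


# ---------------------------------------------------------------------------
# read-level simulation

_COMP = str.maketrans("ACGT", "TGCA")


def transcript_sequence(gene_id: str, length: int = 500) -> str:
    """Deterministic pseudo-random transcript for a gene.

    Seeded by hashing the gene id, so no FASTA fixture needs shipping and
    every caller reconstructs the identical transcriptome.
    """
    digest = hashlib.sha256(gene_id.encode()).digest()
    seed = int.from_bytes(digest[:4], "big")
    rng = np.random.default_rng(seed)
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def write_transcriptome(gene_ids, path, length: int = 500) -> None:
    with open(path, "w") as fh:
        for gid in gene_ids:
            fh.write(f">{gid}\n{transcript_sequence(gid, length)}\n")


def simulate_reads(
    x: Experiment,
    out_prefix,
    umi_length: int = 8,
    read_length: int = 75,
    duplication_rate: float = 0.0,
    error_rate: float = 0.0,
    transcript_length: int = 500,
    seed: int = 0,
) -> tuple[str, str, pd.DataFrame]:
    """Emit a paired FASTQ realisation of an experiment's count matrix.

    Every UMI count unit yields at least one read pair; PCR duplicates add
    ``Poisson(duplication_rate)`` extra copies per molecule.  Read2 carries
    the 8 nt cell barcode followed by the UMI; Read1 a random substring of
    the gene's synthetic transcript.  Returns (R1 path, R2 path, per-read
    origin table).
    """
    for bc in x.wells["barcode"]:
        if len(bc) != 8:
            raise ConfigError(f"barcode {bc!r} is not 8 nt")
    if x.wells["barcode"].duplicated().any():
        raise ConfigError(
            "barcodes are reused across plates; emit reads one plate "
            "(library) at a time, as sequencing does")
    if read_length > transcript_length:
        raise ConfigError("read_length exceeds transcript_length")
    rng = np.random.default_rng(seed)
    gene_ids = x.gene_ids
    barcodes = x.wells["barcode"].to_numpy()
    cell_ids = x.cell_ids
    transcripts = [transcript_sequence(g, transcript_length) for g in gene_ids]

    coo = x.counts.tocoo()
    r1_path = Path(f"{out_prefix}_R1.fastq.gz")
    r2_path = Path(f"{out_prefix}_R2.fastq.gz")
    origin_rows = []
    qual1 = "I" * read_length
    qual2 = "I" * (8 + umi_length)
    rid = 0
    with gzip.open(r1_path, "wt") as f1, gzip.open(r2_path, "wt") as f2:
        order = np.lexsort((coo.col, coo.row))
        for gi, ci, n in zip(coo.row[order], coo.col[order], coo.data[order]):
            n = int(n)
            if n <= 0:
                continue
            umis = _distinct_umis(rng, n, umi_length)
            tr = transcripts[gi]
            bc = barcodes[ci]
            copies = 1 + rng.poisson(duplication_rate, size=n)
            starts = rng.integers(0, transcript_length - read_length + 1,
                                  size=int(copies.sum()))
            k = 0
            for umi, c in zip(umis, copies):
                origin_rows.append(
                    (f"read{rid}", cell_ids[ci], gene_ids[gi], umi, int(c)))
                for _ in range(int(c)):
                    s = int(starts[k]); k += 1
                    r1 = tr[s: s + read_length]
                    r2 = bc + umi
                    if error_rate > 0:
                        r1 = _mutate(rng, r1, error_rate)
                        r2 = _mutate(rng, r2, error_rate)
                    f1.write(f"@read{rid}\n{r1}\n+\n{qual1}\n")
                    f2.write(f"@read{rid}\n{r2}\n+\n{qual2}\n")
                    rid += 1
    origin = pd.DataFrame(
        origin_rows, columns=["first_read_id", "cell_id", "gene_id", "umi",
                              "n_copies"])
    return str(r1_path), str(r2_path), origin


def _distinct_umis(rng: np.random.Generator, n: int, k: int) -> list[str]:
    out: set[str] = set()
    while len(out) < n:
        need = n - len(out)
        draws = rng.integers(0, 4, size=(need, k))
        for row in draws:
            out.add("".join(_BASES[row]))
            if len(out) == n:
                break
    return sorted(out)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        for i in np.flatnonzero(hit):
            alt = [b for b in "ACGT" if b != arr[i]]
            arr[i] = alt[rng.integers(0, 3)]
    return "".join(arr)
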