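"""End-to-end orchestration: simulate/load → demux → QC → normalize →
cluster → markers → composition (→ optional embedding and deconvolution),
with a YAML config, per-stage seed fan-out and a checksummed run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as _cluster
from . import composition as _composition
from . import demux as _demux
from . import markers as _markers
from . import normalize as _normalize
from . import qc as _qc
from . import simulate as _simulate
from .experiment import ValidationError
from .io import load_experiment, save_experiment

log = logging.getLogger("scplate.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed and name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


#: demo scale: six 384-well plates (~2,250 cells) and ~2,850 genes with
#: every planted pathology switched on, so one run exercises each stage
DEMO_SIMULATE: dict = {
    "n_plates": 6,
    "n_background_genes": 2800,
    "n_ambient_genes": 30,
    "aggregate_rate": 0.01,
    "n_low_library_cells": 10,
    "n_high_ercc_cells": 10,
}


@dataclass
class PipelineConfig:
    """One run's worth of parameters; exactly one input mode."""

    mode: str = "simulate"               # simulate | matrix | fastq
    output_dir: str = "scplate_run"
    seed: int = 0
    # mode=matrix
    counts_path: str | None = None
    genes_path: str | None = None
    wells_path: str | None = None
    # mode=fastq
    fastq_r1: str | None = None
    fastq_r2: str | None = None
    transcriptome: str | None = None
    max_barcode_mismatch: int = 0
    # stage blocks
    simulate: dict = field(default_factory=lambda: dict(DEMO_SIMULATE))
    qc: dict = field(default_factory=dict)
    normalize: dict = field(default_factory=lambda: {"method": "spike_total"})
    cluster: dict = field(default_factory=dict)
    markers: dict = field(default_factory=dict)
    composition: dict = field(default_factory=dict)
    embed: bool = False
    deconvolve: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def validate(self) -> None:
        if self.mode not in ("simulate", "matrix", "fastq"):
            raise ValidationError(f"unknown input mode {self.mode!r}")
        if self.mode == "matrix" and not (
                self.counts_path and self.genes_path and self.wells_path):
            raise ValidationError("matrix mode requires counts/genes/wells paths")
        if self.mode == "fastq" and not (
                self.fastq_r1 and self.fastq_r2 and self.wells_path):
            raise ValidationError("fastq mode requires fastq_r1/r2 and wells_path")


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all stages in fixed order and write artifacts + manifest.

    A stage failure halts the run with the stage name; artifacts of
    completed stages persist.  Reruns with an identical config and seed
    produce byte-identical numeric artifacts.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": [], "files": {}}
    t_all = time.time()

    def record(stage: str, t0: float) -> None:
        manifest["stages"].append(
            {"stage": stage, "seconds": round(time.time() - t0, 3)})
        log.info("stage %s done in %.1fs", stage, time.time() - t0)

    stage = "input"
    try:
        t0 = time.time()
        truth = None
        if cfg.mode == "simulate":
            sim_cfg = _simulate.SimConfig(
                **{**cfg.simulate,
                   "seed": cfg.simulate.get("seed",
                                            stage_seed(cfg.seed, "simulate"))})
            x, truth = _simulate.simulate_experiment(sim_cfg)
            truth.save(out / "truth")
            sim_cfg.to_yaml(out / "sim_config.yaml")
        elif cfg.mode == "matrix":
            x = load_experiment(cfg.counts_path, cfg.genes_path, cfg.wells_path)
        else:  # fastq
            stage = "demux"
            wells = pd.read_csv(cfg.wells_path, sep="\t", dtype=str)
            genes = _genes_from_transcriptome(cfg.transcriptome)
            whitelist = dict(zip(wells["barcode"], wells["cell_id"]))
            assignments = _demux.demultiplex_reads(
                cfg.fastq_r1, cfg.fastq_r2, whitelist, cfg.transcriptome,
                max_barcode_mismatch=cfg.max_barcode_mismatch)
            x = _demux.count_matrix_from_assignments(assignments, genes, wells)
            _demux.demux_report(x).to_csv(out / "demux_report.tsv", sep="\t",
                                          index=False)
        save_experiment(x, out / "counts_raw")
        record("input", t0)

        stage = "qc"
        t0 = time.time()
        qc_params = {"seed": stage_seed(cfg.seed, "qc"), **cfg.qc}
        filtered, report = _qc.run_qc(x, **qc_params)
        _qc.save_qc_report(report, out / "qc")
        record("qc", t0)

        stage = "normalize"
        t0 = time.time()
        sf = _normalize.compute_size_factors(filtered, **cfg.normalize)
        nx = _normalize.normalize_counts(filtered, sf)
        sf.to_frame().to_csv(out / "size_factors.tsv", sep="\t",
                             index_label="cell_id")
        save_experiment(nx, out / "counts_filtered")
        record("normalize", t0)

        stage = "cluster"
        t0 = time.time()
        cl_params = {"seed": stage_seed(cfg.seed, "cluster"), **cfg.cluster}
        clusters = _cluster.cluster_cells(nx, **cl_params)
        annotation = _cluster.annotate_clusters(nx, clusters)
        cl_out = clusters.labels.rename("cluster").to_frame()
        cl_out["cell_type"] = annotation["cell_type"].reindex(
            clusters.labels).to_numpy()
        cl_out.to_csv(out / "clusters.tsv", sep="\t", index_label="cell_id")
        annotation.to_csv(out / "cluster_annotation.tsv", sep="\t")
        record("cluster", t0)

        if cfg.embed:
            stage = "embed"
            t0 = time.time()
            coords = _cluster.embed_2d(
                nx, seed=stage_seed(cfg.seed, "embed"), pcs=clusters.pcs)
            coords.to_csv(out / "embedding.tsv", sep="\t")
            record("embed", t0)

        stage = "markers"
        t0 = time.time()
        mk = _markers.wilcoxon_markers(nx, clusters, **cfg.markers)
        mk.to_csv(out / "markers_wilcoxon.tsv", sep="\t", index=False)
        mt = _markers.moderated_t_markers(nx, clusters)
        mt.to_csv(out / "markers_moderated_t.tsv", sep="\t", index=False)
        record("markers", t0)

        stage = "composition"
        t0 = time.time()
        comp_params = {"seed": stage_seed(cfg.seed, "composition"),
                       **cfg.composition}
        comp = _composition.subsample_proportion_test(
            clusters, nx.wells, **comp_params)
        comp.percentages.to_csv(out / "composition_pct.tsv", sep="\t",
                                index=False)
        comp.tests.to_csv(out / "composition_tests.tsv", sep="\t", index=False)
        tcr = _composition.classify_tcr(nx)
        tcr.to_csv(out / "tcr_calls.tsv", sep="\t")
        record("composition", t0)

        if cfg.deconvolve:
            stage = "deconvolve"
            t0 = time.time()
            from . import deconvolve as _deconv
            sig = _deconv.build_signature(
                nx, cl_out["cell_type"])
            bulk = _pseudo_bulk(nx)
            res = _deconv.nnls_deconvolve(bulk, sig)
            sig.values.to_csv(out / "signature.tsv", sep="\t")
            res.proportions.to_csv(out / "deconv_proportions.tsv", sep="\t")
            record("deconvolve", t0)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_manifest(out, manifest)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["total_seconds"] = round(time.time() - t_all, 3)
    _write_manifest(out, manifest)
    return out


def _write_manifest(out: Path, manifest: dict) -> None:
    files = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            files[str(p.relative_to(out))] = _checksum(p)
    manifest["files"] = files
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))


def _genes_from_transcriptome(path) -> pd.DataFrame:
    import pysam

    ids = []
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            ids.append(entry.name)
    return pd.DataFrame({"gene_id": ids, "symbol": ids})


def _pseudo_bulk(nx, n_samples: int = 3) -> pd.DataFrame:
    """Condition-wise pseudo-bulk profiles from the normalized layer."""
    norm = np.asarray(nx.normalized.todense(), float)
    cols = {}
    for cond in sorted(nx.wells["condition"].unique()):
        mask = (nx.wells["condition"] == cond).to_numpy()
        if mask.sum():
            cols[cond] = norm[:, mask].mean(axis=1)
    return pd.DataFrame(cols, index=pd.Index(nx.gene_ids, name="gene_id"))
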