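"""Barcode demultiplexing, gene assignment and UMI-deduplicated counting.

Read2 carries the 8 nt cell barcode followed by the 8 nt UMI; Read1 carries
cDNA.  Genes are assigned by exact k-mer lookup against the deterministic
synthetic transcriptome (genome alignment is out of scope — real-data users
supply a count matrix instead).  Counting collapses PCR duplicates: a
molecule is one distinct (cell, gene, UMI) triple.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam
import scipy.sparse as sp

from .experiment import Experiment, FormatError, ValidationError

__all__ = [
    "ReadAssignment",
    "demultiplex_reads",
    "count_matrix_from_assignments",
    "build_kmer_index",
]

KMER = 31


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    cell_id: str | None
    gene_id: str | None
    umi: str | None
    status: str  # ok | no_barcode | no_gene | ambiguous_gene

    def __post_init__(self):
        ok = self.cell_id is not None and self.gene_id is not None
        if (self.status == "ok") != ok:
            raise ValueError("status=ok iff both cell and gene assigned")


def build_kmer_index(transcriptome_fasta, k: int = KMER) -> dict[str, object]:
    """Map each k-mer to the single gene containing it, or to the sentinel
    ``AMBIGUOUS`` when shared between genes."""
    index: dict[str, object] = {}
    with pysam.FastxFile(str(transcriptome_fasta)) as fh:
        for entry in fh:
            seq = entry.sequence.upper()
            for i in range(len(seq) - k + 1):
                kmer = seq[i: i + k]
                prev = index.get(kmer)
                if prev is None:
                    index[kmer] = entry.name
                elif prev != entry.name:
                    index[kmer] = _AMBIGUOUS
    return index


_AMBIGUOUS = object()


def _assign_gene(seq: str, index: dict, k: int) -> tuple[str | None, str]:
    """Gene for a read, scanning k-mers until one is informative."""
    seq = seq.upper()
    if len(seq) < k:
        return None, "no_gene"
    hits: set = set()
    for i in range(0, len(seq) - k + 1, k):
        hit = index.get(seq[i: i + k])
        if hit is not None:
            hits.add(hit)
    tail = index.get(seq[len(seq) - k:])
    if tail is not None:
        hits.add(tail)
    if _AMBIGUOUS in hits:
        return None, "ambiguous_gene"
    if len(hits) == 1:
        return next(iter(hits)), "ok"
    if len(hits) > 1:
        return None, "ambiguous_gene"
    return None, "no_gene"


def _hamming1_neighbors(bc: str) -> Iterator[str]:
    for i, c in enumerate(bc):
        for alt in "ACGT":
            if alt != c:
                yield bc[:i] + alt + bc[i + 1:]


def demultiplex_reads(
    fastq_r1,
    fastq_r2,
    whitelist: dict[str, str],
    transcriptome,
    max_barcode_mismatch: int = 0,
    umi_length: int = 8,
) -> Iterator[ReadAssignment]:
    """Stream read assignments from a FASTQ pair.

    Parameters
    ----------
    whitelist
        barcode → cell_id.  With ``max_barcode_mismatch=1`` a barcode is
        rescued only when exactly one whitelist entry lies within Hamming
        distance 1; ambiguous rescues are refused (``no_barcode``).
    transcriptome
        FASTA path, or a prebuilt index from :func:`build_kmer_index`.
    """
    for bc in whitelist:
        if len(bc) != 8:
            raise ValidationError(f"whitelist barcode {bc!r} is not 8 nt")
    if max_barcode_mismatch not in (0, 1):
        raise ValidationError("max_barcode_mismatch must be 0 or 1")
    index = (transcriptome if isinstance(transcriptome, dict)
             else build_kmer_index(transcriptome))

    with pysam.FastxFile(str(fastq_r1)) as f1, \
            pysam.FastxFile(str(fastq_r2)) as f2:
        it1, it2 = iter(f1), iter(f2)
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                break
            if r1 is None or r2 is None:
                raise FormatError("unpaired FASTQ files: unequal read counts")
            seq2 = r2.sequence.upper()
            if len(seq2) < 8 + umi_length:
                yield ReadAssignment(r1.name, None, None, None, "no_barcode")
                continue
            bc, umi = seq2[:8], seq2[8: 8 + umi_length]
            cell = whitelist.get(bc)
            if cell is None and max_barcode_mismatch == 1:
                rescues = {whitelist[n] for n in _hamming1_neighbors(bc)
                           if n in whitelist}
                cell = rescues.pop() if len(rescues) == 1 else None
            if cell is None:
                yield ReadAssignment(r1.name, None, None, umi, "no_barcode")
                continue
            gene, status = _assign_gene(r1.sequence, index, KMER)
            if status != "ok":
                yield ReadAssignment(r1.name, None, None, umi, status)
            else:
                yield ReadAssignment(r1.name, cell, gene, umi, "ok")


def count_matrix_from_assignments(
    assignments: Iterable[ReadAssignment],
    genes: pd.DataFrame,
    wells: pd.DataFrame,
) -> Experiment:
    """Build the UMI-deduplicated count matrix from an assignment stream.

    ``counts[g, c]`` is the number of distinct UMIs among ok-assignments for
    that (gene, cell); the dedup key is (cell, gene, UMI), so a UMI reused
    across genes is not merged.  Per-status read tallies are recorded in the
    experiment history.
    """
    genes = pd.DataFrame(genes)
    wells = pd.DataFrame(wells)
    gene_pos = {g: i for i, g in enumerate(genes["gene_id"])}
    cell_pos = {c: i for i, c in enumerate(wells["cell_id"])}
    molecules: set[tuple[str, str, str]] = set()
    tallies: Counter[str] = Counter()
    for a in assignments:
        tallies[a.status] += 1
        if a.status != "ok":
            continue
        if a.cell_id not in cell_pos:
            raise ValidationError(f"assignment names unknown cell {a.cell_id!r}")
        if a.gene_id not in gene_pos:
            raise ValidationError(f"assignment names unknown gene {a.gene_id!r}")
        molecules.add((a.cell_id, a.gene_id, a.umi))

    if molecules:
        rows = np.fromiter((gene_pos[g] for _, g, _ in molecules), dtype=np.int64)
        cols = np.fromiter((cell_pos[c] for c, _, _ in molecules), dtype=np.int64)
        counts = sp.coo_matrix(
            (np.ones(len(molecules), dtype=np.int64), (rows, cols)),
            shape=(len(genes), len(wells))).tocsr()
    else:
        counts = sp.csr_matrix((len(genes), len(wells)), dtype=np.int64)
    x = Experiment(counts=counts, genes=genes, wells=wells)
    x.log_op("count_matrix_from_assignments",
             n_read_pairs=int(sum(tallies.values())),
             **{f"reads_{k}": int(v) for k, v in sorted(tallies.items())})
    return x


def demux_report(x: Experiment) -> pd.DataFrame:
    """Per-status read tallies recorded at counting time, as a tidy table."""
    for entry in reversed(x.history):
        if entry["operation"] == "count_matrix_from_assignments":
            params = entry["parameters"]
            rows = [(k.removeprefix("reads_"), v) for k, v in params.items()
                    if k.startswith("reads_")]
            return pd.DataFrame(rows, columns=["status", "n_reads"])
    raise ValidationError("experiment history holds no demultiplexing record")
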