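"""Reference-set construction rules and RPKM normalization.

Deterministic, pure-function counterparts of the assembly-side steps: length
filtering of assembled contigs, selection of the longest contigs per genome
bin (top-1 for the protein-prior reference, top-200 for the abundance
reference), and the reads-per-kilobase-per-million arithmetic applied to
per-contig mapped-read counts.  Producing the read counts themselves (mapping)
is out of scope; they are consumed as tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ContigRecord",
    "ReferenceSet",
    "filter_short_contigs",
    "select_top_per_bin",
    "compute_rpkm",
    "read_contigs_fasta",
    "read_bin_assignments",
    "read_counts_tsv",
]

MIN_CONTIG_LENGTH = 500  # bp; contigs shorter than this are removed (>= kept)


@dataclass(frozen=True)
class ContigRecord:
    """One assembled contig with its genome-bin assignment."""

    contig_id: str
    length_bp: int
    bin_id: str
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"contig {self.contig_id}: length must be >= 1 bp")
        if self.sequence is not None and len(self.sequence) != self.length_bp:
            raise ValueError(
                f"contig {self.contig_id}: sequence length {len(self.sequence)} "
                f"!= declared {self.length_bp}"
            )


@dataclass
class ReferenceSet:
    """Ordered contig selection with per-bin provenance."""

    contig_ids: list[str] = field(default_factory=list)
    by_bin: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.contig_ids)) != len(self.contig_ids):
            raise ValueError("reference set contains duplicate contig ids")

    def __len__(self) -> int:
        return len(self.contig_ids)


def filter_short_contigs(
    contigs: Iterable[ContigRecord], min_len: int = MIN_CONTIG_LENGTH
) -> list[ContigRecord]:
    """Keep contigs of length >= ``min_len`` (inclusive boundary), order preserved."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [c for c in contigs if c.length_bp >= min_len]


def select_top_per_bin(contigs: Sequence[ContigRecord], k: int) -> ReferenceSet:
    """Select the k longest contigs of each bin (all if a bin holds fewer).

    Within a bin contigs are ranked by length descending; equal lengths are
    broken by contig id ascending so the reference set is identical across
    runs.  Bins are emitted in ascending bin-id order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    bins: dict[str, list[ContigRecord]] = {}
    for c in contigs:
        bins.setdefault(c.bin_id, []).append(c)
    by_bin: dict[str, list[str]] = {}
    ordered: list[str] = []
    for bin_id in sorted(bins):
        ranked = sorted(bins[bin_id], key=lambda c: (-c.length_bp, c.contig_id))
        chosen = [c.contig_id for c in ranked[:k]]
        by_bin[bin_id] = chosen
        ordered.extend(chosen)
    return ReferenceSet(ordered, by_bin)


def compute_rpkm(
    read_counts: Sequence[float] | np.ndarray,
    contig_lengths_bp: Sequence[int] | np.ndarray,
    total_mapped_reads: int,
) -> np.ndarray:
    """Reads per kilobase of contig per million mapped reads.

    rpkm_i = count_i / ((length_i / 1e3) * (total_mapped_reads / 1e6))
    """
    counts = np.asarray(read_counts, dtype=float)
    lengths = np.asarray(contig_lengths_bp, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("read_counts and contig_lengths_bp differ in length")
    if np.any(counts < 0):
        raise ValueError("read counts must be non-negative")
    if np.any(lengths <= 0):
        raise ValueError("contig lengths must be positive")
    if total_mapped_reads < 1:
        raise ValueError("total_mapped_reads must be >= 1")
    return counts / ((lengths / 1e3) * (total_mapped_reads / 1e6))


# ---------------------------------------------------------------------------
# file plumbing


def read_contigs_fasta(
    fasta_path: str | Path, bin_assignments: dict[str, str]
) -> list[ContigRecord]:
    """Load contig records from FASTA, joining bin ids from a mapping.

    Contigs without a bin assignment are skipped (unbinned contigs never enter
    a reference set).
    """
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in bin_assignments:
            records.append(
                ContigRecord(rec.id, len(rec.seq), bin_assignments[rec.id], str(rec.seq))
            )
    return records


def read_bin_assignments(path: str | Path) -> dict[str, str]:
    """Two-column TSV (contig_id, bin_id) -> mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = ["contig_id", "bin_id"]
    return dict(zip(df["contig_id"], df["bin_id"]))


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Per-contig mapped-read counts, one column per sample, indexed by contig id."""
    return pd.read_csv(path, sep="\t", index_col=0)
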