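"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based, half-open intervals on an explicit
strand.  GTF input (1-based, closed) is converted at the I/O boundary and
never leaks into these types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

STRANDS = ("+", "-")

CONSTITUTIVE = "constitutive"
ALTERNATIVE = "alternative"

EVENT_TYPES = ("SE", "MXE", "A5SS", "A3SS", "RI")

#: Responsiveness classes for alternative-splicing events under knockout.
CLASS_ENHANCED = "enhanced"
CLASS_REPRESSED = "repressed"
CLASS_UNRESPONSIVE = "unresponsive"
EVENT_CLASSES = (CLASS_ENHANCED, CLASS_REPRESSED, CLASS_UNRESPONSIVE)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        """True if the two intervals share >= min_bp bases on the same
        chromosome and strand."""
        if self.chrom != other.chrom or self.strand != other.strand:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_bp


@dataclass
class GeneModel:
    """One transcript of one gene: ordered exons with constitutive /
    alternative labels.

    Exons are stored in genomic order (ascending start); on the '-' strand
    transcription order is the reverse of genomic order and is derived via
    :meth:`exons_tx_order`, never stored.  ``cds`` optionally carries CDS
    intervals (genomic order) so exonic peak categories can be split into
    5'UTR / CDS / 3'UTR.
    """

    gene_id: str
    transcript_id: str
    biotype: str
    interval: GenomicInterval
    exons: list[GenomicInterval]
    exon_labels: list[str] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        if not self.exon_labels:
            self.exon_labels = [CONSTITUTIVE] * len(self.exons)
        if len(self.exon_labels) != len(self.exons):
            raise ValueError("exon_labels length must match exons")
        for lab in self.exon_labels:
            if lab not in (CONSTITUTIVE, ALTERNATIVE):
                raise ValueError(f"bad exon label {lab!r}")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = None
        for e in self.exons:
            if e.chrom != self.interval.chrom or e.strand != self.interval.strand:
                raise ValueError("exon chrom/strand disagrees with transcript")
            if e.start < self.interval.start or e.end > self.interval.end:
                raise ValueError("exon outside transcript interval")
            if prev_end is not None and e.start < prev_end:
                raise ValueError("overlapping exons in one transcript")
            prev_end = e.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    def exons_tx_order(self) -> list[GenomicInterval]:
        """Exons in transcription order (reversed genomic order on '-')."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def introns(self) -> list[GenomicInterval]:
        """Introns in genomic order (empty for single-exon transcripts)."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    def junctions(self) -> list[tuple[int, str]]:
        """Internal exon/intron junction coordinates in genomic order.

        Returns (position, kind) pairs where kind is ``exon_intron`` (5'ss,
        donor) or ``intron_exon`` (3'ss, acceptor) in transcription
        orientation.  A junction coordinate p separates base p-1 from base p.
        """
        out: list[tuple[int, str]] = []
        n = len(self.exons)
        for i, e in enumerate(self.exons):
            if i > 0:
                out.append((e.start, "intron_exon" if self.strand == "+" else "exon_intron"))
            if i < n - 1:
                out.append((e.end, "exon_intron" if self.strand == "+" else "intron_exon"))
        return sorted(out)


@dataclass(frozen=True)
class Peak:
    """An eCLIP cluster from a single library, with enrichment statistics
    against the size-matched input."""

    interval: GenomicInterval
    library_id: str
    neg_log10_p: float
    fold_enrichment: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.neg_log10_p < 0:
            raise ValueError("neg_log10_p must be >= 0")
        if self.fold_enrichment < 0:
            raise ValueError("fold_enrichment must be >= 0")


@dataclass
class MergedPeak:
    """A replicate-consensus peak: the union span of a connected overlap
    component supported by >= min_support distinct libraries."""

    interval: GenomicInterval
    support: int
    source_ids: list[tuple[str, GenomicInterval]]


class CoverageTrack:
    """Dense per-base read depth, one vector per (chromosome, strand)."""

    def __init__(self, chrom_sizes: Mapping[str, int]):
        self.chrom_sizes = dict(chrom_sizes)
        self._data: dict[tuple[str, str], np.ndarray] = {}

    def _key(self, chrom: str, strand: str) -> tuple[str, str]:
        if chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if strand not in STRANDS:
            raise ValueError(f"invalid strand {strand!r}")
        return (chrom, strand)

    def get(self, chrom: str, strand: str) -> np.ndarray:
        key = self._key(chrom, strand)
        if key not in self._data:
            self._data[key] = np.zeros(self.chrom_sizes[chrom], dtype=np.int64)
        return self._data[key]

    def add_record(self, chrom: str, start: int, end: int, depth: int, strand: str) -> None:
        if end > self.chrom_sizes.get(chrom, -1):
            raise ValueError(
                f"record {chrom}:{start}-{end} beyond chromosome length "
                f"{self.chrom_sizes.get(chrom)}"
            )
        if depth < 0:
            raise ValueError("depth must be >= 0")
        self.get(chrom, strand)[start:end] += depth

    def window(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        """Depth over [start, end), zero-padded implicitly by clipping the
        request to the chromosome; the caller handles truncation."""
        arr = self.get(chrom, strand)
        return arr[max(start, 0):min(end, len(arr))]

    def total(self) -> int:
        return int(sum(int(v.sum()) for v in self._data.values()))

    def keys(self) -> list[tuple[str, str]]:
        return sorted(self._data.keys())


@dataclass
class SpliceEvent:
    """One alternative-splicing event with per-condition PSI replicates.

    ``delta_psi`` follows the knockout-minus-wild-type convention:
    mean(PSI condition 2) - mean(PSI condition 1).  Flanking exons are given
    in transcription order (upstream = transcribed first).
    """

    event_id: str
    gene_id: str
    event_type: str
    alt_exon: GenomicInterval
    upstream_const_exon: GenomicInterval
    downstream_const_exon: GenomicInterval
    psi_per_sample: dict[str, list[float]]
    delta_psi: float
    fdr: float
    second_alt_exon: GenomicInterval | None = None  # MXE only

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if abs(self.delta_psi) > 1 + 1e-9:
            raise ValueError("|delta_psi| must be <= 1")
        if not (0 <= self.fdr <= 1):
            raise ValueError("fdr must be in [0, 1]")
        for cond, vals in self.psi_per_sample.items():
            for v in vals:
                if not (0 <= v <= 1):
                    raise ValueError(f"PSI {v} outside [0,1] in condition {cond!r}")
        for flank in (self.upstream_const_exon, self.downstream_const_exon):
            if flank.overlaps(self.alt_exon):
                raise ValueError("flanking exon overlaps the alternative exon")

    @property
    def chrom(self) -> str:
        return self.alt_exon.chrom

    @property
    def strand(self) -> str:
        return self.alt_exon.strand


@dataclass(frozen=True)
class GOAssociation:
    gene_id: str
    term_id: str
    term_name: str = ""


def longest_protein_coding(models: Iterable[GeneModel]) -> GeneModel | None:
    """Host-transcript selection rule: prefer protein_coding biotype, then
    the longest transcript span, then lexicographically smallest
    transcript_id."""
    models = list(models)
    if not models:
        return None
    return min(
        models,
        key=lambda m: (
            0 if m.biotype == "protein_coding" else 1,
            -len(m.interval),
            m.transcript_id,
        ),
    )
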