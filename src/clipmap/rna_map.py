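"""Splice-site-anchored RNA binding maps.

Implements boundary selection from peaks, per-base input-normalised
metagene density around 5' and 3' splice sites, class-stratified composite
binned maps between flanking constitutive exons, and replicate
reproducibility of coverage tracks.

Offset conventions (transcription orientation on both strands):

* 5'ss (exon|intron): offsets run -exon_window .. +intron_window-1 with
  offset 0 the first intronic base and offset -1 the last exonic base.
* 3'ss (intron|exon): offsets run -intron_window .. +exon_window-1 with
  offset 0 the first exonic base and offset -1 the last intronic base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .models import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    MergedPeak,
    SpliceEvent,
    longest_protein_coding,
)

logger = logging.getLogger(__name__)

KIND_5SS = "exon_intron"
KIND_3SS = "intron_exon"


@dataclass(frozen=True)
class Boundary:
    """One exon/intron junction selected for profiling.

    ``position`` is the junction coordinate (0-based, separating base
    position-1 from base position).  ``tx_span`` carries the host
    transcript's span so windows can be truncated at gene ends.
    """

    kind: str
    chrom: str
    position: int
    strand: str
    gene_id: str
    transcript_id: str
    tx_span: tuple[int, int]


def select_boundaries(
    merged_peaks: list[MergedPeak],
    gene_models: list[GeneModel],
) -> list[Boundary]:
    """Select the splice-site boundaries a peak set interrogates.

    For each peak (host transcript = longest protein-coding transcript
    overlapping it) the selected set is the union of

    1. junctions covered by the peak (strictly inside its span), and
    2. for each peak terminal, the nearest junction not covered by the
       peak, in each direction along the transcript.

    A peak running from inside exon 3 to inside intron 4 of a 6-exon gene
    therefore yields five boundaries, intron2|exon3 through intron4|exon5.
    Peaks overlapping no transcript are skipped (count logged).
    """
    by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for m in gene_models:
        by_key.setdefault((m.chrom, m.strand), []).append(m)

    selected: set[Boundary] = set()
    skipped = 0
    for peak in merged_peaks:
        iv = peak.interval
        host = longest_protein_coding(
            m for m in by_key.get((iv.chrom, iv.strand), []) if m.interval.overlaps(iv)
        )
        if host is None:
            skipped += 1
            continue
        junctions = host.junctions()
        if not junctions:
            continue
        chosen: set[tuple[int, str]] = set()
        for pos, kind in junctions:
            if iv.start < pos < iv.end:
                chosen.add((pos, kind))
        upstream = [(p, k) for p, k in junctions if p <= iv.start]
        downstream = [(p, k) for p, k in junctions if p >= iv.end]
        if upstream:
            chosen.add(max(upstream))
        if downstream:
            chosen.add(min(downstream))
        for pos, kind in chosen:
            selected.add(
                Boundary(
                    kind=kind,
                    chrom=host.chrom,
                    position=pos,
                    strand=host.strand,
                    gene_id=host.gene_id,
                    transcript_id=host.transcript_id,
                    tx_span=(host.interval.start, host.interval.end),
                )
            )
    if skipped:
        logger.info("select_boundaries: %d peaks had no host transcript", skipped)
    return sorted(selected, key=lambda b: (b.chrom, b.position, b.kind, b.transcript_id))


@dataclass
class BoundaryProfile:
    """Aggregated per-offset counts and input-normalised relative density
    around one boundary kind."""

    kind: str
    offsets: np.ndarray
    sample_counts: np.ndarray
    control_counts: np.ndarray
    relative_density: np.ndarray
    n_boundaries: int = 0

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "offset": self.offsets,
                "sample_count": self.sample_counts,
                "control_count": self.control_counts,
                "relative_density": self.relative_density,
            }
        )


def _boundary_offset_bases(b: Boundary, offsets: np.ndarray) -> np.ndarray:
    """Genomic base index for each transcription-orientation offset."""
    if b.strand == "+":
        return b.position + offsets
    return b.position - 1 - offsets


def _offsets_for(kind: str, exon_window: int, intron_window: int) -> np.ndarray:
    if kind == KIND_5SS:
        return np.arange(-exon_window, intron_window)
    return np.arange(-intron_window, exon_window)


def boundary_density(
    boundaries: list[Boundary],
    ip_track: CoverageTrack,
    input_track: CoverageTrack,
    exon_window: int = 100,
    intron_window: int = 300,
    epsilon: float = 1.0,
) -> tuple[BoundaryProfile, BoundaryProfile]:
    """Per-base metagene density around 5'ss and 3'ss boundaries.

    For every boundary the IP and input depth over the window (exon_window
    exonic bases, intron_window intronic bases, transcription orientation)
    are summed per offset across boundaries; the relative density is the
    elementwise ratio (sample + epsilon) / (control + epsilon).  Windows
    are truncated at the host transcript span and at chromosome ends, so
    truncated boundaries contribute only their defined offsets.

    Returns the (5'ss profile, 3'ss profile) pair.
    """
    if not boundaries:
        raise ValueError("empty boundary list")

    profiles = {}
    for kind in (KIND_5SS, KIND_3SS):
        offsets = _offsets_for(kind, exon_window, intron_window)
        sample = np.zeros(len(offsets), dtype=np.float64)
        control = np.zeros(len(offsets), dtype=np.float64)
        n = 0
        for b in (x for x in boundaries if x.kind == kind):
            n += 1
            bases = _boundary_offset_bases(b, offsets)
            lo, hi = b.tx_span
            chrom_len = ip_track.chrom_sizes[b.chrom]
            ok = (bases >= max(lo, 0)) & (bases < min(hi, chrom_len))
            if not ok.any():
                continue
            ip = ip_track.get(b.chrom, b.strand)
            inp = input_track.get(b.chrom, b.strand)
            sample[ok] += ip[bases[ok]]
            control[ok] += inp[bases[ok]]
        density = (sample + epsilon) / (control + epsilon)
        profiles[kind] = BoundaryProfile(
            kind=kind,
            offsets=offsets,
            sample_counts=sample,
            control_counts=control,
            relative_density=density,
            n_boundaries=n,
        )
    return profiles[KIND_5SS], profiles[KIND_3SS]


@dataclass
class CompositeMap:
    """Binned occupancy between the two flanking constitutive exons of a
    set of events of one responsiveness class."""

    event_class: str
    n_bins: int
    occupancy: np.ndarray
    n_events: int
    n_skipped: int = 0
    window_definition: str = "upstream constitutive exon 5'ss -> downstream constitutive exon 3'ss"
    #: per-event transcription-orientation fraction of the alternative
    #: exon's 3'ss within the window (diagnostic for anchoring plots)
    alt_3ss_fraction: list[float] = field(default_factory=list)


def _event_window(ev: SpliceEvent) -> tuple[int, int]:
    """Genomic [start, end) between the flanking constitutive exons
    (boundary-to-boundary, excluding their bodies)."""
    if ev.strand == "+":
        return ev.upstream_const_exon.end, ev.downstream_const_exon.start
    return ev.downstream_const_exon.end, ev.upstream_const_exon.start


def composite_map(
    merged_peaks: list[MergedPeak],
    events_by_class: dict[str, list[SpliceEvent]],
    n_bins: int = 100,
    bin_mode: str = "fractional",
    weighted: bool = False,
) -> list[CompositeMap]:
    """Class-stratified composite occupancy maps.

    Per event the window runs from the upstream constitutive exon's 5'ss to
    the downstream constitutive exon's 3'ss (transcription orientation) and
    is split into ``n_bins`` equal-width bins ("fractional" mode) or into
    ``n_bins`` fixed 100-bp bins anchored at the upstream boundary
    ("fixed100bp" mode).  A bin is occupied for an event iff >= 1 peak base
    overlaps it (or, with ``weighted``, contributes the covered fraction of
    the bin); occupancy is the fraction of the class's events occupying the
    bin.  Fractional-mode events with windows shorter than ``n_bins`` bases
    are skipped and counted.
    """
    if bin_mode not in ("fractional", "fixed100bp"):
        raise ValueError(f"unknown bin_mode {bin_mode!r}")

    peaks_by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for m in merged_peaks:
        peaks_by_key.setdefault((m.interval.chrom, m.interval.strand), []).append(
            (m.interval.start, m.interval.end)
        )
    for lst in peaks_by_key.values():
        lst.sort()

    out = []
    for cls, events in events_by_class.items():
        occ = np.zeros(n_bins, dtype=np.float64)
        denom = np.zeros(n_bins, dtype=np.float64)
        n_used = 0
        n_skipped = 0
        fracs = []
        for ev in events:
            win_start, win_end = _event_window(ev)
            length = win_end - win_start
            if length <= 0:
                n_skipped += 1
                continue
            if bin_mode == "fractional":
                if length < n_bins:
                    n_skipped += 1
                    continue
                edges = np.linspace(win_start, win_end, n_bins + 1)
                valid = np.ones(n_bins, dtype=bool)
            else:
                edges = win_start + 100.0 * np.arange(n_bins + 1)
                valid = edges[1:] <= win_end
            lo, hi = edges[:-1].copy(), edges[1:].copy()
            if ev.strand == "-":
                # transcription runs right to left: bin 0 abuts the upstream
                # exon which sits at the genomic *end* of the window
                if bin_mode == "fractional":
                    lo, hi = (win_start + win_end) - hi, (win_start + win_end) - lo
                else:
                    lo = win_end - 100.0 * np.arange(1, n_bins + 1)
                    hi = win_end - 100.0 * np.arange(n_bins)
                    valid = lo >= win_start
            covered = np.zeros(n_bins, dtype=np.float64)
            for ps, pe in peaks_by_key.get((ev.chrom, ev.strand), []):
                if pe <= win_start or ps >= win_end:
                    continue
                ov = np.minimum(hi, pe) - np.maximum(lo, ps)
                # merged peaks are disjoint, so summing per-peak coverage is
                # exact; clip guards the degenerate gap-joined case
                covered += np.clip(ov / (hi - lo), 0, 1)
            covered = np.clip(covered, 0, 1)
            contrib = covered if weighted else (covered > 0).astype(float)
            occ[valid] += contrib[valid]
            denom[valid] += 1
            n_used += 1
            anchor = ev.alt_exon.start if ev.strand == "+" else ev.alt_exon.end
            frac = (anchor - win_start) / length if ev.strand == "+" else (win_end - anchor) / length
            fracs.append(float(frac))
        with np.errstate(invalid="ignore"):
            occupancy = np.where(denom > 0, occ / np.maximum(denom, 1), 0.0)
        out.append(
            CompositeMap(
                event_class=cls,
                n_bins=n_bins,
                occupancy=occupancy,
                n_events=n_used,
                n_skipped=n_skipped,
                alt_3ss_fraction=fracs,
            )
        )
    return out


def replicate_correlation(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    min_depth: int = 3,
) -> tuple[float, int]:
    """Pearson correlation of log2 read depth at positions where both
    tracks exceed ``min_depth`` (strict), the standard eCLIP replicate
    reproducibility measure.  Returns (r, number of positions)."""
    if set(track_a.chrom_sizes) != set(track_b.chrom_sizes):
        raise ValueError("tracks cover different chromosome sets")
    xs, ys = [], []
    for chrom in sorted(track_a.chrom_sizes):
        for strand in ("+", "-"):
            a = track_a.get(chrom, strand)
            b = track_b.get(chrom, strand)
            mask = (a > min_depth) & (b > min_depth)
            if mask.any():
                xs.append(a[mask])
                ys.append(b[mask])
    if not xs:
        raise ValueError("no positions exceed the depth threshold in both tracks")
    x = np.log2(np.concatenate(xs).astype(float))
    y = np.log2(np.concatenate(ys).astype(float))
    n = len(x)
    if n < 3:
        raise ValueError(f"only {n} qualifying positions; correlation undefined")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in log2 depths; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, n
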