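"""High-confidence filtering, replicate-consensus merging, and genic
annotation of eCLIP peaks.

The consensus rule follows the two-step strategy used for reproducible
eCLIP clusters: a cluster is kept only when peaks from at least
``min_support`` distinct libraries share overlapping regions, and all
peaks chained by overlap are retained and combined into one merged span.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .models import (
    GeneModel,
    GenomicInterval,
    MergedPeak,
    Peak,
    longest_protein_coding,
)

#: genic categories in assignment precedence order (highest first)
CATEGORY_PRECEDENCE = [
    "exon_intron_junction",
    "CDS_exon",
    "5'UTR",
    "3'UTR",
    "exon",          # exonic fallback when the annotation carries no CDS
    "noncoding_exon",
    "intron",
    "intergenic",
]


def filter_high_confidence(
    peaks: list[Peak],
    p_threshold: float = 1e-3,
    fold_threshold: float = 5.0,
    fold_strict: bool = False,
) -> list[Peak]:
    """Keep peaks with p <= p_threshold and fold enrichment over input of
    at least (or, with ``fold_strict``, strictly more than) fold_threshold.

    Input order is preserved.  Defaults reproduce the high-confidence
    criterion p <= 1e-3 and >= 5-fold versus the size-matched input.
    """
    if p_threshold <= 0 or fold_threshold < 0:
        raise ValueError("thresholds must be positive")
    min_neg_log10_p = -math.log10(p_threshold)
    out = []
    for pk in peaks:
        if pk.neg_log10_p < min_neg_log10_p:
            continue
        if fold_strict:
            if pk.fold_enrichment <= fold_threshold:
                continue
        elif pk.fold_enrichment < fold_threshold:
            continue
        out.append(pk)
    return out


def merge_replicate_peaks(
    peak_lists: list[list[Peak]],
    min_support: int = 2,
    min_overlap_bp: int = 1,
    join_gap: int = 0,
) -> list[MergedPeak]:
    """2-of-N replicate consensus merging.

    Builds connected components of same-chromosome, same-strand peaks
    (pooled across all libraries) under >= ``min_overlap_bp`` overlap,
    keeps components supported by >= ``min_support`` distinct libraries,
    and emits one merged peak per kept component spanning
    min(start)..max(end).  ``join_gap`` > 0 additionally unions merged
    intervals closer than that many bases (redundancy elimination for
    gap-joined dialects; with the default 0 the merged intervals are
    disjoint by construction).
    """
    if len(peak_lists) < 2:
        raise ValueError("consensus merging needs >= 2 libraries")
    pooled: list[Peak] = [pk for lst in peak_lists for pk in lst]
    pooled.sort(key=lambda p: (p.interval.chrom, p.interval.strand, p.interval.start, p.interval.end))

    merged: list[MergedPeak] = []
    component: list[Peak] = []
    comp_end = None

    def flush() -> None:
        if not component:
            return
        libs = {p.library_id for p in component}
        if len(libs) >= min_support:
            iv = GenomicInterval(
                component[0].interval.chrom,
                min(p.interval.start for p in component),
                max(p.interval.end for p in component),
                component[0].interval.strand,
            )
            merged.append(
                MergedPeak(
                    interval=iv,
                    support=len(libs),
                    source_ids=[(p.library_id, p.interval) for p in component],
                )
            )

    for pk in pooled:
        iv = pk.interval
        if component and (
            iv.chrom != component[0].interval.chrom
            or iv.strand != component[0].interval.strand
            or iv.start > comp_end - min_overlap_bp
        ):
            flush()
            component = []
            comp_end = None
        component.append(pk)
        comp_end = iv.end if comp_end is None else max(comp_end, iv.end)
    flush()

    merged.sort(key=lambda m: (m.interval.chrom, m.interval.start, m.interval.end, m.interval.strand))

    if join_gap > 0:
        joined: list[MergedPeak] = []
        for m in merged:
            last = joined[-1] if joined else None
            if (
                last is not None
                and m.interval.chrom == last.interval.chrom
                and m.interval.strand == last.interval.strand
                and m.interval.start <= last.interval.end + join_gap
            ):
                last.interval = GenomicInterval(
                    last.interval.chrom,
                    last.interval.start,
                    max(last.interval.end, m.interval.end),
                    last.interval.strand,
                )
                last.source_ids.extend(m.source_ids)
                last.support = len({lib for lib, _ in last.source_ids})
            else:
                joined.append(m)
        merged = joined
    return merged


@dataclass
class GenicAnnotation:
    peak: MergedPeak
    category: str
    gene_id: str | None


def _host_transcript(iv: GenomicInterval, models: list[GeneModel]) -> GeneModel | None:
    hits = [m for m in models if m.interval.overlaps(iv)]
    return longest_protein_coding(hits)


def _categorize(iv: GenomicInterval, model: GeneModel) -> str:
    """Assign the highest-precedence category the peak's bases touch on the
    host transcript."""
    touched: set[str] = set()
    exonic = [e for e in model.exons if e.overlaps(iv)]
    intronic = [i for i in model.introns() if i.overlaps(iv)]
    if exonic and intronic:
        touched.add("exon_intron_junction")
    # peak sticking out of the transcript across a terminal exon edge is
    # exon/flank, not a splice junction: only internal junctions qualify
    if exonic:
        if model.biotype != "protein_coding":
            touched.add("noncoding_exon")
        elif model.cds:
            cds_start = min(c.start for c in model.cds)
            cds_end = max(c.end for c in model.cds)
            for e in exonic:
                s, e_ = max(e.start, iv.start), min(e.end, iv.end)
                # classify the overlapped exonic bases against the CDS span
                if s < cds_end and e_ > cds_start:
                    touched.add("CDS_exon")
                if s < cds_start:
                    touched.add("5'UTR" if model.strand == "+" else "3'UTR")
                if e_ > cds_end:
                    touched.add("3'UTR" if model.strand == "+" else "5'UTR")
        else:
            touched.add("exon")
    if intronic:
        touched.add("intron")
    if not touched:
        return "intergenic"
    for cat in CATEGORY_PRECEDENCE:
        if cat in touched:
            return cat
    return "intergenic"


def annotate_peaks(
    merged: list[MergedPeak],
    gene_models: list[GeneModel],
) -> list[GenicAnnotation]:
    """Assign each merged peak exactly one genic category.

    The host transcript is the longest protein-coding transcript among
    those overlapping the peak (ties: longest span, then lexicographic
    transcript id); peaks overlapping no transcript are intergenic.
    Category precedence: exon_intron_junction > CDS_exon > 5'UTR > 3'UTR >
    noncoding_exon > intron > intergenic; without CDS features the exonic
    categories collapse to plain "exon".
    """
    out = []
    for m in merged:
        host = _host_transcript(m.interval, gene_models)
        if host is None:
            out.append(GenicAnnotation(peak=m, category="intergenic", gene_id=None))
        else:
            out.append(
                GenicAnnotation(peak=m, category=_categorize(m.interval, host), gene_id=host.gene_id)
            )
    return out


def annotation_summary(annotations: list[GenicAnnotation]):
    """Counts and percentages per genic category (pie-chart table)."""
    import pandas as pd

    counts: dict[str, int] = {}
    for a in annotations:
        counts[a.category] = counts.get(a.category, 0) + 1
    total = sum(counts.values())
    rows = [
        {"category": c, "count": n, "percent": round(100.0 * n / total, 1)}
        for c, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["category", "count", "percent"])
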