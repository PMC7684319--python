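"""Readers and writers for every external format the pipeline touches.

One coordinate convention everywhere: 0-based, half-open.  GTF (1-based,
closed) is converted at this boundary; BED-family inputs are taken as
already 0-based half-open.

Formats:

* GTF (Gencode-style attributes) -> :class:`~clipmap.models.GeneModel`
* BED6+2 peaks: chrom, start, end, name, score(=-log10 p), strand,
  fold_enrichment[, raw_p]
* stranded bedGraph coverage (one file per strand)
* splice-event tables: rMATS ``SE.MATS.JC.txt``-style per-type columns,
  or a documented "simple" unified TSV
* GAF 2.x gene-GO associations
* FASTA genome sequence
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

from .models import (
    ALTERNATIVE,
    CONSTITUTIVE,
    CoverageTrack,
    GOAssociation,
    GeneModel,
    GenomicInterval,
    Peak,
    SpliceEvent,
)

# --------------------------------------------------------------------------
# GTF

_GTF_FEATURES = {"gene", "transcript", "exon", "CDS"}


def _validate_gtf_lines(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}: malformed GTF line {lineno}: expected 9 tab-separated fields")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed GTF line {lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise ValueError(f"{path}: malformed GTF line {lineno}: bad coordinate range {start}-{end}")
            if fields[6] not in ("+", "-", "."):
                raise ValueError(f"{path}: malformed GTF line {lineno}: bad strand {fields[6]!r}")


def read_gtf(path: str | Path, alt_exon_labels: dict[str, set[int]] | None = None) -> list[GeneModel]:
    """Load transcript models from a GTF file.

    Coordinates are converted to 0-based half-open (pyranges does this on
    read: a 1-based closed exon [101, 200] becomes start=100, end=200).
    Exons are grouped by transcript and sorted by genomic start; CDS
    features, when present, are captured so UTR/CDS categories can be
    resolved downstream.

    Parameters
    ----------
    alt_exon_labels:
        Optional sidecar ``{transcript_id: {exon indices (genomic order)}}``
        marking alternative exons.  GTF itself carries no such labels, so
        every exon defaults to constitutive.
    """
    _validate_gtf_lines(path)
    df = pr.read_gtf(str(path)).df
    if df.empty:
        return []
    biotype_col = next(
        (c for c in ("gene_biotype", "gene_type", "transcript_biotype") if c in df.columns),
        None,
    )
    models: list[GeneModel] = []
    tx_rows = df[df.Feature == "transcript"]
    exon_rows = df[df.Feature == "exon"]
    cds_rows = df[df.Feature == "CDS"] if (df.Feature == "CDS").any() else None
    exons_by_tx = dict(tuple(exon_rows.groupby("transcript_id", sort=False)))
    cds_by_tx = dict(tuple(cds_rows.groupby("transcript_id", sort=False))) if cds_rows is not None else {}

    # transcripts may be declared only implicitly through their exons
    if tx_rows.empty:
        tx_iter = (
            (tid, grp.iloc[0], grp.Start.min(), grp.End.max())
            for tid, grp in exons_by_tx.items()
        )
    else:
        tx_iter = (
            (row.transcript_id, row, row.Start, row.End)
            for row in tx_rows.itertuples()
        )

    for tid, row, tx_start, tx_end in tx_iter:
        if tid not in exons_by_tx:
            raise ValueError(f"transcript {tid!r} has zero exons")
        grp = exons_by_tx[tid].sort_values("Start")
        strand = grp.Strand.iloc[0]
        chrom = str(grp.Chromosome.iloc[0])
        exons = [
            GenomicInterval(chrom, int(s), int(e), strand)
            for s, e in zip(grp.Start, grp.End)
        ]
        labels = [CONSTITUTIVE] * len(exons)
        if alt_exon_labels and tid in alt_exon_labels:
            for idx in alt_exon_labels[tid]:
                labels[idx] = ALTERNATIVE
        cds = []
        if tid in cds_by_tx:
            cg = cds_by_tx[tid].sort_values("Start")
            cds = [
                GenomicInterval(chrom, int(s), int(e), strand)
                for s, e in zip(cg.Start, cg.End)
            ]
        biotype = str(getattr(row, biotype_col)) if biotype_col else ""
        models.append(
            GeneModel(
                gene_id=str(row.gene_id),
                transcript_id=str(tid),
                biotype=biotype,
                interval=GenomicInterval(chrom, int(tx_start), int(tx_end), strand),
                exons=exons,
                exon_labels=labels,
                cds=cds,
            )
        )
    return models


def write_gtf(models: Sequence[GeneModel], path: str | Path) -> None:
    """Emit transcript/exon/CDS features with Gencode-style attributes
    (1-based closed coordinates on write)."""
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda m: (m.chrom, m.interval.start, m.transcript_id)):
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; gene_biotype "{m.biotype}";'
            def line(feature: str, iv: GenomicInterval) -> str:
                return (
                    f"{iv.chrom}\tclipmap\t{feature}\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{iv.strand}\t.\t{attrs}\n"
                )
            fh.write(line("transcript", m.interval))
            for e in m.exons:
                fh.write(line("exon", e))
            for c in m.cds:
                fh.write(line("CDS", c))


# --------------------------------------------------------------------------
# Peaks (BED6+2)

def read_peaks(path: str | Path, library_id: str) -> list[Peak]:
    """Read a BED6+2 peak table: chrom, start, end, name, score(=-log10 p),
    strand, fold_enrichment[, raw_p].  Coordinates are BED-standard 0-based
    half-open and taken as-is."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 7:
                raise ValueError(f"{path}: line {lineno}: expected >=7 BED6+2 fields")
            chrom, start, end, name, score, strand, fold = f[:7]
            start, end = int(start), int(end)
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start >= end")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: line {lineno}: unknown strand {strand!r}")
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end, strand),
                    library_id=library_id,
                    neg_log10_p=float(score),
                    fold_enrichment=float(fold),
                    name=name,
                )
            )
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))):
            name = p.name or f"pk{i + 1}"
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t{name}\t"
                f"{p.neg_log10_p:g}\t{p.interval.strand}\t{p.fold_enrichment:g}\n"
            )


# --------------------------------------------------------------------------
# Coverage (stranded bedGraph: one file per strand)

def read_coverage(
    plus_path: str | Path,
    minus_path: str | Path,
    chrom_sizes: dict[str, int],
) -> CoverageTrack:
    """Read stranded per-base coverage from two bedGraph files.

    Bases not covered by any record are 0; overlapping records sum.
    A record extending beyond the declared chromosome length is an error.
    """
    track = CoverageTrack(chrom_sizes)
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        if not Path(path).exists():
            raise FileNotFoundError(f"missing bedGraph for strand {strand}: {path}")
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.split()
                if len(f) < 4:
                    raise ValueError(f"{path}: line {lineno}: expected 4 bedGraph fields")
                chrom, start, end, depth = f[0], int(f[1]), int(f[2]), int(round(float(f[3])))
                try:
                    track.add_record(chrom, start, end, depth, strand)
                except (ValueError, KeyError) as exc:
                    raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return track


def write_coverage(track: CoverageTrack, plus_path: str | Path, minus_path: str | Path) -> None:
    """Write a CoverageTrack as two run-length-encoded bedGraph files
    (zero runs omitted)."""
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        with open(path, "w") as fh:
            for chrom in sorted(track.chrom_sizes):
                arr = track.get(chrom, strand)
                if arr.sum() == 0:
                    continue
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(arr)]))
                for s, e in zip(starts, ends):
                    d = int(arr[s])
                    if d:
                        fh.write(f"{chrom}\t{s}\t{e}\t{d}\n")


# --------------------------------------------------------------------------
# Splice events

SIMPLE_EVENT_COLUMNS = [
    "event_id", "gene_id", "event_type", "chrom", "strand",
    "alt_start", "alt_end", "up_start", "up_end", "down_start", "down_end",
    "psi_cond1", "psi_cond2", "delta_psi", "fdr",
]


def _parse_psi_list(text: str) -> list[float]:
    vals = [float(x) for x in str(text).split(",") if x not in ("", "NA")]
    for v in vals:
        if not (0 <= v <= 1):
            raise ValueError(f"PSI value {v} outside [0, 1]")
    return vals


def _check_delta(computed: float, file_value: float, event_id: str) -> None:
    if abs(computed - file_value) > 1e-6:
        raise ValueError(
            f"event {event_id}: file delta_psi {file_value} disagrees with "
            f"recomputed mean(cond2)-mean(cond1) = {computed:.6g}"
        )


def read_splice_events(path: str | Path, dialect: str = "simple") -> list[SpliceEvent]:
    """Read an alternative-splicing event table.

    dialect "simple": the documented unified TSV (header
    ``SIMPLE_EVENT_COLUMNS``); psi columns are comma-separated replicate
    lists.  dialect "rmats": rMATS ``*.MATS.JC.txt`` per-type column names
    (event type inferred from the columns present).  delta_psi is always
    recomputed as mean(cond2) - mean(cond1) and checked against the file's
    value to 1e-6 where one is present (for rMATS the file value is
    ``-IncLevelDifference``, since rMATS reports mean1 - mean2).
    """
    if dialect in ("simple", "simple-tsv"):
        return _read_simple_events(path)
    if dialect == "rmats":
        return _read_rmats_events(path)
    if dialect == "majiq":
        raise ValueError(
            "MAJIQ LSVs have no canonical binary-event reduction; export them "
            "to the simple-tsv dialect instead"
        )
    raise ValueError(f"unknown events dialect {dialect!r}")


def _read_simple_events(path: str | Path) -> list[SpliceEvent]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SIMPLE_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    events = []
    for row in df.itertuples():
        psi1, psi2 = _parse_psi_list(row.psi_cond1), _parse_psi_list(row.psi_cond2)
        delta = float(np.mean(psi2) - np.mean(psi1))
        _check_delta(delta, float(row.delta_psi), row.event_id)
        mk = lambda s, e: GenomicInterval(row.chrom, int(s), int(e), row.strand)
        events.append(
            SpliceEvent(
                event_id=row.event_id,
                gene_id=row.gene_id,
                event_type=row.event_type,
                alt_exon=mk(row.alt_start, row.alt_end),
                upstream_const_exon=mk(row.up_start, row.up_end),
                downstream_const_exon=mk(row.down_start, row.down_end),
                psi_per_sample={"cond1": psi1, "cond2": psi2},
                delta_psi=delta,
                fdr=float(row.fdr),
            )
        )
    return events


def _read_rmats_events(path: str | Path) -> list[SpliceEvent]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = set(df.columns)
    if {"exonStart_0base", "exonEnd"} <= cols:
        etype = "SE"
    elif {"1stExonStart_0base", "2ndExonStart_0base"} <= cols:
        etype = "MXE"
    elif {"riExonStart_0base", "riExonEnd"} <= cols:
        etype = "RI"
    elif {"longExonStart_0base", "shortES"} <= cols:
        etype = "A5SS" if "A5SS" in str(path) else "A3SS"
    else:
        raise ValueError(f"{path}: unrecognized rMATS column layout")
    events = []
    for rec in df.to_dict("records"):
        chrom, strand = rec["chr"], rec["strand"]
        mk = lambda s, e: GenomicInterval(chrom, int(s), int(e), strand)
        up = mk(rec["upstreamES"], rec["upstreamEE"])
        down = mk(rec["downstreamES"], rec["downstreamEE"])
        second = None
        if etype == "SE":
            alt = mk(rec["exonStart_0base"], rec["exonEnd"])
        elif etype == "MXE":
            alt = mk(rec["1stExonStart_0base"], rec["1stExonEnd"])
            second = mk(rec["2ndExonStart_0base"], rec["2ndExonEnd"])
        elif etype == "RI":
            # the retained intron itself: between the flanking exons
            alt = mk(rec["upstreamEE"], rec["downstreamES"])
        else:  # A5SS / A3SS: the variable region between long and short forms
            long_s, long_e = int(rec["longExonStart_0base"]), int(rec["longExonEnd"])
            short_s, short_e = int(rec["shortES"]), int(rec["shortEE"])
            if (long_s, long_e) == (short_s, short_e):
                raise ValueError(f"{path}: degenerate A5SS/A3SS event {rec['ID']}")
            s, e = (short_e, long_e) if long_e != short_e else (long_s, short_s)
            alt = mk(min(s, e), max(s, e))
        psi1 = _parse_psi_list(rec["IncLevel1"])
        psi2 = _parse_psi_list(rec["IncLevel2"])
        delta = float(np.mean(psi2) - np.mean(psi1))
        _check_delta(delta, -float(rec["IncLevelDifference"]), str(rec["ID"]))
        # transcription order: rMATS upstream/downstream are genomic on '+'
        if strand == "-":
            up, down = down, up
        events.append(
            SpliceEvent(
                event_id=f"{etype}_{rec['ID']}",
                gene_id=str(rec["GeneID"]).strip('"'),
                event_type=etype,
                alt_exon=alt,
                upstream_const_exon=up,
                downstream_const_exon=down,
                psi_per_sample={"cond1": psi1, "cond2": psi2},
                delta_psi=delta,
                fdr=float(rec["FDR"]),
                second_alt_exon=second,
            )
        )
    return events


def write_splice_events(events: Sequence[SpliceEvent], path: str | Path) -> None:
    """Write events in the simple unified TSV dialect."""
    rows = []
    for ev in events:
        # delta must stay consistent with the 6-decimal replicate values
        psi1 = [round(v, 6) for v in ev.psi_per_sample["cond1"]]
        psi2 = [round(v, 6) for v in ev.psi_per_sample["cond2"]]
        delta = float(np.mean(psi2) - np.mean(psi1))
        rows.append({
            "event_id": ev.event_id,
            "gene_id": ev.gene_id,
            "event_type": ev.event_type,
            "chrom": ev.chrom,
            "strand": ev.strand,
            "alt_start": ev.alt_exon.start,
            "alt_end": ev.alt_exon.end,
            "up_start": ev.upstream_const_exon.start,
            "up_end": ev.upstream_const_exon.end,
            "down_start": ev.downstream_const_exon.start,
            "down_end": ev.downstream_const_exon.end,
            "psi_cond1": ",".join(f"{v:.6f}" for v in psi1),
            "psi_cond2": ",".join(f"{v:.6f}" for v in psi2),
            "delta_psi": f"{delta:.6f}",
            "fdr": f"{ev.fdr:.6g}",
        })
    pd.DataFrame(rows, columns=SIMPLE_EVENT_COLUMNS).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# GAF

def read_gaf(path: str | Path) -> list[GOAssociation]:
    """Read a GAF 2.x gene-GO association file.

    Column positions per the GAF standard: DB object symbol is column 3,
    GO ID column 5 (1-based).  Duplicate (gene, term) pairs collapse to one
    association.  GAF carries no term names; term_name is set to the term id.
    """
    seen: dict[tuple[str, str], GOAssociation] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 15:
                raise ValueError(f"{path}: line {lineno}: GAF 2.x needs >=15 columns, got {len(f)}")
            gene, term = f[2], f[4]
            key = (gene, term)
            if key not in seen:
                seen[key] = GOAssociation(gene_id=gene, term_id=term, term_name=term)
    return list(seen.values())


def write_gaf(associations: Sequence[GOAssociation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for a in sorted(set((a.gene_id, a.term_id) for a in associations)):
            gene, term = a
            f = ["SIM", gene, gene, "", term, "SIM:0000", "IEA", "", "P",
                 "", "", "gene", "taxon:10090", "20200101", "SIM"]
            fh.write("\t".join(f) + "\n")


# --------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (small) FASTA file into a name -> sequence dict."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence before header")
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


# --------------------------------------------------------------------------
# Generic tables

def write_table(records: pd.DataFrame | Iterable[dict], path: str | Path, sort_by: list[str] | None = None) -> None:
    """Write a deterministic TSV: column order preserved, rows optionally
    sorted, floats at 6 significant digits."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if sort_by:
        df = df.sort_values(sort_by, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", quoting=csv.QUOTE_MINIMAL)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
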