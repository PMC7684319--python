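"""Synthetic study-like inputs with planted, parameterised structure.

Generates multi-exon gene models on both strands with canonical GT..AG
introns and consensus-like splice sites, four eCLIP peak libraries with a
planted positional preference near splice sites, IP/input coverage with
Poisson noise and fold enrichment under peaks, alternative-splicing event
tables with enhanced/repressed/unresponsive classes at a set effect size,
and GO / protein-complex fixtures with one planted enriched term and one
planted shifted complex.  Every generator is deterministic for a fixed
config seed (one RNG substream per generator at a stable offset).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .models import (
    ALTERNATIVE,
    CLASS_ENHANCED,
    CLASS_REPRESSED,
    CLASS_UNRESPONSIVE,
    CONSTITUTIVE,
    CoverageTrack,
    GOAssociation,
    GeneModel,
    GenomicInterval,
    MergedPeak,
    Peak,
    SpliceEvent,
)
from .splice import reverse_complement

# stable RNG substream offsets, one per generator
_ANNOTATION, _PEAKS, _COVERAGE, _EVENTS, _GO, _COMPLEXES, _DEGRADE = range(1, 8)

REGION_EXON_BODY = "exon_body"
REGION_UPSTREAM_5SS = "within_50nt_upstream_of_5ss"
REGION_DOWNSTREAM_3SS = "within_25nt_downstream_of_3ss"
REGION_DEEP_INTRON = "deep_intron"
REGIONS = (REGION_EXON_BODY, REGION_UPSTREAM_5SS, REGION_DOWNSTREAM_3SS, REGION_DEEP_INTRON)

#: exon-side extents of the splice-site-proximal placement regions
UPSTREAM_5SS_NT = 50
DOWNSTREAM_3SS_NT = 25

DONOR_CONSENSUS = "CAGGTAAGT"            # exon last 3 | intron first 6; GT fixed
DONOR_FIXED = (3, 4)
ACCEPTOR_CONSENSUS = "T" * 17 + "CAG" + "GCC"  # intron last 20 | exon first 3; AG fixed
ACCEPTOR_FIXED = (18, 19)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Ranges are inclusive (lo, hi) tuples.  ``positional_model`` gives the
    probability that a planted binding site falls in each region class;
    the splice-site-proximal regions mirror the observed enrichment within
    ~50 nt upstream of the 5'ss and ~25 nt downstream of the 3'ss.
    """

    seed: int = 0
    # annotation
    n_genes: int = 100
    exons_per_gene: tuple[int, int] = (5, 8)
    exon_len: tuple[int, int] = (80, 220)
    intron_len: tuple[int, int] = (250, 1200)
    utr_len: int = 20
    gene_gap: int = 400
    genes_per_chrom: int = 50
    alt_exon_fraction: float = 1.0
    ss_mismatch_rate: float = 0.1
    # peaks
    n_libraries: int = 4
    peaks_per_library: int = 400
    peak_width: tuple[int, int] = (30, 80)
    jitter: int = 8
    detect_prob: float = 1.0
    frac_low_confidence: float = 0.2
    positional_model: dict = field(
        default_factory=lambda: {
            REGION_EXON_BODY: 0.20,
            REGION_UPSTREAM_5SS: 0.35,
            REGION_DOWNSTREAM_3SS: 0.25,
            REGION_DEEP_INTRON: 0.20,
        }
    )
    # coverage
    enrichment_fold: float = 5.0
    background_rate: float = 2.0
    # events
    class_fractions: dict = field(
        default_factory=lambda: {
            CLASS_ENHANCED: 0.3,
            CLASS_REPRESSED: 0.3,
            CLASS_UNRESPONSIVE: 0.4,
        }
    )
    effect_size_dpsi: float = 0.3
    psi_noise_sd: float = 0.02
    n_replicates: int = 2
    # GO
    go_n_terms: int = 30
    go_term_prob: float = 0.08
    go_list_size: int = 30
    go_relative_risk: float = 5.0
    # complexes
    n_proteins: int = 200
    n_complexes: int = 20
    complex_size: tuple[int, int] = (3, 10)
    planted_complex_size: int = 8
    planted_shift: float = 2.0

    def __post_init__(self) -> None:
        for name in ("exons_per_gene", "exon_len", "intron_len", "peak_width", "complex_size"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"empty or invalid range {name}={getattr(self, name)}")
        if abs(sum(self.positional_model.values()) - 1.0) > 1e-9:
            raise ValueError("positional_model probabilities must sum to 1")
        if set(self.positional_model) - set(REGIONS):
            raise ValueError(f"unknown region in positional_model: {set(self.positional_model) - set(REGIONS)}")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if self.enrichment_fold <= 0 or self.background_rate < 0:
            raise ValueError("enrichment_fold must be > 0 and background_rate >= 0")
        if self.exons_per_gene[0] < 3:
            raise ValueError("genes need >= 3 exons for an internal alternative exon")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def _rng(config: SimulationConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng((config.seed * 10 + offset) % (2 ** 31))


def _sample_site(consensus: str, fixed: tuple[int, ...], rate: float, rng: np.random.Generator) -> str:
    out = []
    for i, base in enumerate(consensus):
        if i not in fixed and rng.random() < rate:
            out.append("ACGT"[(("ACGT".index(base)) + rng.integers(1, 4)) % 4])
        else:
            out.append(base)
    return "".join(out)


# --------------------------------------------------------------------------
# Annotation + genome

def simulate_annotation(config: SimulationConfig) -> tuple[list[GeneModel], dict[str, str]]:
    """Simulate gene models and a matching genome sequence.

    Genes are laid out left to right along chromosomes (``genes_per_chrom``
    per chromosome, alternating strand), each with one internal exon
    labelled alternative in a ``alt_exon_fraction`` of genes.  Every intron
    carries canonical GT..AG dinucleotides on the transcribed strand and
    consensus-like donor/acceptor context with per-position mismatch
    probability ``ss_mismatch_rate``.
    """
    if config.intron_len[0] < 30:
        raise ValueError("intron_len must be >= 30 (splice-site windows need room)")
    rng = _rng(config, _ANNOTATION)
    models: list[GeneModel] = []
    cursors: dict[str, int] = {}
    margin = 1000
    for g in range(config.n_genes):
        chrom = f"chr{g // config.genes_per_chrom + 1}"
        cursor = cursors.get(chrom, margin)
        strand = "+" if g % 2 == 0 else "-"
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_len[0], config.exon_len[1] + 1, size=n_exons)
        intron_lens = rng.integers(config.intron_len[0], config.intron_len[1] + 1, size=n_exons - 1)
        exons = []
        pos = cursor
        for i in range(n_exons):
            exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[i]), strand))
            pos += int(exon_lens[i])
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        interval = GenomicInterval(chrom, cursor, pos, strand)
        labels = [CONSTITUTIVE] * n_exons
        if rng.random() < config.alt_exon_fraction:
            alt_idx = int(rng.integers(1, n_exons - 1))  # internal, genomic order
            labels[alt_idx] = ALTERNATIVE
        gene_id = f"gene{g + 1:04d}"
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=f"{gene_id}.t1",
                biotype="protein_coding",
                interval=interval,
                exons=exons,
                exon_labels=labels,
                cds=_derive_cds(exons, config.utr_len),
            )
        )
        cursors[chrom] = pos + config.gene_gap
    genome = _simulate_genome(models, cursors, config, rng, margin)
    return models, genome


def _derive_cds(exons: list[GenomicInterval], utr_len: int) -> list[GenomicInterval]:
    """CDS = exonic bases minus utr_len from each transcript end.  The
    trimmed exonic span is the same set of genomic positions on either
    strand, so the computation is strand-free."""
    total = sum(len(e) for e in exons)
    lo_t, hi_t = utr_len, total - utr_len
    if lo_t >= hi_t:
        return []
    cds = []
    cum = 0
    for e in exons:
        a, b = max(cum, lo_t), min(cum + len(e), hi_t)
        if a < b:
            cds.append(GenomicInterval(e.chrom, e.start + (a - cum), e.start + (b - cum), e.strand))
        cum += len(e)
    return cds


def _simulate_genome(
    models: list[GeneModel],
    cursors: dict[str, int],
    config: SimulationConfig,
    rng: np.random.Generator,
    margin: int,
) -> dict[str, str]:
    sizes = {c: cursors[c] + margin for c in cursors}
    genome: dict[str, np.ndarray] = {
        c: rng.choice(np.array(list("ACGT")), size=n) for c, n in sorted(sizes.items())
    }
    for m in models:
        seq = genome[m.chrom]
        for intron in m.introns():
            if m.strand == "+":
                donor_j, acceptor_j = intron.start, intron.end
                _write(seq, donor_j - 3, _sample_site(DONOR_CONSENSUS, DONOR_FIXED, config.ss_mismatch_rate, rng))
                _write(seq, acceptor_j - 20, _sample_site(ACCEPTOR_CONSENSUS, ACCEPTOR_FIXED, config.ss_mismatch_rate, rng))
            else:
                donor_j, acceptor_j = intron.end, intron.start
                _write(seq, donor_j - 6, reverse_complement(_sample_site(DONOR_CONSENSUS, DONOR_FIXED, config.ss_mismatch_rate, rng)))
                _write(seq, acceptor_j - 3, reverse_complement(_sample_site(ACCEPTOR_CONSENSUS, ACCEPTOR_FIXED, config.ss_mismatch_rate, rng)))
    return {c: "".join(a) for c, a in genome.items()}


def _write(seq: np.ndarray, start: int, text: str) -> None:
    seq[start:start + len(text)] = list(text)


def chrom_sizes_of(genome: dict[str, str]) -> dict[str, int]:
    return {c: len(s) for c, s in genome.items()}


# --------------------------------------------------------------------------
# Peaks

def _place_in_region(start: int, end: int, width_range: tuple[int, int], rng) -> tuple[int, int] | None:
    length = end - start
    if length < 5:
        return None
    w = int(rng.integers(width_range[0], width_range[1] + 1))
    w = min(w, length)
    s = int(rng.integers(start, end - w + 1))
    return s, s + w


def _region_interval(model: GeneModel, region: str, rng) -> tuple[int, int] | None:
    """Genomic [start, end) of one sampled instance of a placement region."""
    tx = model.exons_tx_order()
    if region == REGION_EXON_BODY:
        e = tx[int(rng.integers(0, len(tx)))]
        return e.start, e.end
    if region == REGION_UPSTREAM_5SS:
        e = tx[int(rng.integers(0, len(tx) - 1))]  # any exon with a donor
        if model.strand == "+":
            return max(e.start, e.end - UPSTREAM_5SS_NT), e.end
        return e.start, min(e.end, e.start + UPSTREAM_5SS_NT)
    if region == REGION_DOWNSTREAM_3SS:
        e = tx[int(rng.integers(1, len(tx)))]  # any exon with an acceptor
        if model.strand == "+":
            return e.start, min(e.end, e.start + DOWNSTREAM_3SS_NT)
        return max(e.start, e.end - DOWNSTREAM_3SS_NT), e.end
    if region == REGION_DEEP_INTRON:
        introns = model.introns()
        i = introns[int(rng.integers(0, len(introns)))]
        pad = 300
        if len(i) > 2 * pad + 50:
            return i.start + pad, i.end - pad
        third = len(i) // 3
        return i.start + third, i.end - third
    raise ValueError(f"unknown region {region!r}")


def simulate_peaks(
    models: list[GeneModel],
    config: SimulationConfig,
) -> dict[str, list[Peak]]:
    """Simulate per-library peak tables with a planted positional model.

    ``peaks_per_library`` true binding sites are drawn (gene, then region
    by ``positional_model``, then uniform placement inside it); each
    library observes each site with probability ``detect_prob``, shifted
    by a uniform jitter in [-jitter, +jitter].  A ``frac_low_confidence``
    fraction of sites carries statistics failing the high-confidence
    filter (p or fold below threshold).  With jitter 0 and detect_prob 1
    all libraries are identical.
    """
    rng = _rng(config, _PEAKS)
    region_names = list(config.positional_model)
    region_p = np.array([config.positional_model[r] for r in region_names])

    truth: list[tuple[GenomicInterval, float, float]] = []
    for t in range(config.peaks_per_library):
        placed = None
        for _ in range(100):
            model = models[int(rng.integers(0, len(models)))]
            region = region_names[int(rng.choice(len(region_names), p=region_p))]
            span = _region_interval(model, region, rng)
            if span is None:
                continue
            placed = (model, _place_in_region(span[0], span[1], config.peak_width, rng))
            if placed[1] is not None:
                break
        if placed is None or placed[1] is None:
            raise RuntimeError("could not place a peak after 100 tries")
        model, (s, e) = placed
        if rng.random() < config.frac_low_confidence:
            if rng.random() < 0.5:
                neg_log10_p = float(rng.uniform(0.0, 2.9))
                fold = float(rng.uniform(5.01, 12.0))
            else:
                neg_log10_p = float(rng.uniform(3.1, 9.0))
                fold = float(rng.uniform(0.5, 4.9))
        else:
            neg_log10_p = float(rng.uniform(3.1, 9.0))
            fold = float(rng.uniform(5.01, 12.0))
        truth.append((GenomicInterval(model.chrom, s, e, model.strand), neg_log10_p, fold))

    libraries: dict[str, list[Peak]] = {}
    for lib_idx in range(config.n_libraries):
        lib_id = f"lib{lib_idx + 1}"
        lst = []
        for t, (iv, nlp, fold) in enumerate(truth):
            if rng.random() >= config.detect_prob:
                continue
            shift = int(rng.integers(-config.jitter, config.jitter + 1)) if config.jitter else 0
            s = max(0, iv.start + shift)
            lst.append(
                Peak(
                    interval=GenomicInterval(iv.chrom, s, s + len(iv), iv.strand),
                    library_id=lib_id,
                    neg_log10_p=nlp,
                    fold_enrichment=fold,
                    name=f"true{t + 1}",
                )
            )
        libraries[lib_id] = lst
    return libraries


def simulate_class_peaks(
    models: list[GeneModel],
    events: list[SpliceEvent],
    planted_classes: dict[str, str],
    config: SimulationConfig,
    target_classes: tuple[str, ...] = (CLASS_ENHANCED, CLASS_REPRESSED),
    upstream_nt: int = 60,
    downstream_nt: int = 20,
    peaks_per_event: int = 1,
) -> dict[str, list[Peak]]:
    """Plant peaks around the alternative exon's 3'ss of events in the
    target classes (the position-dependent binding pattern of a splicing
    regulator acting at the acceptor side), for composite-map recovery.

    The placement window runs ``upstream_nt`` intronic bases before to
    ``downstream_nt`` exonic bases after the alternative 3'ss in
    transcription orientation.
    """
    rng = _rng(config, _PEAKS)
    truth: list[GenomicInterval] = []
    for ev in events:
        if planted_classes.get(ev.event_id) not in target_classes:
            continue
        for _ in range(peaks_per_event):
            if ev.strand == "+":
                span = (ev.alt_exon.start - upstream_nt, ev.alt_exon.start + downstream_nt)
            else:
                span = (ev.alt_exon.end - downstream_nt, ev.alt_exon.end + upstream_nt)
            placed = _place_in_region(span[0], span[1], config.peak_width, rng)
            if placed:
                truth.append(GenomicInterval(ev.chrom, placed[0], placed[1], ev.strand))
    libraries: dict[str, list[Peak]] = {}
    for lib_idx in range(config.n_libraries):
        lib_id = f"lib{lib_idx + 1}"
        lst = []
        for t, iv in enumerate(truth):
            shift = int(rng.integers(-config.jitter, config.jitter + 1)) if config.jitter else 0
            s = max(0, iv.start + shift)
            lst.append(
                Peak(
                    interval=GenomicInterval(iv.chrom, s, s + len(iv), iv.strand),
                    library_id=lib_id,
                    neg_log10_p=float(rng.uniform(3.1, 9.0)),
                    fold_enrichment=float(rng.uniform(5.01, 12.0)),
                    name=f"target{t + 1}",
                )
            )
        libraries[lib_id] = lst
    return libraries


# --------------------------------------------------------------------------
# Coverage

def simulate_coverage(
    models: list[GeneModel],
    truth_peaks: list[MergedPeak] | list[Peak],
    config: SimulationConfig,
    chrom_sizes: dict[str, int] | None = None,
    stream: int = 0,
) -> tuple[CoverageTrack, CoverageTrack]:
    """Simulate (IP, input) coverage tracks.

    Input depth is Poisson(background_rate) per base on both strands; IP
    depth is Poisson(background_rate x enrichment_fold) under the given
    peaks and Poisson(background_rate) elsewhere.  ``stream`` selects an
    independent replicate draw (e.g. a second IP library) at the same
    parameters.
    """
    rng = np.random.default_rng((config.seed * 10 + _COVERAGE + 1009 * stream) % (2 ** 31))
    if chrom_sizes is None:
        chrom_sizes = {}
        for m in models:
            chrom_sizes[m.chrom] = max(chrom_sizes.get(m.chrom, 0), m.interval.end + 1000)
    ip = CoverageTrack(chrom_sizes)
    inp = CoverageTrack(chrom_sizes)
    peak_ivs = [p.interval for p in truth_peaks]
    by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in peak_ivs:
        by_key.setdefault((iv.chrom, iv.strand), []).append(iv)
    for chrom in sorted(chrom_sizes):
        n = chrom_sizes[chrom]
        for strand in ("+", "-"):
            rate = np.full(n, float(config.background_rate))
            for iv in by_key.get((chrom, strand), []):
                rate[iv.start:min(iv.end, n)] = config.background_rate * config.enrichment_fold
            if config.background_rate > 0:
                ip.get(chrom, strand)[:] = rng.poisson(rate)
                inp.get(chrom, strand)[:] = rng.poisson(np.full(n, float(config.background_rate)))
    return ip, inp


# --------------------------------------------------------------------------
# Events

def simulate_events(
    models: list[GeneModel],
    config: SimulationConfig,
) -> tuple[list[SpliceEvent], dict[str, str]]:
    """Simulate one skipped-exon event per gene with an alternative exon.

    Each event is assigned a planted class by ``class_fractions``;
    enhanced events get delta-PSI +effect_size, repressed -effect_size,
    unresponsive 0, each with per-replicate Gaussian noise (values clipped
    to [0, 1]); delta_psi is the replicate-mean difference by
    construction.  FDR is < 0.05 for responsive and uniform(0.05, 1) for
    unresponsive events.

    Returns (events, planted class per event_id) so recovery against the
    ground truth can be scored.
    """
    rng = _rng(config, _EVENTS)
    classes = sorted(config.class_fractions)
    probs = np.array([config.class_fractions[c] for c in classes])
    events: list[SpliceEvent] = []
    planted: dict[str, str] = {}
    for m in models:
        if ALTERNATIVE not in m.exon_labels:
            continue
        tx = m.exons_tx_order()
        labels_tx = m.exon_labels if m.strand == "+" else list(reversed(m.exon_labels))
        alt_i = labels_tx.index(ALTERNATIVE)
        alt, up, down = tx[alt_i], tx[alt_i - 1], tx[alt_i + 1]
        cls = classes[int(rng.choice(len(classes), p=probs))]
        effect = {
            CLASS_ENHANCED: config.effect_size_dpsi,
            CLASS_REPRESSED: -config.effect_size_dpsi,
            CLASS_UNRESPONSIVE: 0.0,
        }[cls]
        base = float(rng.uniform(0.35, 0.65))
        wt = np.clip(base + rng.normal(0, config.psi_noise_sd, config.n_replicates), 0, 1)
        ko = np.clip(base + effect + rng.normal(0, config.psi_noise_sd, config.n_replicates), 0, 1)
        if cls == CLASS_UNRESPONSIVE:
            fdr = float(rng.uniform(0.05, 1.0))
        else:
            fdr = float(rng.uniform(1e-8, 0.0499))
        event_id = f"SE_{m.gene_id}"
        events.append(
            SpliceEvent(
                event_id=event_id,
                gene_id=m.gene_id,
                event_type="SE",
                alt_exon=alt,
                upstream_const_exon=up,
                downstream_const_exon=down,
                psi_per_sample={"cond1": [float(v) for v in wt], "cond2": [float(v) for v in ko]},
                delta_psi=float(ko.mean() - wt.mean()),
                fdr=fdr,
            )
        )
        planted[event_id] = cls
    return events, planted


def degrade_splice_sites(
    genome: dict[str, str],
    events: list[SpliceEvent],
    planted_classes: dict[str, str],
    config: SimulationConfig,
    factor: float = 2.0,
    target_classes: tuple[str, ...] = (CLASS_ENHANCED, CLASS_REPRESSED),
) -> dict[str, str]:
    """Re-plant the alternative exon's 3'ss of responsive events with a
    ``factor``-fold higher consensus mismatch rate (weaker acceptor), the
    sequence feature distinguishing regulator-responsive exons.  The AG
    dinucleotide stays fixed, so intron boundaries remain canonical."""
    arrs = {c: np.array(list(s)) for c, s in genome.items()}
    rng = _rng(config, _DEGRADE)
    rate = min(1.0, config.ss_mismatch_rate * factor)
    for ev in events:
        if planted_classes.get(ev.event_id) not in target_classes:
            continue
        site = _sample_site(ACCEPTOR_CONSENSUS, ACCEPTOR_FIXED, rate, rng)
        if ev.strand == "+":
            _write(arrs[ev.chrom], ev.alt_exon.start - 20, site)
        else:
            _write(arrs[ev.chrom], ev.alt_exon.end - 3, reverse_complement(site))
    return {c: "".join(a) for c, a in arrs.items()}


# --------------------------------------------------------------------------
# GO and complexes

def simulate_go(
    models: list[GeneModel] | list[str],
    config: SimulationConfig,
) -> tuple[list[GOAssociation], set[str], str]:
    """Simulate gene-GO associations with one planted enriched term.
    ``models`` may be gene models or bare gene identifiers.

    Every (gene, term) pair is annotated with probability
    ``go_term_prob``; for the planted term the probability is multiplied
    by ``go_relative_risk`` inside a designated gene list (risk 1 = null).
    Returns (associations, designated gene list, planted term id).
    """
    rng = _rng(config, _GO)
    genes = sorted({m.gene_id if hasattr(m, "gene_id") else str(m) for m in models})
    terms = [f"GO:{i + 1:07d}" for i in range(config.go_n_terms)]
    planted_term = terms[0]
    list_size = min(config.go_list_size, len(genes))
    gene_list = set(rng.choice(genes, size=list_size, replace=False).tolist())
    assoc: list[GOAssociation] = []
    for gene in genes:
        for term in terms:
            p = config.go_term_prob
            if term == planted_term and gene in gene_list:
                p = min(1.0, p * config.go_relative_risk)
            if rng.random() < p:
                assoc.append(GOAssociation(gene_id=gene, term_id=term, term_name=term))
    return assoc, gene_list, planted_term


def simulate_complexes(
    config: SimulationConfig,
) -> tuple[dict[str, list[str]], dict[str, float], str]:
    """Simulate protein scores and complex definitions with one planted
    complex whose member scores are shifted by ``planted_shift`` standard
    deviations.  Returns (complexes, protein scores, planted complex id)."""
    rng = _rng(config, _COMPLEXES)
    proteins = [f"P{i + 1:04d}" for i in range(config.n_proteins)]
    scores = {p: float(v) for p, v in zip(proteins, rng.normal(0.0, 1.0, config.n_proteins))}
    complexes: dict[str, list[str]] = {}
    for c in range(config.n_complexes):
        size = int(rng.integers(config.complex_size[0], config.complex_size[1] + 1))
        members = rng.choice(proteins, size=size, replace=False).tolist()
        complexes[f"CPX{c + 1:03d}"] = sorted(members)
    planted_id = "CPX_PLANTED"
    planted_members = rng.choice(proteins, size=config.planted_complex_size, replace=False).tolist()
    for m in planted_members:
        scores[m] += config.planted_shift
    complexes[planted_id] = sorted(planted_members)
    return complexes, scores, planted_id
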