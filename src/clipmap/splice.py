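"""PSI computation, event classification, peak-event intersection,
splice-site strength, and exon-architecture statistics.

Sign convention: delta_psi = PSI(condition 2) - PSI(condition 1),
i.e. knockout minus wild type.  "Enhanced" events gain inclusion upon
knockout (delta_psi above the threshold), "repressed" events lose it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .models import (
    ALTERNATIVE,
    CLASS_ENHANCED,
    CLASS_REPRESSED,
    CLASS_UNRESPONSIVE,
    EVENT_CLASSES,
    GeneModel,
    GenomicInterval,
    MergedPeak,
    SpliceEvent,
)

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: splice-site window geometry: last 3 exonic + first 6 intronic bases for
#: the donor, last 20 intronic + first 3 exonic for the acceptor
DONOR_EXON, DONOR_INTRON = 3, 6
ACCEPTOR_INTRON, ACCEPTOR_EXON = 20, 3
DONOR_LEN = DONOR_EXON + DONOR_INTRON        # 9
ACCEPTOR_LEN = ACCEPTOR_INTRON + ACCEPTOR_EXON  # 23


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# --------------------------------------------------------------------------
# PSI

def compute_psi(
    inclusion_counts: float,
    skipping_counts: float,
    inclusion_eff_len: float = 1.0,
    skipping_eff_len: float = 1.0,
) -> float:
    """Percent spliced-in from junction read counts, with effective-length
    normalisation: PSI = (I/lI) / (I/lI + S/lS)."""
    if inclusion_counts < 0 or skipping_counts < 0:
        raise ValueError("counts must be >= 0")
    if inclusion_counts == 0 and skipping_counts == 0:
        raise ValueError("PSI undefined: no inclusion or skipping reads")
    i = inclusion_counts / inclusion_eff_len
    s = skipping_counts / skipping_eff_len
    return i / (i + s)


def psi_from_band_intensities(inclusion_intensity: float, skip_intensity: float) -> float:
    """PSI from RT-PCR densitometry: inclusion / (inclusion + skip)."""
    if inclusion_intensity < 0 or skip_intensity < 0:
        raise ValueError("band intensities must be >= 0")
    total = inclusion_intensity + skip_intensity
    if total == 0:
        raise ValueError("PSI undefined: both band intensities are zero")
    return inclusion_intensity / total


# --------------------------------------------------------------------------
# Classification

@dataclass
class ClassifiedEvent:
    event: SpliceEvent
    responsiveness: str


def classify_events(
    events: list[SpliceEvent],
    dpsi_threshold: float = 0.1,
    fdr_threshold: float = 0.05,
) -> list[ClassifiedEvent]:
    """Partition events into enhanced / repressed / unresponsive.

    enhanced:  delta_psi >  +dpsi_threshold and fdr < fdr_threshold
    repressed: delta_psi <  -dpsi_threshold and fdr < fdr_threshold
    otherwise unresponsive.  Strict inequalities on both thresholds.
    """
    out = []
    for ev in events:
        if ev.fdr < fdr_threshold and ev.delta_psi > dpsi_threshold:
            cls = CLASS_ENHANCED
        elif ev.fdr < fdr_threshold and ev.delta_psi < -dpsi_threshold:
            cls = CLASS_REPRESSED
        else:
            cls = CLASS_UNRESPONSIVE
        out.append(ClassifiedEvent(event=ev, responsiveness=cls))
    return out


def events_by_class(classified: list[ClassifiedEvent]) -> dict[str, list[SpliceEvent]]:
    out: dict[str, list[SpliceEvent]] = {c: [] for c in EVENT_CLASSES}
    for ce in classified:
        out[ce.responsiveness].append(ce.event)
    return out


def percent(k: int, n: int) -> float:
    """Percentage to one decimal, the convention used for reported
    proportions (e.g. 223 of 454 -> 49.1)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * k / n, 1)


def class_proportions(items, by: str = "event_type") -> pd.DataFrame:
    """Counts and percentages of events per category.

    ``items`` may be ClassifiedEvents, SpliceEvents, or a precomputed
    ``{category: count}`` mapping; ``by`` selects the grouping attribute
    ("event_type" or "responsiveness").
    """
    if isinstance(items, dict):
        counts = dict(items)
    else:
        counts = {}
        for item in items:
            if isinstance(item, ClassifiedEvent):
                key = item.responsiveness if by == "responsiveness" else getattr(item.event, by)
            else:
                key = getattr(item, by)
            counts[key] = counts.get(key, 0) + 1
    total = sum(counts.values())
    rows = [
        {"category": c, "count": n, "percent": percent(n, total)}
        for c, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["category", "count", "percent"])


# --------------------------------------------------------------------------
# Peak / event intersection

def intersect_peaks_events(
    merged_peaks: list[MergedPeak],
    gene_models: list[GeneModel],
    events: list[SpliceEvent],
    flank_nt: int = 300,
) -> dict:
    """Associate peaks with alternative and constitutive exons and derive
    the gene-level intersection.

    A peak is associated with an alternative exon iff it overlaps the exon
    body, and with a constitutive exon iff it overlaps the exon or lies
    within ``flank_nt`` bases upstream or downstream of it.  Gene-level
    sets (genes with peaks; genes with events) support Venn-style
    intersection counts.
    """
    alt_exons: list[GenomicInterval] = []
    const_exons: list[GenomicInterval] = []
    for m in gene_models:
        for exon, label in zip(m.exons, m.exon_labels):
            (alt_exons if label == ALTERNATIVE else const_exons).append(exon)

    def near(iv: GenomicInterval, exon: GenomicInterval, flank: int) -> bool:
        if iv.chrom != exon.chrom or iv.strand != exon.strand:
            return False
        return iv.start < exon.end + flank and iv.end > exon.start - flank

    peaks_on_alt = sum(
        1 for p in merged_peaks if any(p.interval.overlaps(e) for e in alt_exons)
    )
    peaks_near_const = sum(
        1 for p in merged_peaks if any(near(p.interval, e, flank_nt) for e in const_exons)
    )

    model_by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for m in gene_models:
        model_by_key.setdefault((m.chrom, m.strand), []).append(m)
    peak_genes: set[str] = set()
    for p in merged_peaks:
        for m in model_by_key.get((p.interval.chrom, p.interval.strand), []):
            if m.interval.overlaps(p.interval):
                peak_genes.add(m.gene_id)
    event_genes = {ev.gene_id for ev in events}
    both = peak_genes & event_genes
    return {
        "peaks_on_alt_exons": peaks_on_alt,
        "peaks_near_const_exons": peaks_near_const,
        "n_peak_genes": len(peak_genes),
        "n_event_genes": len(event_genes),
        "n_genes_in_both": len(both),
        "pct_peak_genes_with_events": percent(len(both), len(peak_genes)) if peak_genes else 0.0,
        "pct_event_genes_with_peaks": percent(len(both), len(event_genes)) if event_genes else 0.0,
        "genes_in_both": sorted(both),
    }


def overlap_significance(set_a: set, set_b: set, universe: set, method: str = "chi2") -> tuple[float, float]:
    """Significance of the overlap of two gene sets within a universe.

    Builds the 2x2 table [in both, a only, b only, neither] and applies a
    chi-squared test (df=1, no continuity correction) or Fisher's exact
    test (two-sided).  Returns (statistic, p); for Fisher the statistic is
    the odds ratio.
    """
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    if method == "chi2":
        if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
            return 0.0, 1.0
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(chi2), float(p)
    if method == "fisher":
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return float(odds), float(p)
    raise ValueError(f"unknown method {method!r}")


# --------------------------------------------------------------------------
# Delta-PSI correlation across factors

def dpsi_correlation_matrix(
    dpsi_tables: dict[str, dict[str, float]],
    min_shared: int = 3,
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Spearman correlation of per-event delta-PSI across
    splicing factors (pairwise-complete events), plus an average-linkage
    display order on 1 - rho.

    Pairs sharing fewer than ``min_shared`` events get NaN.  Returns the
    rho matrix and the dendrogram leaf order.
    """
    factors = sorted(dpsi_tables)
    n = len(factors)
    rho = pd.DataFrame(np.eye(n), index=factors, columns=factors)
    for i, j in itertools.combinations(range(n), 2):
        fa, fb = factors[i], factors[j]
        shared = sorted(set(dpsi_tables[fa]) & set(dpsi_tables[fb]))
        if len(shared) < min_shared:
            r = np.nan
        else:
            r = stats.spearmanr(
                [dpsi_tables[fa][e] for e in shared],
                [dpsi_tables[fb][e] for e in shared],
            ).statistic
        rho.iloc[i, j] = rho.iloc[j, i] = r
    order = factors
    if n > 2 and not rho.isna().any().any():
        dist = 1.0 - rho.values
        condensed = dist[np.triu_indices(n, k=1)]
        link = hierarchy.linkage(condensed, method="average")
        order = [factors[i] for i in hierarchy.leaves_list(link)]
    return rho, order


# --------------------------------------------------------------------------
# Exon architecture

ARCHITECTURE_FEATURES = [
    "alt_exon_len",
    "upstream_exon_len",
    "downstream_exon_len",
    "upstream_intron_len",
    "downstream_intron_len",
]


def architecture_features(classified: list[ClassifiedEvent]) -> pd.DataFrame:
    """Exon/intron length features per event, in transcription order."""
    rows = []
    for ce in classified:
        ev = ce.event
        if ev.strand == "+":
            up_intron = ev.alt_exon.start - ev.upstream_const_exon.end
            down_intron = ev.downstream_const_exon.start - ev.alt_exon.end
        else:
            up_intron = ev.upstream_const_exon.start - ev.alt_exon.end
            down_intron = ev.alt_exon.start - ev.downstream_const_exon.end
        rows.append(
            {
                "event_id": ev.event_id,
                "responsiveness": ce.responsiveness,
                "alt_exon_len": len(ev.alt_exon),
                "upstream_exon_len": len(ev.upstream_const_exon),
                "downstream_exon_len": len(ev.downstream_const_exon),
                "upstream_intron_len": up_intron,
                "downstream_intron_len": down_intron,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty and (df[ARCHITECTURE_FEATURES] <= 0).any().any():
        raise ValueError("non-positive exon/intron length; malformed event geometry")
    return df


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided unpaired Wilcoxon (Mann-Whitney U) p-value; exact for
    small samples (n <= 10 per group, no ties), normal approximation with
    tie correction otherwise."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("empty group")
    method = "exact" if (len(x) <= 10 and len(y) <= 10) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def architecture_comparison(features: pd.DataFrame) -> pd.DataFrame:
    """Pairwise class comparisons per architecture feature.

    Two-sided unpaired Wilcoxon tests for every class pair and feature,
    with Benjamini-Hochberg adjusted p-values across the whole grid
    reported alongside the raw values.  Class pairs with fewer than two
    events on either side are flagged and not tested.
    """
    rows = []
    classes = [c for c in EVENT_CLASSES if (features.responsiveness == c).any()]
    for feat in ARCHITECTURE_FEATURES:
        for ca, cb in itertools.combinations(classes, 2):
            xa = features.loc[features.responsiveness == ca, feat]
            xb = features.loc[features.responsiveness == cb, feat]
            if len(xa) < 2 or len(xb) < 2:
                rows.append({"feature": feat, "class_a": ca, "class_b": cb,
                             "n_a": len(xa), "n_b": len(xb), "p_raw": np.nan})
                continue
            rows.append(
                {
                    "feature": feat, "class_a": ca, "class_b": cb,
                    "n_a": len(xa), "n_b": len(xb),
                    "median_a": float(xa.median()), "median_b": float(xb.median()),
                    "p_raw": wilcoxon_rank_sum(xa, xb),
                }
            )
    df = pd.DataFrame(rows)
    tested = df.p_raw.notna()
    df["p_bh"] = np.nan
    if tested.any():
        df.loc[tested, "p_bh"] = stats.false_discovery_control(df.loc[tested, "p_raw"], method="bh")
    return df


# --------------------------------------------------------------------------
# Splice-site windows and strength

@dataclass(frozen=True)
class SpliceSiteWindow:
    """A splice-site sequence window in transcription orientation:
    9-mer for the donor (5'ss), 23-mer for the acceptor (3'ss)."""

    site_kind: str  # "5ss" | "3ss"
    sequence: str
    event_id: str = ""
    site_role: str = ""  # e.g. alt_5ss, alt_3ss, con1_5ss, con2_3ss

    def __post_init__(self):
        want = DONOR_LEN if self.site_kind == "5ss" else ACCEPTOR_LEN
        if self.site_kind not in ("5ss", "3ss"):
            raise ValueError(f"bad site kind {self.site_kind!r}")
        if len(self.sequence) != want:
            raise ValueError(
                f"{self.site_kind} window must be {want} nt, got {len(self.sequence)}"
            )

    @property
    def has_n(self) -> bool:
        return "N" in self.sequence.upper()


def donor_window(genome: dict[str, str], chrom: str, junction: int, strand: str) -> str:
    """9-mer around a 5'ss junction: last 3 exonic + first 6 intronic
    bases, reverse-complemented on '-'."""
    seq = genome[chrom]
    if strand == "+":
        return seq[junction - DONOR_EXON:junction + DONOR_INTRON].upper()
    return reverse_complement(seq[junction - DONOR_INTRON:junction + DONOR_EXON]).upper()


def acceptor_window(genome: dict[str, str], chrom: str, junction: int, strand: str) -> str:
    """23-mer around a 3'ss junction: last 20 intronic + first 3 exonic
    bases, reverse-complemented on '-'."""
    seq = genome[chrom]
    if strand == "+":
        return seq[junction - ACCEPTOR_INTRON:junction + ACCEPTOR_EXON].upper()
    return reverse_complement(seq[junction - ACCEPTOR_EXON:junction + ACCEPTOR_INTRON]).upper()


def _exon_donor_junction(exon: GenomicInterval) -> int:
    return exon.end if exon.strand == "+" else exon.start


def _exon_acceptor_junction(exon: GenomicInterval) -> int:
    return exon.start if exon.strand == "+" else exon.end


def extract_splice_site_windows(
    events: list[SpliceEvent],
    genome: dict[str, str],
    sites: tuple[str, ...] = ("alt_5ss", "alt_3ss", "con1_5ss", "con2_3ss"),
) -> list[SpliceSiteWindow]:
    """Extract splice-site windows for event exons.

    Site roles: alt_5ss / alt_3ss are the alternative exon's own donor and
    acceptor; con1_5ss is the upstream constitutive exon's donor and
    con2_3ss the downstream constitutive exon's acceptor (the flanking
    sites in transcription order).
    """
    out = []
    for ev in events:
        for role in sites:
            if role == "alt_5ss":
                seq = donor_window(genome, ev.chrom, _exon_donor_junction(ev.alt_exon), ev.strand)
                kind = "5ss"
            elif role == "alt_3ss":
                seq = acceptor_window(genome, ev.chrom, _exon_acceptor_junction(ev.alt_exon), ev.strand)
                kind = "3ss"
            elif role == "con1_5ss":
                seq = donor_window(genome, ev.chrom, _exon_donor_junction(ev.upstream_const_exon), ev.strand)
                kind = "5ss"
            elif role == "con2_3ss":
                seq = acceptor_window(genome, ev.chrom, _exon_acceptor_junction(ev.downstream_const_exon), ev.strand)
                kind = "3ss"
            else:
                raise ValueError(f"unknown site role {role!r}")
            out.append(SpliceSiteWindow(site_kind=kind, sequence=seq, event_id=ev.event_id, site_role=role))
    return out


class PwmScorer:
    """Position weight matrix log-odds splice-site scorer.

    A stand-in scorer trained on the annotation's constitutive splice
    sites (pseudocount 0.5, uniform background), obeying the same 9-mer /
    23-mer window geometry as maximum-entropy splice-site models whose
    external score tables can be supplied instead.
    """

    BASES = "ACGT"

    def __init__(self, donor_pwm: np.ndarray, acceptor_pwm: np.ndarray):
        self.donor_pwm = donor_pwm        # (9, 4) log2(f/0.25)
        self.acceptor_pwm = acceptor_pwm  # (23, 4)

    @classmethod
    def train(cls, models: list[GeneModel], genome: dict[str, str], pseudocount: float = 0.5) -> "PwmScorer":
        donors, acceptors = [], []
        for m in models:
            tx = m.exons_tx_order()
            labels = m.exon_labels if m.strand == "+" else list(reversed(m.exon_labels))
            for i, (exon, lab) in enumerate(zip(tx, labels)):
                if lab != "constitutive":
                    continue
                if i < len(tx) - 1:
                    donors.append(donor_window(genome, m.chrom, _exon_donor_junction(exon), m.strand))
                if i > 0:
                    acceptors.append(acceptor_window(genome, m.chrom, _exon_acceptor_junction(exon), m.strand))
        if not donors or not acceptors:
            raise ValueError("no constitutive splice sites to train on")
        return cls(
            donor_pwm=cls._pwm(donors, DONOR_LEN, pseudocount),
            acceptor_pwm=cls._pwm(acceptors, ACCEPTOR_LEN, pseudocount),
        )

    @classmethod
    def _pwm(cls, seqs: list[str], length: int, pseudocount: float) -> np.ndarray:
        counts = np.full((length, 4), pseudocount)
        for s in seqs:
            if len(s) != length or "N" in s:
                continue
            for pos, base in enumerate(s):
                counts[pos, cls.BASES.index(base)] += 1
        freq = counts / counts.sum(axis=1, keepdims=True)
        return np.log2(freq / 0.25)

    def score(self, window: SpliceSiteWindow) -> float:
        pwm = self.donor_pwm if window.site_kind == "5ss" else self.acceptor_pwm
        return float(
            sum(pwm[pos, self.BASES.index(b)] for pos, b in enumerate(window.sequence.upper()))
        )


class TableScorer:
    """Scores looked up from an external site -> score table (e.g. the
    output of a maximum-entropy splice-site scorer)."""

    def __init__(self, table: dict[str, float]):
        self.table = {k.upper(): v for k, v in table.items()}

    @classmethod
    def from_tsv(cls, path) -> "TableScorer":
        df = pd.read_csv(path, sep="\t", header=None, names=["sequence", "score"])
        return cls(dict(zip(df.sequence, df.score)))

    def score(self, window: SpliceSiteWindow) -> float:
        return float(self.table[window.sequence.upper()])


@dataclass
class SpliceSiteComparison:
    scores: pd.DataFrame
    tests: pd.DataFrame
    n_excluded: int = 0


def score_splice_sites(
    windows_by_class: dict[str, list[SpliceSiteWindow]],
    scorer,
) -> SpliceSiteComparison:
    """Score splice-site windows and compare class score distributions.

    Windows containing N are excluded (count reported).  For each site
    role the classes are compared pairwise by two-sided unpaired Wilcoxon
    tests; sample sizes are reported with each test.
    """
    rows = []
    excluded = 0
    for cls_name, windows in windows_by_class.items():
        for w in windows:
            if w.has_n:
                excluded += 1
                continue
            rows.append(
                {
                    "class": cls_name,
                    "site_role": w.site_role or w.site_kind,
                    "site_kind": w.site_kind,
                    "event_id": w.event_id,
                    "score": scorer.score(w),
                }
            )
    scores = pd.DataFrame(rows, columns=["class", "site_role", "site_kind", "event_id", "score"])
    tests = []
    for role in sorted(scores.site_role.unique()) if not scores.empty else []:
        sub = scores[scores.site_role == role]
        classes = sorted(sub["class"].unique())
        for ca, cb in itertools.combinations(classes, 2):
            xa = sub.loc[sub["class"] == ca, "score"]
            xb = sub.loc[sub["class"] == cb, "score"]
            if len(xa) < 2 or len(xb) < 2:
                continue
            tests.append(
                {
                    "site_role": role, "class_a": ca, "class_b": cb,
                    "n_a": len(xa), "n_b": len(xb),
                    "median_a": float(xa.median()), "median_b": float(xb.median()),
                    "p_wilcoxon": wilcoxon_rank_sum(xa, xb),
                }
            )
    return SpliceSiteComparison(
        scores=scores,
        tests=pd.DataFrame(tests, columns=["site_role", "class_a", "class_b", "n_a", "n_b",
                                           "median_a", "median_b", "p_wilcoxon"]),
        n_excluded=excluded,
    )
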