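"""PSI arithmetic, event classification, set statistics, exon
architecture, and splice-site strength."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from clipmap.models import GenomicInterval, SpliceEvent
from clipmap.splice import (
    PwmScorer,
    SpliceSiteWindow,
    TableScorer,
    acceptor_window,
    architecture_comparison,
    architecture_features,
    class_proportions,
    classify_events,
    compute_psi,
    donor_window,
    dpsi_correlation_matrix,
    events_by_class,
    extract_splice_site_windows,
    intersect_peaks_events,
    overlap_significance,
    percent,
    psi_from_band_intensities,
    reverse_complement,
    score_splice_sites,
    wilcoxon_rank_sum,
)
from tests.conftest import make_gene, make_peak


def event(event_id="e", delta=0.2, fdr=0.01, chrom="chrT", strand="+",
          alt=(500, 600), up=(300, 400), down=(700, 800), gene_id="g"):
    return SpliceEvent(
        event_id=event_id, gene_id=gene_id, event_type="SE",
        alt_exon=GenomicInterval(chrom, *alt, strand),
        upstream_const_exon=GenomicInterval(chrom, *up, strand),
        downstream_const_exon=GenomicInterval(chrom, *down, strand),
        psi_per_sample={"cond1": [0.5], "cond2": [min(1.0, 0.5 + delta)]},
        delta_psi=delta, fdr=fdr,
    )


# --------------------------------------------------------------------------
# PSI

@pytest.mark.parametrize("i,s,li,ls,expected", [
    (10, 10, 1, 1, 0.5),
    (0, 7, 1, 1, 0.0),
    (30, 10, 3, 1, 0.5),  # effective-length normalisation
])
def test_compute_psi(i, s, li, ls, expected):
    assert compute_psi(i, s, li, ls) == pytest.approx(expected)


def test_compute_psi_both_zero_is_error():
    with pytest.raises(ValueError):
        compute_psi(0, 0)


@settings(max_examples=50, deadline=None)
@given(
    i=st.integers(0, 1000), s=st.integers(0, 1000),
    k=st.floats(0.01, 100, allow_nan=False),
)
def test_compute_psi_scale_invariant(i, s, k):
    if i == 0 and s == 0:
        return
    assert compute_psi(i * k, s * k) == pytest.approx(compute_psi(i, s))


@pytest.mark.parametrize("inc,skip,expected", [(30, 30, 0.5), (5, 0, 1.0), (80, 20, 0.8)])
def test_psi_from_band_intensities(inc, skip, expected):
    assert psi_from_band_intensities(inc, skip) == pytest.approx(expected)


# --------------------------------------------------------------------------
# Classification

@pytest.mark.parametrize("delta,fdr,expected", [
    (0.2, 0.01, "enhanced"),
    (0.2, 0.2, "unresponsive"),
    (-0.25, 0.01, "repressed"),
    (0.05, 0.001, "unresponsive"),
    (0.1, 0.01, "unresponsive"),  # strict threshold: exactly 0.1 does not pass
])
def test_classify_rules(delta, fdr, expected):
    (ce,) = classify_events([event(delta=delta, fdr=fdr)])
    assert ce.responsiveness == expected


def test_classify_partitions_events():
    rng = np.random.default_rng(2)
    events = [
        event(event_id=f"e{i}", delta=float(rng.uniform(-0.5, 0.5)), fdr=float(rng.uniform(0, 1)))
        for i in range(100)
    ]
    classified = classify_events(events)
    assert len(classified) == 100
    by = events_by_class(classified)
    assert sum(len(v) for v in by.values()) == 100
    ids = [e.event_id for v in by.values() for e in v]
    assert len(set(ids)) == 100


def test_class_proportions_one_decimal_convention():
    df = class_proportions({"SE": 223, "other": 231})
    assert df.loc[df.category == "SE", "percent"].item() == 49.1
    df = class_proportions({"RI": 82, "other": 372})
    assert df.loc[df.category == "RI", "percent"].item() == 18.1
    df = class_proportions({"SE": 7})
    assert df.percent.tolist() == [100.0]
    assert percent(45, 152) == 29.6


# --------------------------------------------------------------------------
# Peak-event intersection

def test_intersect_flank_rule():
    gene = make_gene(alt_index=2)
    ev = event(alt=(500, 600), up=(300, 400), down=(700, 800))
    # const exon [300,400): peak 200 nt upstream of it is associated (<=300)
    near = [make_peak("chrT", 80, 100)]
    far_gene = make_gene(start=4000, gene_id="g2", transcript_id="g2.t1")
    from tests.test_peaks import to_merged

    res = intersect_peaks_events(to_merged(near), [gene], [ev], flank_nt=300)
    assert res["peaks_near_const_exons"] == 1
    # 500 nt away from every exon: not associated
    far = to_merged([make_peak("chrT", 2000, 2010)])
    res = intersect_peaks_events(far, [gene], [ev], flank_nt=300)
    assert res["peaks_near_const_exons"] == 0
    assert res["peaks_on_alt_exons"] == 0


def test_intersect_matches_distance_oracle():
    from tests.test_peaks import to_merged

    models = [
        make_gene(alt_index=2, gene_id="gA", transcript_id="gA.t1"),
        make_gene(alt_index=3, strand="-", start=3000, gene_id="gB", transcript_id="gB.t1"),
    ]
    events = []
    rng = np.random.default_rng(4)
    peaks = []
    for _ in range(150):
        s = int(rng.integers(0, 5000))
        w = int(rng.integers(10, 100))
        peaks.append(make_peak("chrT", s, s + w, "+" if rng.random() < 0.5 else "-"))
    merged = to_merged(peaks)
    res = intersect_peaks_events(merged, models, events, flank_nt=300)
    alt_exons = [e for m in models for e, l in zip(m.exons, m.exon_labels) if l == "alternative"]
    const_exons = [e for m in models for e, l in zip(m.exons, m.exon_labels) if l == "constitutive"]
    brute_alt = sum(
        1 for p in merged if any(p.interval.overlaps(e) for e in alt_exons)
    )
    brute_const = 0
    for p in merged:
        hit = False
        for e in const_exons:
            if e.chrom == p.interval.chrom and e.strand == p.interval.strand:
                gap = max(e.start - p.interval.end, p.interval.start - e.end)
                if gap < 300:
                    hit = True
        brute_const += hit
    assert res["peaks_on_alt_exons"] == brute_alt
    assert res["peaks_near_const_exons"] == brute_const


# --------------------------------------------------------------------------
# Overlap significance

def test_overlap_significance_independence_and_perfect():
    universe = {f"g{i}" for i in range(40)}
    lst = sorted(universe)
    a = set(lst[:20])           # [10,10,10,10] table
    b = set(lst[10:30])
    chi2, p = overlap_significance(a, b, universe, "chi2")
    assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)
    universe = {f"g{i}" for i in range(100)}
    both = set(sorted(universe)[:50])
    for method in ("chi2", "fisher"):
        _, p = overlap_significance(both, both, universe, method)
        assert p < 1e-10


def fisher_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration of the two-sided Fisher p."""
    n = a + b + c + d
    row = a + b
    col = a + c
    lo, hi = max(0, row + col - n), min(row, col)
    pmf = {k: stats.hypergeom.pmf(k, n, col, row) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9))


@pytest.mark.parametrize("seed", range(10))
def test_fisher_matches_hypergeometric_enumeration(seed):
    rng = np.random.default_rng(seed)
    a, b, c, d = (int(rng.integers(0, 15)) for _ in range(4))
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return
    genes = [f"g{i}" for i in range(a + b + c + d)]
    sa = set(genes[: a + b])
    sb = set(genes[:a]) | set(genes[a + b: a + b + c])
    _, p = overlap_significance(sa, sb, set(genes), "fisher")
    assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-6)


# --------------------------------------------------------------------------
# Delta-PSI correlation

def test_dpsi_correlation_self_negation_and_hand():
    events = {f"e{i}": float(v) for i, v in enumerate([0.3, -0.2, 0.1, 0.5, -0.4,
                                                       0.25, -0.15, 0.05, 0.45, -0.35])}
    neg = {k: -v for k, v in events.items()}
    rho, order = dpsi_correlation_matrix({"A": events, "B": dict(events), "C": neg})
    assert rho.loc["A", "A"] == 1.0
    assert rho.loc["A", "B"] == pytest.approx(1.0)
    assert rho.loc["A", "C"] == pytest.approx(-1.0)
    # hand computation for a scrambled third factor
    rng = np.random.default_rng(0)
    other = {k: float(rng.normal()) for k in events}
    rho2, _ = dpsi_correlation_matrix({"A": events, "D": other})
    hand = stats.spearmanr(list(events.values()), [other[k] for k in events]).statistic
    assert rho2.loc["A", "D"] == pytest.approx(hand)


def test_dpsi_correlation_too_few_shared_is_nan():
    rho, _ = dpsi_correlation_matrix({"A": {"e1": 0.1, "e2": 0.2}, "B": {"e1": 0.3, "e3": 0.2}})
    assert np.isnan(rho.loc["A", "B"])


# --------------------------------------------------------------------------
# Architecture

def planted_architecture(n_per_class=200, enhanced_len=80, other_len=150, seed=0):
    rng = np.random.default_rng(seed)
    events = []
    for cls, delta, fdr in (("enhanced", 0.3, 0.01), ("unresponsive", 0.0, 0.5)):
        for i in range(n_per_class):
            alt_len = int(rng.normal(enhanced_len if cls == "enhanced" else other_len, 10))
            alt_len = max(30, alt_len)
            start = 2000
            ev = event(
                event_id=f"{cls}{i}", delta=delta, fdr=fdr,
                alt=(start, start + alt_len),
                up=(1000, 1200), down=(4000, 4200),
            )
            events.append(ev)
    return classify_events(events)


def test_architecture_detects_planted_short_enhanced_exons():
    classified = planted_architecture()
    feats = architecture_features(classified)
    tests = architecture_comparison(feats)
    row = tests[(tests.feature == "alt_exon_len")
                & (tests.class_a == "enhanced") & (tests.class_b == "unresponsive")]
    assert row.p_raw.item() < 0.01
    assert row.median_a.item() < row.median_b.item()


def test_architecture_null_p_uniformish():
    # identical distributions: raw p should not be systematically small
    ps = []
    for seed in range(30):
        classified = planted_architecture(n_per_class=40, enhanced_len=150, seed=seed)
        tests = architecture_comparison(architecture_features(classified))
        row = tests[(tests.feature == "alt_exon_len")
                    & (tests.class_a == "enhanced") & (tests.class_b == "unresponsive")]
        ps.append(row.p_raw.item())
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_architecture_single_event_class_flagged_not_tested():
    classified = classify_events([event(event_id="a", delta=0.3, fdr=0.01),
                                  event(event_id="b", delta=0.0, fdr=0.9)])
    tests = architecture_comparison(architecture_features(classified))
    assert tests.p_raw.isna().all()


def test_wilcoxon_exact_small_samples():
    x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    assert wilcoxon_rank_sum(x, y) == pytest.approx(0.1, abs=1e-9)


# --------------------------------------------------------------------------
# Splice-site windows

def test_donor_window_convention_plus():
    #              0123456789...
    genome = {"c": "AACAGGTAAGTTTTT"}
    # exon ends at junction 5 (exon last 3 = CAG), intron starts GTAAGT
    assert donor_window(genome, "c", 5, "+") == "CAGGTAAGT"


def test_windows_minus_strand_is_reverse_complement():
    rng = np.random.default_rng(8)
    seq = "".join(rng.choice(list("ACGT"), 60))
    genome = {"c": seq}
    j = 30
    # mirrored genome: the '-' window at mirrored junction equals the '+' one
    mirrored = {"c": reverse_complement(seq)}
    jm = len(seq) - j
    assert donor_window(genome, "c", j, "+") == donor_window(mirrored, "c", jm, "-")
    assert acceptor_window(genome, "c", j, "+") == acceptor_window(mirrored, "c", jm, "-")


def test_extract_windows_hand_sliced():
    rng = np.random.default_rng(9)
    seq = "".join(rng.choice(list("ACGT"), 1000))
    genome = {"chrT": seq}
    ev = event(alt=(500, 600), up=(300, 400), down=(700, 800))
    windows = {w.site_role: w for w in extract_splice_site_windows([ev], genome)}
    assert windows["alt_5ss"].sequence == seq[597:606]
    assert windows["alt_3ss"].sequence == seq[480:503]
    assert windows["con1_5ss"].sequence == seq[397:406]
    assert windows["con2_3ss"].sequence == seq[680:703]
    assert len(windows["alt_5ss"].sequence) == 9
    assert len(windows["alt_3ss"].sequence) == 23


def test_window_length_validation():
    with pytest.raises(ValueError, match="9 nt"):
        SpliceSiteWindow(site_kind="5ss", sequence="CAGGT")


# --------------------------------------------------------------------------
# Scoring

def test_pwm_consensus_beats_scrambled(sim_small):
    cfg, models, genome = sim_small
    scorer = PwmScorer.train(models, genome)
    consensus = SpliceSiteWindow(site_kind="5ss", sequence="CAGGTAAGT")
    scrambled = SpliceSiteWindow(site_kind="5ss", sequence="TCTAGCATG")
    assert scorer.score(consensus) > scorer.score(scrambled)


def test_pwm_auc_on_planted_consensus(sim_small):
    cfg, models, genome = sim_small
    scorer = PwmScorer.train(models, genome)
    rng = np.random.default_rng(12)
    fg = []
    bg = []
    for _ in range(200):
        s = list("T" * 17 + "CAG" + "GCC")
        for i in range(23):
            if i not in (18, 19) and rng.random() < 0.1:
                s[i] = "ACGT"[int(rng.integers(0, 4))]
        fg.append(scorer.score(SpliceSiteWindow("3ss", "".join(s))))
        bg.append(scorer.score(SpliceSiteWindow("3ss", "".join(rng.choice(list("ACGT"), 23)))))
    auc = np.mean([f > b for f, b in itertools.product(fg, bg)])
    assert auc >= 0.9


def test_table_scorer_round_trip(tmp_path):
    table = {"CAGGTAAGT": 9.7, "AAAGTAAGT": 3.2}
    p = tmp_path / "scores.tsv"
    p.write_text("".join(f"{k}\t{v}\n" for k, v in table.items()))
    scorer = TableScorer.from_tsv(p)
    for seq, val in table.items():
        assert scorer.score(SpliceSiteWindow("5ss", seq)) == val


def test_score_splice_sites_excludes_n_windows(sim_small):
    cfg, models, genome = sim_small
    scorer = PwmScorer.train(models, genome)
    good = SpliceSiteWindow("5ss", "CAGGTAAGT", site_role="alt_5ss")
    bad = SpliceSiteWindow("5ss", "CANGTAAGT", site_role="alt_5ss")
    comp = score_splice_sites({"enhanced": [good, bad]}, scorer)
    assert comp.n_excluded == 1
    assert len(comp.scores) == 1


def test_weak_3ss_detected_at_realistic_group_sizes():
    """Planted weaker acceptors in responsive classes are detected by the
    Wilcoxon comparison at realistic per-class sample sizes (79/61/53),
    while donors stay null."""
    from clipmap.synthetic import (
        SimulationConfig,
        degrade_splice_sites,
        simulate_annotation,
        simulate_events,
    )

    n = 79 + 61 + 53
    cfg = SimulationConfig(
        seed=20, n_genes=n,
        class_fractions={"enhanced": 61 / n, "repressed": 53 / n, "unresponsive": 79 / n},
    )
    models, genome = simulate_annotation(cfg)
    events, planted = simulate_events(models, cfg)
    genome = degrade_splice_sites(genome, events, planted, cfg, factor=2.0)
    scorer = PwmScorer.train(models, genome)
    by_class = {}
    for ev in events:
        by_class.setdefault(planted[ev.event_id], []).append(ev)
    windows = {
        cls: extract_splice_site_windows(evs, genome, sites=("alt_5ss", "alt_3ss"))
        for cls, evs in by_class.items()
    }
    comp = score_splice_sites(windows, scorer)
    t = comp.tests.set_index(["site_role", "class_a", "class_b"])
    assert t.loc[("alt_3ss", "enhanced", "unresponsive"), "p_wilcoxon"] < 0.01
    assert t.loc[("alt_3ss", "repressed", "unresponsive"), "p_wilcoxon"] < 0.01
    # donors were not degraded: no signal expected
    assert t.loc[("alt_5ss", "enhanced", "unresponsive"), "p_wilcoxon"] > 0.05
    assert t.loc[("alt_5ss", "repressed", "unresponsive"), "p_wilcoxon"] > 0.05
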