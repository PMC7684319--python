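"""Boundary selection, metagene density, composite maps, replicate
correlation."""

import dataclasses

import numpy as np
import pytest

from clipmap.models import CoverageTrack, GenomicInterval
from clipmap.peaks import merge_replicate_peaks
from clipmap.rna_map import (
    boundary_density,
    composite_map,
    replicate_correlation,
    select_boundaries,
)
from clipmap.splice import classify_events
from tests.conftest import make_gene, make_peak


def to_merged(peaks):
    other = [dataclasses.replace(p, library_id="lib2") for p in peaks]
    return merge_replicate_peaks([peaks, other], min_support=2)


# --------------------------------------------------------------------------
# Boundary selection

def test_worked_five_boundary_expansion(six_exon_gene):
    # exons [100,200) [300,400) [500,600) [700,800) [900,1000) [1100,1200)
    # peak from inside exon 3 to inside intron 4 (after exon 4)
    merged = to_merged([make_peak("chrT", 550, 850)])
    bounds = select_boundaries(merged, [six_exon_gene])
    assert sorted(b.position for b in bounds) == [500, 600, 700, 800, 900]
    kinds = {b.position: b.kind for b in bounds}
    # '+' strand: exon ends are 5'ss (exon_intron), exon starts are 3'ss
    assert kinds[600] == "exon_intron" and kinds[500] == "intron_exon"


def test_worked_five_boundary_expansion_minus_strand(six_exon_gene_minus):
    merged = to_merged([make_peak("chrT", 550, 850, strand="-")])
    bounds = select_boundaries(merged, [six_exon_gene_minus])
    assert sorted(b.position for b in bounds) == [500, 600, 700, 800, 900]
    kinds = {b.position: b.kind for b in bounds}
    # on '-' an exon's genomic start is its transcription end (5'ss)
    assert kinds[500] == "exon_intron" and kinds[600] == "intron_exon"


def test_peak_inside_intron_selects_flanking_boundaries(six_exon_gene):
    merged = to_merged([make_peak("chrT", 230, 260)])  # inside intron 1 [200,300)
    bounds = select_boundaries(merged, [six_exon_gene])
    assert sorted(b.position for b in bounds) == [200, 300]


def test_peak_with_no_host_transcript_skipped(six_exon_gene):
    merged = to_merged([make_peak("chrT", 9000, 9050)])
    assert select_boundaries(merged, [six_exon_gene]) == []


def boundaries_oracle(merged, models):
    """Exhaustive per-peak scan over all junctions of the host transcript."""
    out = set()
    for m in merged:
        iv = m.interval
        hosts = [g for g in models
                 if g.chrom == iv.chrom and g.strand == iv.strand and g.interval.overlaps(iv)]
        if not hosts:
            continue
        host = min(hosts, key=lambda g: (g.biotype != "protein_coding", -len(g.interval), g.transcript_id))
        junctions = []
        for i, e in enumerate(host.exons):
            if i > 0:
                junctions.append(e.start)
            if i < len(host.exons) - 1:
                junctions.append(e.end)
        chosen = {p for p in junctions if iv.start < p < iv.end}
        before = [p for p in junctions if p <= iv.start]
        after = [p for p in junctions if p >= iv.end]
        if before:
            chosen.add(max(before))
        if after:
            chosen.add(min(after))
        out |= {(host.transcript_id, p) for p in chosen}
    return out


def test_select_boundaries_matches_scan_oracle():
    models = [
        make_gene(gene_id="gA", transcript_id="gA.t1"),
        make_gene(strand="-", start=3000, gene_id="gB", transcript_id="gB.t1"),
        make_gene(n_exons=4, exon_len=60, intron_len=300, start=7000,
                  gene_id="gC", transcript_id="gC.t1"),
    ]
    rng = np.random.default_rng(17)
    peaks = []
    for _ in range(200):
        s = int(rng.integers(0, 9000))
        w = int(rng.integers(10, 200))
        strand = "+" if rng.random() < 0.5 else "-"
        peaks.append(make_peak("chrT", s, s + w, strand))
    merged = to_merged(peaks)
    got = {(b.transcript_id, b.position) for b in select_boundaries(merged, models)}
    assert got == boundaries_oracle(merged, models)


# --------------------------------------------------------------------------
# Boundary density

def test_density_hand_oracle_single_boundary():
    gene = make_gene(chrom="c", n_exons=2, exon_len=8, intron_len=8, start=4)
    # exons [4,12) and [20,28); 5'ss junction at 12
    ip = CoverageTrack({"c": 32})
    inp = CoverageTrack({"c": 32})
    ip_vals = np.arange(32) % 7
    inp_vals = (np.arange(32) * 3) % 5
    ip.get("c", "+")[:] = ip_vals
    inp.get("c", "+")[:] = inp_vals
    merged = to_merged([make_peak("c", 10, 14)])
    bounds = [b for b in select_boundaries(merged, [gene]) if b.kind == "exon_intron"]
    assert len(bounds) == 1 and bounds[0].position == 12
    p5, _ = boundary_density(bounds, ip, inp, exon_window=4, intron_window=4, epsilon=1.0)
    # offsets -4..3 map to genomic bases 8..15 on '+'
    expected = (ip_vals[8:16] + 1.0) / (inp_vals[8:16] + 1.0)
    assert p5.relative_density == pytest.approx(expected)
    assert p5.offsets.tolist() == list(range(-4, 4))


def test_density_equal_tracks_converges_to_one(six_exon_gene):
    ip = CoverageTrack({"chrT": 2000})
    inp = CoverageTrack({"chrT": 2000})
    ip.get("chrT", "+")[:] = 50
    inp.get("chrT", "+")[:] = 50
    merged = to_merged([make_peak("chrT", 350, 380)])
    bounds = select_boundaries(merged, [six_exon_gene])
    p5, p3 = boundary_density(bounds, ip, inp, epsilon=1.0)
    for prof in (p5, p3):
        present = prof.control_counts > 0
        assert np.allclose(prof.relative_density[present], 1.0, atol=0.05)


def test_density_empty_boundaries_is_error():
    ip = CoverageTrack({"c": 10})
    with pytest.raises(ValueError, match="empty"):
        boundary_density([], ip, ip)


def test_density_truncated_at_transcript_span():
    # first exon is only 30 nt from the transcript start: the 5'ss window
    # (100 exonic bases) must truncate at the gene start
    gene = make_gene(chrom="c", n_exons=2, exon_len=30, intron_len=400, start=10)
    ip = CoverageTrack({"c": 1000})
    inp = CoverageTrack({"c": 1000})
    ip.get("c", "+")[:] = 1
    inp.get("c", "+")[:] = 1
    merged = to_merged([make_peak("c", 15, 25)])
    bounds = [b for b in select_boundaries(merged, [gene]) if b.kind == "exon_intron"]
    p5, _ = boundary_density(bounds, ip, inp)
    # exonic offsets beyond the 30 exon bases contribute nothing
    assert p5.sample_counts[p5.offsets < -30].sum() == 0
    assert (p5.sample_counts[(p5.offsets >= -30) & (p5.offsets < 300)] == 1).all()


def test_density_conservation_sums(sim_small):
    from clipmap.synthetic import (
        chrom_sizes_of,
        simulate_coverage,
        simulate_peaks,
    )

    cfg, models, genome = sim_small
    libs = simulate_peaks(models, cfg)
    merged = merge_replicate_peaks(list(libs.values()))
    bounds = select_boundaries(merged, models)
    sizes = chrom_sizes_of(genome)
    ip, inp = simulate_coverage(models, merged, cfg, sizes)
    p5, p3 = boundary_density(bounds, ip, inp)
    # brute force: re-walk every boundary window base by base
    total = {"exon_intron": 0, "intron_exon": 0}
    for b in bounds:
        offsets = range(-100, 300) if b.kind == "exon_intron" else range(-300, 100)
        arr = ip.get(b.chrom, b.strand)
        for o in offsets:
            base = b.position + o if b.strand == "+" else b.position - 1 - o
            if b.tx_span[0] <= base < min(b.tx_span[1], sizes[b.chrom]) and base >= 0:
                total[b.kind] += arr[base]
    assert p5.sample_counts.sum() == total["exon_intron"]
    assert p3.sample_counts.sum() == total["intron_exon"]


def test_density_strand_mirror_symmetry():
    # a '+' gene and its coordinate-mirrored '-' twin with mirrored tracks
    # must produce identical profiles
    L = 2000
    gene_p = make_gene(chrom="p", gene_id="gp", transcript_id="gp.t1")
    exons_m = [GenomicInterval("m", L - e.end, L - e.start, "-") for e in reversed(gene_p.exons)]
    gene_m = dataclasses.replace(
        gene_p,
        gene_id="gm", transcript_id="gm.t1",
        interval=GenomicInterval("m", L - gene_p.interval.end, L - gene_p.interval.start, "-"),
        exons=exons_m, exon_labels=list(gene_p.exon_labels), cds=[],
    )
    rng = np.random.default_rng(3)
    depth_ip = rng.integers(0, 20, L)
    depth_in = rng.integers(0, 20, L)
    ip_p = CoverageTrack({"p": L}); ip_p.get("p", "+")[:] = depth_ip
    in_p = CoverageTrack({"p": L}); in_p.get("p", "+")[:] = depth_in
    ip_m = CoverageTrack({"m": L}); ip_m.get("m", "-")[:] = depth_ip[::-1]
    in_m = CoverageTrack({"m": L}); in_m.get("m", "-")[:] = depth_in[::-1]

    peak_p = to_merged([make_peak("p", 550, 850)])
    peak_m = to_merged([make_peak("m", L - 850, L - 550, strand="-")])
    b_p = select_boundaries(peak_p, [gene_p])
    b_m = select_boundaries(peak_m, [gene_m])
    p5p, p3p = boundary_density(b_p, ip_p, in_p)
    p5m, p3m = boundary_density(b_m, ip_m, in_m)
    assert np.array_equal(p5p.sample_counts, p5m.sample_counts)
    assert np.array_equal(p3p.sample_counts, p3m.sample_counts)
    assert np.allclose(p5p.relative_density, p5m.relative_density)


# --------------------------------------------------------------------------
# Composite maps

def make_event(gene, event_id="ev1"):
    alt_i = gene.exon_labels.index("alternative")
    tx = gene.exons_tx_order()
    labels = gene.exon_labels if gene.strand == "+" else list(reversed(gene.exon_labels))
    i = labels.index("alternative")
    from clipmap.models import SpliceEvent

    return SpliceEvent(
        event_id=event_id, gene_id=gene.gene_id, event_type="SE",
        alt_exon=tx[i], upstream_const_exon=tx[i - 1], downstream_const_exon=tx[i + 1],
        psi_per_sample={"cond1": [0.5], "cond2": [0.8]},
        delta_psi=0.3, fdr=0.01,
    )


def test_composite_no_peaks_zero_occupancy(six_exon_gene):
    gene = make_gene(alt_index=2)
    ev = make_event(gene)
    (cm,) = composite_map([], {"enhanced": [ev]}, n_bins=50)
    assert cm.occupancy.tolist() == [0.0] * 50
    assert cm.n_events == 1


def test_composite_full_window_peak_fills_all_bins():
    gene = make_gene(alt_index=2)
    ev = make_event(gene)
    # window is [exon2.end, exon4.start) = [400, 700); peak covers it all
    merged = to_merged([make_peak("chrT", 350, 750)])
    (cm,) = composite_map(merged, {"enhanced": [ev]}, n_bins=50)
    assert cm.occupancy.tolist() == [1.0] * 50


def test_composite_short_window_skipped():
    gene = make_gene(alt_index=2, exon_len=20, intron_len=30)
    ev = make_event(gene)
    (cm,) = composite_map([], {"enhanced": [ev]}, n_bins=100)
    assert cm.n_events == 0 and cm.n_skipped == 1


def test_composite_occupancy_monotone_under_added_peak():
    gene = make_gene(alt_index=2)
    ev = make_event(gene)
    base = to_merged([make_peak("chrT", 420, 450)])
    more = to_merged([make_peak("chrT", 420, 450), make_peak("chrT", 600, 640)])
    (cm1,) = composite_map(base, {"enhanced": [ev]}, n_bins=60)
    (cm2,) = composite_map(more, {"enhanced": [ev]}, n_bins=60)
    assert (cm2.occupancy >= cm1.occupancy).all()
    assert cm2.occupancy.sum() > cm1.occupancy.sum()


def test_composite_strand_mirror():
    L = 2000
    gene_p = make_gene(alt_index=2, gene_id="gp", transcript_id="gp.t1")
    gene_m = make_gene(alt_index=3, strand="-", gene_id="gm", transcript_id="gm.t1")
    # '-' gene alt_index 3 in genomic order == transcription index 2 of 6
    ev_p, ev_m = make_event(gene_p, "p"), make_event(gene_m, "m")
    # same transcription-relative position: peak 20-50 nt into the window
    peaks_p = to_merged([make_peak("chrT", 420, 450, "+")])
    win_end_m = ev_m.upstream_const_exon.start  # '-' window = [down.end, up.start)
    peaks_m = to_merged([make_peak("chrT", win_end_m - 50, win_end_m - 20, "-")])
    (cp,) = composite_map(peaks_p, {"x": [ev_p]}, n_bins=60)
    (cm,) = composite_map(peaks_m, {"x": [ev_m]}, n_bins=60)
    assert cp.occupancy.tolist() == cm.occupancy.tolist()


# --------------------------------------------------------------------------
# Replicate correlation

def test_correlation_track_vs_itself():
    t = CoverageTrack({"c": 1000})
    t.get("c", "+")[:] = np.random.default_rng(0).poisson(20, 1000)
    r, n = replicate_correlation(t, t)
    assert r == pytest.approx(1.0)
    assert n > 900


def test_correlation_independent_tracks_near_zero():
    rng = np.random.default_rng(1)
    a = CoverageTrack({"c": 100_000}); a.get("c", "+")[:] = rng.poisson(20, 100_000)
    b = CoverageTrack({"c": 100_000}); b.get("c", "+")[:] = rng.poisson(20, 100_000)
    r, n = replicate_correlation(a, b)
    assert n >= 10_000
    assert abs(r) < 0.1


def test_correlation_hand_fixture():
    a = CoverageTrack({"c": 5}); a.get("c", "+")[:] = [8, 16, 4, 32, 64]
    b = CoverageTrack({"c": 5}); b.get("c", "+")[:] = [4, 8, 16, 32, 8]
    r, n = replicate_correlation(a, b, min_depth=3)
    x, y = np.log2([8, 16, 4, 32, 64]), np.log2([4, 8, 16, 32, 8])
    assert n == 5
    assert r == pytest.approx(np.corrcoef(x, y)[0, 1])


def test_correlation_too_few_positions_is_error():
    a = CoverageTrack({"c": 10})
    b = CoverageTrack({"c": 10})
    a.get("c", "+")[:2] = 10
    b.get("c", "+")[:2] = 10
    with pytest.raises(ValueError):
        replicate_correlation(a, b)
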