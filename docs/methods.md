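# Methods

`clipmap` implements the downstream integration of eCLIP binding data
with alternative-splicing (AS) quantification: consensus peak calling
across replicate libraries, splice-site-anchored binding maps, ΔPSI-based
event classification, splice-site strength and exon-architecture
comparisons, and GO / protein-complex enrichment.  This note records the
models, parameter choices and numerical conventions, and what the
synthetic-data generator does and does not emulate.

## Coordinates and data model

All genomic coordinates are 0-based, half-open, on an explicit strand.
GTF input (1-based, closed) is converted once at the I/O boundary.  A
junction coordinate `p` separates base `p-1` from base `p`; "5'ss"
(donor) and "3'ss" (acceptor) are always meant in transcription
orientation, so on the `-` strand an exon's genomic start is its donor
junction.  When a peak overlaps several transcripts, the host is the
longest protein-coding transcript (ties: longest span, then lexicographic
transcript id); this single rule is used for genic annotation, boundary
selection and window truncation.

## High-confidence peaks and replicate consensus

A peak is high-confidence when p ≤ 1e-3 **and** fold enrichment over the
size-matched input ≥ 5.  The fold threshold is inclusive by default (the
inclusive convention matches how such peak sets are usually defined); a
strict `>` flag is available
because the two conventions both occur in practice.

Consensus merging builds connected components of same-chromosome,
same-strand peaks pooled over all libraries under ≥ 1 bp overlap
(`min_overlap_bp` is exposed, since "overlap" admits several cutoffs), keeps
components supported by ≥ `min_support` (default 2) distinct libraries,
and emits the union span `min(start)..max(end)` of each kept component.
Combining chained peaks into the union span makes the subsequent
redundancy elimination meaningful: output intervals are disjoint by
construction, and an optional `join_gap` unions near-adjacent spans for
gap-joined dialects.  Consequences tested as invariants: merging is
idempotent, monotone in `min_support`, and each source peak contributes
to at most one merged peak.

Genic categories are assigned by precedence
`exon_intron_junction > CDS_exon > 5'UTR > 3'UTR > noncoding_exon >
intron > intergenic` over the bases the peak touches on its host
transcript.  Without CDS features in the annotation the exonic categories
collapse to a single `exon` category, since the UTR/CDS split is a
property of annotation richness, not of the peak.

## RNA maps

**Boundary selection.**  For each merged peak the selected splice-site
boundaries are (1) all junctions strictly inside the peak and (2) for
each peak terminal, the nearest junction not covered by the peak.  A peak
running from inside exon 3 to inside intron 4 of a six-exon transcript
therefore selects five boundaries (intron2|exon3 … intron4|exon5).  A
junction coinciding with a peak edge counts as "not covered" (distance
zero, rule 2); this tie-break is part of the contract and shared with the
test oracle.

**Per-base metagene density.**  Around every selected boundary a window
of 100 exonic and 300 intronic bases (defaults) is read from the IP and
input coverage tracks in transcription orientation; counts are summed per
offset across boundaries and the relative density is the elementwise
ratio `(sample + ε) / (control + ε)`.  The pseudocount ε = 1 handles
zero-control positions, which the ratio definition leaves open, and is
exposed.  Summing counts before dividing (rather than averaging
per-boundary ratios) defines the profile as a ratio of total read
counts, which weights boundaries by their coverage.
Windows truncate at the host transcript span and chromosome ends, so
truncated boundaries contribute only their defined offsets.

**Composite maps.**  Per AS event the window runs from the upstream
constitutive exon's 5'ss to the downstream constitutive exon's 3'ss
(boundary to boundary, excluding the flanking exon bodies — the
alternative reading would mix exon-body binding into the flanks).  The
window is divided into `n_bins` = 100 equal-width bins; a bin is occupied
for an event iff at least one merged-peak base overlaps it, and the map
reports the fraction of the class's events occupying each bin.
Equal-width fractional bins are the default because averaging across
events of different window lengths needs a common axis; a fixed-100-bp
mode anchored at the upstream boundary is provided, as is a
peak-coverage-weighted occupancy variant.  Events with windows shorter
than `n_bins` bases are skipped and counted.

**Replicate correlation.**  Pearson correlation of log2 read depth at
positions where **both** tracks exceed depth 3 (strict inequality; the
threshold is applied to both tracks so the qualifying set is symmetric
in the pair).

## Event classification and splicing statistics

ΔPSI = mean PSI(condition 2) − mean PSI(condition 1), i.e. knockout minus
wild type.  "Enhanced" means inclusion rises upon knockout
(ΔPSI > +0.1), "repressed" the reverse; both additionally require
FDR < 0.05.  Thresholds are strict inequalities (strict and inclusive
conventions both circulate; strict is adopted and configurable), and the
sign convention is switchable.  PSI from junction counts uses effective
length normalisation `PSI = (I/lI)/(I/lI + S/lS)`; PSI from RT-PCR
densitometry is `inc/(inc+skip)`.

Peak–event intersection: a peak is associated with an alternative exon
iff it overlaps the exon body, and with a constitutive exon iff it
overlaps the exon or lies within 300 nt up- or downstream.  Set-overlap
significance uses a 2×2 chi-squared test (df = 1, no continuity
correction) or the two-sided Fisher exact test.  ΔPSI correlation across
factors is pairwise-complete Spearman with average-linkage ordering on
1 − ρ; pairs sharing fewer than 3 events are reported missing.

Rank tests are two-sided unpaired Wilcoxon (Mann–Whitney U), exact for
group sizes ≤ 10 without ties, otherwise the tie-corrected normal
approximation.  Raw p-values are primary (matching how the comparisons
are usually reported); Benjamini–Hochberg adjusted values are reported
alongside for the architecture feature×pair grid.

Splice-site windows are 9-mers (last 3 exonic + first 6 intronic bases)
for donors and 23-mers (last 20 intronic + first 3 exonic) for acceptors,
reverse-complemented on `-`.  The built-in scorer is a PWM log-odds model
(pseudocount 0.5, uniform background) trained on the annotation's
constitutive sites; it deliberately does not re-derive the trained
parameters of maximum-entropy splice-site models, whose score tables can
be supplied as first-class external input instead.  Windows containing N
are excluded and counted.

## Enrichment

GO enrichment: per term with ≥ 5 annotated background genes, a 2×2
in-list × has-term chi-squared test (df = 1, no continuity correction)
with Bonferroni correction over the tested terms.  Term assignments are
taken as given (no GO-graph ancestor propagation).  Degenerate margins
(e.g. a term covering the whole background) are skipped and logged.

Complex enrichment: observed score = unweighted mean member score
(weighting is exposed as a strategy hook; no particular weighting is
canonical); members absent from the data contribute the background
minimum and are logged.  The null is `n_perm` = 1000 random same-size
member sets drawn from all scored proteins, and
`p = (1 + #{null ≥ observed}) / (1 + n_perm)` — add-one smoothing keeps
p in (0, 1] and makes the extreme case exactly 1/(n_perm+1).  The ranked
curve flags complexes at p < 5.012e-2; the cutoff is treated as a plain
threshold parameter.

## Synthetic data

The generator emulates the structure of a real study's inputs, not its
sequences:

* multi-exon genes (5–8 exons of 80–220 nt, introns 250–1200 nt) on both
  strands, one internal alternative exon per gene, canonical GT..AG
  introns with consensus-like donor/acceptor context (per-position
  mismatch rate 0.1) and a 20-nt UTR trim defining the CDS;
* four peak libraries: true binding sites placed by a positional model
  (default mass 0.35 within 50 nt upstream of donors and 0.25 within
  25 nt downstream of acceptors, mirroring the observed preference, with
  0.2 exon-body and 0.2 deep-intron background), observed per library
  with ±8 nt jitter; 20 % of sites carry statistics failing the
  high-confidence filter.  With jitter 0 all libraries are identical by
  construction;
* coverage: input ~ Poisson(2) per base, IP ~ Poisson(2 × 5) under peaks
  — the simplest count model with known moments, enabling exact
  recovery checks (the source gives no noise model);
* events: two PSI replicates per condition, base PSI uniform in
  [0.35, 0.65], planted ΔPSI ±0.3 with N(0, 0.02) replicate noise,
  FDR < 0.05 for responsive and uniform(0.05, 1) otherwise; class mix
  0.3/0.3/0.4 enhanced/repressed/unresponsive;
* GO: 30 terms at annotation probability 0.08 per gene, one term planted
  at relative risk 5 in a designated list; complexes: 20 random
  complexes over 200 N(0,1)-scored proteins plus one 8-member complex
  shifted by 2 sd.

Each generator draws from its own RNG substream at a stable offset from
the config seed, so any generator is byte-reproducible in isolation.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level artefacts (PCR duplicates, mapping
bias, crosslink-induced truncations), realistic sequence composition
beyond splice-site dinucleotides and consensus context, transcript
abundance (occupancy in real CLIP data tracks expression; no
abundance normalisation is modelled), overlapping genes and alternative
isoform structure, and correlated replicate noise.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen to give the
statistical checks clear power while completing in seconds: positional
recovery uses 200 genes / 1200 planted sites (≥ 1000 selected
boundaries); composite-map recovery uses 900 events (~300 per class)
with constant 150/500 nt exon/intron geometry so the alternative 3'ss
falls at the same bin for every event — with variable lengths the
fractional-bin anchor varies per event and the composite smears by
construction, which is a property of the axis, not the signal;
classification recovery uses 500 events; calibration checks use 100
seeds.  The GO recovery demonstration uses a 100-gene list in a 500-gene
background, the list size at which top-ranked recovery of a relative-risk-5
term is the expected outcome.

Genome-scale totals (thousands of peaks, hundreds of events) require
sequencing-scale input data and are not reproduced at desk scale; the
acceptance script instead recomputes the reference proportion arithmetic
exactly and measures planted-signal recovery on the synthetic study.

## Known limitations

* The UTR/CDS genic split requires CDS features; annotation without them
  yields the collapsed `exon` category.
* MAJIQ-style local splicing variants have no canonical binary-event
  reduction; such tables must be exported to the simple TSV dialect.
* Composite-map occupancy is binary per event; the weighted variant
  approximates coverage only through merged (disjoint) peaks.
* The PWM scorer is a stand-in with the correct window geometry, not a
  maximum-entropy model; absolute scores are not comparable to published
  splice-site scores, only rank comparisons within a run are meaningful.
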