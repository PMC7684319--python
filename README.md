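# clipmap

Splice-site-anchored RNA binding maps and alternative-splicing
integration for eCLIP peak data.

RNA-binding proteins that act in splicing leave a positional signature:
where they sit relative to splice sites determines whether an exon is
included or skipped.  `clipmap` is a library for the downstream half of
that analysis — it starts from per-replicate eCLIP peak tables, IP/input
coverage tracks, a gene annotation and rMATS-style AS event tables, and
produces replicate-consensus peaks, metagene binding maps anchored on 5'
and 3' splice sites, ΔPSI-based event classification, class-stratified
composite occupancy maps, splice-site strength and exon-architecture
comparisons, and GO / protein-complex enrichment statistics.  It is
aimed at people analysing CLIP + RNA-seq experiments who want the
integration steps as tested, reusable functions rather than one-off
scripts.

## The statistics at the core

* **High-confidence peaks**: keep clusters with p ≤ 10⁻³ and ≥ 5-fold
  enrichment over the size-matched input; merge clusters supported by
  ≥ 2 of N replicate libraries into the union span of each connected
  overlap component.
* **RNA map**: for boundaries selected by the peaks (junctions covered
  by a peak, plus the nearest uncovered junction beyond each peak
  terminal), count IP and input depth per base over 100 nt of exon and
  300 nt of intron in transcription orientation; relative density at
  offset *i* is (sample*ᵢ* + ε)/(control*ᵢ* + ε).
* **Event classification**: ΔPSI = PSI(KO) − PSI(WT); an event is
  *enhanced* if ΔPSI > 0.1 and FDR < 0.05, *repressed* if ΔPSI < −0.1
  and FDR < 0.05, otherwise *unresponsive*.
* **Composite map**: the window between the flanking constitutive exons
  is split into 100 equal bins; occupancy per bin is the fraction of a
  class's events with ≥ 1 peak base in that bin.
* **Enrichment**: chi-squared (df = 1) + Bonferroni for GO terms;
  empirical permutation p = (1 + #{null ≥ obs})/(1 + 1000) for protein
  complexes; Fisher/chi-squared for set intersections; two-sided
  unpaired Wilcoxon for splice-site strength and exon-architecture
  contrasts (9-mer donor / 23-mer acceptor windows).

A fully parameterised synthetic-data generator
(`clipmap.synthetic`) emulates such a study's inputs — gene models with
GT..AG introns, peak libraries with a planted positional preference,
Poisson coverage with fold enrichment under peaks, events with planted
response classes — so the whole pipeline runs and is tested without any
external data.

## Worked example

Plant binding within 50 nt upstream of donor sites at 5-fold IP
enrichment and read it back as a metagene profile
(`examples/02_rna_map.py`):

```text
712 boundaries selected from 393 merged peaks
5'ss profile maximum at offset -29 nt (negative = exonic side)
mean relative density, planted window vs deep intron: 4.84x
```

The profile maximum falls inside the planted [−50, 0) window and the
input-normalised signal is ~5-fold above the deep-intron baseline — the
map recovers both the position and the magnitude of the simulated
binding.  Recover a planted GO term and protein complex
(`examples/05_enrichment.py`):

```text
top GO term: GO:0000001 (planted: GO:0000001)  k=37/100 vs 64/500  chi2=65.6  p_bonferroni=1.67e-14
 rank  complex_id  n_members  n_members_in_data    score   p_perm  passes_cutoff
    1 CPX_PLANTED          8                  8 2.379946 0.000999           True
```

The planted complex ranks first at the smoothed minimum p = 1/1001.
The other scripts in `examples/` cover consensus merging, event
classification, splice-site strength and the end-to-end pipeline; each
prints what it computes and says what the numbers mean.

A thin CLI wraps the same functions:

```bash
clipmap run --seed 7 --out demo_run        # full synthetic run, 30 files + manifest
clipmap peaks merge --peaks a.bed --peaks b.bed --out merged.tsv
clipmap splice classify --events events.tsv --out classified.tsv
```

Identical config + seed reproduces every output file byte for byte (the
manifest records a sha256 per file).

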