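"""Splice-site-anchored RNA binding map.

Plants binding within 50 nt upstream of 5' splice sites at 5-fold IP
enrichment, then recovers that positional preference as an
input-normalised per-base metagene profile around donor sites.
"""

import numpy as np

from clipmap.peaks import filter_high_confidence, merge_replicate_peaks
from clipmap.rna_map import boundary_density, select_boundaries
from clipmap.synthetic import (
    SimulationConfig,
    chrom_sizes_of,
    simulate_annotation,
    simulate_coverage,
    simulate_peaks,
)

cfg = SimulationConfig(
    seed=42, n_genes=120, peaks_per_library=600, jitter=0, frac_low_confidence=0.0,
    background_rate=5.0, enrichment_fold=5.0,
    positional_model={"within_50nt_upstream_of_5ss": 1.0, "exon_body": 0.0,
                      "within_25nt_downstream_of_3ss": 0.0, "deep_intron": 0.0},
)
models, genome = simulate_annotation(cfg)
libraries = simulate_peaks(models, cfg)
merged = merge_replicate_peaks([filter_high_confidence(v) for v in libraries.values()])

boundaries = select_boundaries(merged, models)
ip, inp = simulate_coverage(models, merged, cfg, chrom_sizes_of(genome))
profile_5ss, profile_3ss = boundary_density(boundaries, ip, inp, exon_window=100, intron_window=300)

peak_offset = int(profile_5ss.offsets[np.argmax(profile_5ss.relative_density)])
exon_window = (profile_5ss.offsets >= -50) & (profile_5ss.offsets < 0)
deep_intron = profile_5ss.offsets >= 100
ratio = profile_5ss.relative_density[exon_window].mean() / profile_5ss.relative_density[deep_intron].mean()

print(f"{len(boundaries)} boundaries selected from {len(merged)} merged peaks")
print(f"5'ss profile maximum at offset {peak_offset} nt (negative = exonic side)")
print(f"mean relative density, planted window vs deep intron: {ratio:.2f}x")

# The maximum falls inside the planted [-50, 0) exonic window and the
# signal stands several-fold above the deep-intron baseline, i.e. the map
# reads back the position-dependent binding that was simulated.
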