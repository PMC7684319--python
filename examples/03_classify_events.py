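"""Delta-PSI event classification and exon architecture.

Simulates skipped-exon events with planted enhanced / repressed /
unresponsive classes (|dPSI| effect 0.3, replicate noise 0.02), applies
the |dPSI| > 0.1 and FDR < 0.05 classification, and compares exon/intron
length features between classes.
"""

import numpy as np

from clipmap.splice import (
    architecture_comparison,
    architecture_features,
    class_proportions,
    classify_events,
)
from clipmap.synthetic import SimulationConfig, simulate_annotation, simulate_events

cfg = SimulationConfig(seed=42, n_genes=300)
models, _ = simulate_annotation(cfg)
events, planted = simulate_events(models, cfg)

classified = classify_events(events, dpsi_threshold=0.1, fdr_threshold=0.05)
recovery = np.mean([ce.responsiveness == planted[ce.event.event_id] for ce in classified])
print(f"{len(events)} events; planted-class recovery {100 * recovery:.1f}%")
print("\nClass proportions:")
print(class_proportions(classified, by="responsiveness").to_string(index=False))

features = architecture_features(classified)
tests = architecture_comparison(features)
print("\nExon-architecture Wilcoxon comparisons (first rows):")
print(tests.head(6).to_string(index=False))

# With a 0.3 effect and 0.02 noise the threshold rule recovers essentially
# every planted label.  The generator draws identical length distributions
# for all classes, so architecture comparisons are null: occasional small
# raw p-values are chance and the BH-adjusted column stays non-significant.
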