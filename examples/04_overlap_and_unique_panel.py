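"""Two-step overlap: find candidates untouched by exercise or altitude.

Uses the packaged summary table for the exercise leg and a synthetic
altitude union, then decomposes the candidate panel into the seven Venn
regions and derives the confounder-free panel.
"""

import numpy as np

from eposcreen import (
    GenePanel, derive_unique_panel, load_candidate_screen_summary,
    screen_panel, two_step_overlap,
)
from eposcreen.degfilter import FilteredSet

summary = load_candidate_screen_summary()
epo = GenePanel(name="epo", genes=set(summary.index))
exercise = GenePanel(name="exercise",
                     genes=screen_panel(list(summary.index), summary).responsive_genes)

# Synthetic stand-in for the altitude union: hits half the candidates.
rng = np.random.default_rng(0)
alt_genes = set(rng.choice(sorted(epo.genes), size=len(epo.genes) // 2,
                           replace=False))
altitude = [FilteredSet(study_id="altitude_union", genes=alt_genes)]

ov = two_step_overlap(epo, altitude, exercise)
print("Venn regions (candidate, altitude, exercise):")
for key, n in sorted(ov.region_counts.items()):
    print(f"  {key}: {n}")
print("candidate ∩ altitude:", len(ov.pairwise(0, 1)))
print("candidate ∩ exercise:", len(ov.pairwise(0, 2)))

unique = derive_unique_panel(epo, alt_genes, exercise)
print(f"\nconfounder-free panel: {len(unique.genes)} of {len(epo.genes)} "
      "candidates are moved by neither stimulus")
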