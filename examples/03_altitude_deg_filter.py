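"""Replicate study-specific DEG cut-offs and build the altitude union.

Generates synthetic DEG tables in the three supported dialects (linear
FC + FDR; log2FC only; DESeq2-style with contrast labels), applies each
study's published thresholds and aggregates the union -- the hypoxia-
responsive confounder panel.
"""

from eposcreen import (
    STUDY_THRESHOLDS, SimConfig, altitude_union, filter_table, gen_deg_tables,
)

cfg = SimConfig(seed=42, n_genes=500,
                deg_fractions={"sutehall": 0.05, "pham": 0.1, "manella": 0.3})
tables, truth = gen_deg_tables(cfg)

filtered = []
for dialect, rows in tables.items():
    fs = filter_table(rows, STUDY_THRESHOLDS[dialect])
    filtered.append(fs)
    thr = STUDY_THRESHOLDS[dialect]
    bound = (f"FC >= {thr.min_abs_fc}" if thr.min_abs_fc
             else f"|log2FC| {'>= ' if thr.fc_inclusive else '> '}{thr.min_abs_log2fc}")
    print(f"{dialect:<9s} {bound:<16s} -> {len(fs.genes):>3d} DEGs "
          f"(planted {len(truth.deg_sets[dialect])})")

union, presence = altitude_union(filtered)
multi = int((presence["n_altitude_studies"] > 1).sum())
print(f"\naltitude union: {len(union)} unique genes; "
      f"{multi} appear in more than one study")
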