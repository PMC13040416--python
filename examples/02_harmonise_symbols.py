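"""Resolve outdated gene identifiers to approved symbols.

Builds a tiny alias table in memory (the shape a nomenclature snapshot
export has), then resolves a panel containing a historical alias, case
damage and a LOC placeholder that only a second-pass table can name.
"""

from eposcreen import AliasRecord, AliasTable, harmonise_panel

primary = AliasTable([
    AliasRecord("MARCHF8", synonyms=("MARCH8",), biotype="protein_coding",
                description="membrane associated ring-CH-type finger 8"),
    AliasRecord("ALAS2", biotype="protein_coding",
                description="5'-aminolevulinate synthase 2"),
    AliasRecord("RPS2P55", biotype="pseudogene",
                description="ribosomal protein S2 pseudogene 55"),
])
secondary = AliasTable([
    AliasRecord("RPS2P55", synonyms=("LOC286444",), biotype="pseudogene"),
])

panel = ["MARCH8", "  alas2 ", "LOC286444", "LOC100131164"]
harmonised, audit, unmapped = harmonise_panel(panel, primary, secondary)

for row in audit:
    print(f"{row.input_symbol!r:<18} -> {row.resolved_symbol or '(unmapped)':<12}"
          f" via {row.route}")
print("\nharmonised panel:", harmonised.symbols)
print("unmapped:", unmapped, "(LOC ids with no official name stay unmapped)")
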