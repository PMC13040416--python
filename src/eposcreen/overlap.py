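"""Two-step overlap of a candidate panel against confounder gene sets.

Step 1 aggregates the confounder (altitude) study sets into one union;
step 2 decomposes candidate-panel membership against the altitude union and
the exercise-responsive set into the full three-set Venn (seven regions),
attributes altitude overlaps back to individual source studies, and derives
the confounder-free panel: candidates untouched by either stimulus.

All comparisons are symbol-level; direction of regulation travels only as
provenance metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .degfilter import FilteredSet, altitude_union

__all__ = [
    "GenePanel",
    "OverlapResult",
    "AttributionTable",
    "venn3_regions",
    "two_step_overlap",
    "derive_unique_panel",
    "study_attribution",
]

#: Region keys: presence triple (in A, in B, in C) over (epo, altitude, exercise).
REGION_KEYS = ("100", "010", "001", "110", "101", "011", "111")


@dataclass
class GenePanel:
    """A named gene set with optional per-gene source tags."""

    name: str
    genes: set[str]
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("panel name must be non-empty")
        self.genes = set(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class OverlapResult:
    """Seven-region Venn decomposition of (candidate, altitude, exercise)."""

    set_names: tuple[str, str, str]
    region_genes: dict[str, set[str]]

    @property
    def region_counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.region_genes.items()}

    @property
    def membership(self) -> dict[str, str]:
        """Per-gene region key (each gene sits in exactly one region)."""
        return {g: k for k, genes in self.region_genes.items() for g in genes}

    def pairwise(self, i: int, j: int) -> set[str]:
        """All genes shared by sets i and j (regardless of the third)."""
        return {
            g
            for key, genes in self.region_genes.items()
            if key[i] == "1" and key[j] == "1"
            for g in genes
        }


def venn3_regions(a: set[str], b: set[str], c: set[str]) -> dict[str, set[str]]:
    """Exclusive seven-region decomposition of three sets."""
    regions = {k: set() for k in REGION_KEYS}
    for g in a | b | c:
        key = f"{int(g in a)}{int(g in b)}{int(g in c)}"
        regions[key].add(g)
    return regions


def two_step_overlap(
    epo: GenePanel,
    altitude_sets: list[FilteredSet],
    exercise: GenePanel,
) -> OverlapResult:
    """Aggregate altitude sets, then decompose candidate-panel membership."""
    if not epo.genes:
        raise ValueError("candidate (EPO) panel is empty")
    alt_union, _ = altitude_union(altitude_sets)
    regions = venn3_regions(epo.genes, alt_union, exercise.genes)
    return OverlapResult(
        set_names=(epo.name, "altitude_union", exercise.name),
        region_genes=regions,
    )


def derive_unique_panel(
    epo: GenePanel,
    altitude_union_genes: set[str],
    exercise: GenePanel,
) -> GenePanel:
    """Candidates unaffected by either confounder: epo \\ (altitude | exercise)."""
    unique = epo.genes - (altitude_union_genes | exercise.genes)
    return GenePanel(
        name=f"{epo.name}_unique",
        genes=unique,
        provenance={g: set(epo.provenance.get(g, set())) for g in unique},
    )


@dataclass
class AttributionTable:
    """Partition of an overlap set by source-study sharing pattern."""

    rows: list[tuple[str, int, str]]  # (category, count, note)
    genes_by_category: dict[str, set[str]]

    @property
    def total(self) -> int:
        return sum(n for _, n, _ in self.rows)


def study_attribution(
    overlap_genes: set[str],
    per_study_sets: dict[str, set[str]],
) -> AttributionTable:
    """Attribute each overlap gene to the exact combination of studies holding it.

    Categories are 'unique to X' plus every pairwise / higher-order sharing
    pattern; they are mutually exclusive and sum to the overlap size. A gene
    present in no study set is a consistency error.
    """
    studies = sorted(per_study_sets)
    pattern_genes: dict[tuple[str, ...], set[str]] = {}
    for g in overlap_genes:
        members = tuple(s for s in studies if g in per_study_sets[s])
        if not members:
            raise ValueError(f"gene {g!r} in overlap set but absent from every study set")
        pattern_genes.setdefault(members, set()).add(g)

    rows: list[tuple[str, int, str]] = []
    genes_by_category: dict[str, set[str]] = {}
    # Enumerate all patterns (including empty ones) for a stable, complete table.
    for r in range(1, len(studies) + 1):
        for combo in combinations(studies, r):
            genes = pattern_genes.get(combo, set())
            if r == 1:
                cat = f"unique_to_{combo[0]}"
                note = f"present only in {combo[0]}"
            else:
                cat = "shared_" + "_".join(combo)
                note = "present in " + " and ".join(combo) + " only"
            rows.append((cat, len(genes), note))
            genes_by_category[cat] = genes
    return AttributionTable(rows=rows, genes_by_category=genes_by_category)
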