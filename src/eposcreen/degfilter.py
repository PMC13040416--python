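"""Study-specific differential-expression threshold filtering.

Each altitude study publishes its own cut-offs for calling a gene
differentially expressed, in its own table dialect:

* ``sutehall`` -- linear fold change with an FDR column; FC >= 1.2, FDR <= 5%.
* ``pham``     -- log2 fold change only; |log2FC| >= 1 (FC >= 2), no printed
  p criterion, with Day-1 / Day-3 (HA1/HA3) contrasts.
* ``manella``  -- DESeq2-style rows (baseMean, log2FoldChange, lfcSE, stat,
  pvalue, padj) with altitude-interval contrast labels; q < 0.01 (strict)
  and |log2FC| > 0.5 (strict).

Inclusivity follows each study's printed operator exactly. Thresholds are
applied to |log2FC| by default (two-sided) since published DEG lists
conventionally include down-regulation; linear and log2 effect fields are
interconvertible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "DEGRow",
    "ThresholdConfig",
    "FilteredSet",
    "STUDY_THRESHOLDS",
    "MANELLA_CONTRASTS",
    "row_passes",
    "filter_table",
    "altitude_union",
]

#: Altitude-interval contrast labels used by the three-altitude study design
#: (sea level ~200 m, ~3800 m, ~5100 m).
MANELLA_CONTRASTS = ("200-3800M", "200-5100M", "3800-5100M")


@dataclass(frozen=True)
class DEGRow:
    """One differential-expression record; only fields the dialect reports."""

    gene: str
    fc: float | None = None          # linear fold change, > 0
    log2fc: float | None = None
    lfcse: float | None = None
    stat: float | None = None
    base_mean: float | None = None
    p: float | None = None
    p_adj: float | None = None       # FDR / q / padj, whatever the study calls it
    contrast: str | None = None      # e.g. altitude interval or day label

    def effective_log2fc(self) -> float:
        if self.log2fc is not None:
            return self.log2fc
        if self.fc is not None:
            if self.fc <= 0:
                raise ValueError(f"{self.gene}: linear fold change must be > 0")
            return math.log2(self.fc)
        raise ValueError(f"{self.gene}: row has neither fc nor log2fc")


@dataclass(frozen=True)
class ThresholdConfig:
    """One study's DEG cut-offs.

    Exactly one of ``min_abs_fc`` (linear) / ``min_abs_log2fc`` must be set;
    the ``*_inclusive`` flags encode the printed operator (>= vs >, <= vs <).
    """

    study_id: str
    min_abs_fc: float | None = None
    min_abs_log2fc: float | None = None
    fc_inclusive: bool = True
    max_adj_p: float | None = None
    adj_p_inclusive: bool = True
    two_sided: bool = True

    def __post_init__(self) -> None:
        if (self.min_abs_fc is None) == (self.min_abs_log2fc is None):
            raise ValueError("exactly one of min_abs_fc / min_abs_log2fc must be set")
        bound = self.min_abs_fc if self.min_abs_fc is not None else self.min_abs_log2fc
        if bound <= 0:
            raise ValueError("effect-size bound must be positive")
        if self.max_adj_p is not None and not 0 < self.max_adj_p <= 1:
            raise ValueError("max_adj_p must be in (0, 1]")

    @property
    def log2_bound(self) -> float:
        if self.min_abs_log2fc is not None:
            return self.min_abs_log2fc
        return math.log2(self.min_abs_fc)


#: The three studies' published cut-offs, operators as printed.
STUDY_THRESHOLDS: dict[str, ThresholdConfig] = {
    "sutehall": ThresholdConfig(
        study_id="sutehall", min_abs_fc=1.2, fc_inclusive=True,
        max_adj_p=0.05, adj_p_inclusive=True,
    ),
    "pham": ThresholdConfig(
        study_id="pham", min_abs_log2fc=1.0, fc_inclusive=True,
    ),
    "manella": ThresholdConfig(
        study_id="manella", min_abs_log2fc=0.5, fc_inclusive=False,
        max_adj_p=0.01, adj_p_inclusive=False,
    ),
}


def row_passes(row: DEGRow, cfg: ThresholdConfig) -> bool:
    """Decide one row against one study's cut-offs."""
    val = row.effective_log2fc()
    if cfg.two_sided:
        val = abs(val)
    bound = cfg.log2_bound
    ok = (val >= bound) if cfg.fc_inclusive else (val > bound)
    if not ok:
        return False
    if cfg.max_adj_p is not None:
        if row.p_adj is None or math.isnan(row.p_adj):
            return False
        if cfg.adj_p_inclusive:
            ok = row.p_adj <= cfg.max_adj_p
        else:
            ok = row.p_adj < cfg.max_adj_p
    return ok


@dataclass
class FilteredSet:
    """Genes passing one study's cut-offs, with per-contrast breakdown."""

    study_id: str
    genes: set[str]
    per_contrast: dict[str, set[str]] = field(default_factory=dict)
    n_rows: int = 0


def filter_table(table: list[DEGRow], cfg: ThresholdConfig) -> FilteredSet:
    """Apply the cut-offs row-wise; union over rows, duplicates collapse.

    When rows carry contrast labels (altitude intervals, day labels), the
    per-contrast pass sets are retained alongside the study-level union.
    """
    genes: set[str] = set()
    per_contrast: dict[str, set[str]] = {}
    for row in table:
        if not row_passes(row, cfg):
            continue
        genes.add(row.gene)
        if row.contrast is not None:
            per_contrast.setdefault(row.contrast, set()).add(row.gene)
    return FilteredSet(study_id=cfg.study_id, genes=genes,
                       per_contrast=per_contrast, n_rows=len(table))


def altitude_union(sets: list[FilteredSet]):
    """Aggregate unique DEGs across studies into one hypoxia-responsive panel.

    Returns ``(union_set, presence)`` where ``presence`` is a pandas DataFrame
    indexed by gene with one boolean column per study plus an
    ``n_altitude_studies`` count column.
    """
    import pandas as pd

    union: set[str] = set()
    for fs in sets:
        union |= fs.genes
    idx = sorted(union)
    presence = pd.DataFrame(index=pd.Index(idx, name="gene"))
    for fs in sets:
        presence[fs.study_id] = [g in fs.genes for g in idx]
    presence["n_altitude_studies"] = presence.sum(axis=1).astype(int)
    return union, presence
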