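"""Exercise-responsiveness screening of candidate genes.

Candidate doping biomarkers are screened against multi-modality exercise
expression summaries (GEPREP-style): for each gene, Cohen's *d* is computed
for every exercise modality against a sedentary control, and a gene is called
*responsive* when it passes the statistical gate (omnibus p below alpha, or a
non-computable NaN p caused by zero within-group variance) **and** at least
one modality shows |d| at or above the effect-size threshold.

Cohen's d here is the standardized mean difference with an equal-weight
pooled SD, ``(m1 - m2) / sqrt((s1^2 + s2^2) / 2)``, because the upstream
database exposes only group means and SDs, not group sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScreenConfig",
    "EffectSizeRecord",
    "GeneScreenStatus",
    "ScreenResult",
    "cohens_d",
    "kruskal_wallis",
    "effect_sizes",
    "classify_gene",
    "screen_panel",
]

#: Canonical modality labels, control last.
DEFAULT_CONDITIONS = (
    "acute_aerobic",
    "acute_anaerobic",
    "longterm_aerobic",
    "longterm_resistance",
    "other",
    "inactivity",
)


@dataclass(frozen=True)
class ScreenConfig:
    """Screening rule parameters.

    alpha
        Significance level for the omnibus p gate (default 0.05, strict ``<``
        unless ``alpha_inclusive``).
    d_threshold
        Minimum |Cohen's d| for a biologically meaningful response (default
        0.5, a moderate effect).
    control_label
        Name of the sedentary control condition.
    gate_on_p
        If True (default), only genes with p < alpha or NaN p can be called
        responsive; if False the effect-size rule applies irrespective of p.
    undefined_is_hit
        Whether an undefined d (both SDs zero, means differ; reported as
        signed infinity) counts as a threshold hit. Default False.
    """

    alpha: float = 0.05
    d_threshold: float = 0.5
    control_label: str = "inactivity"
    gate_on_p: bool = True
    alpha_inclusive: bool = False
    undefined_is_hit: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.d_threshold <= 0:
            raise ValueError(f"d_threshold must be > 0, got {self.d_threshold}")


@dataclass(frozen=True)
class EffectSizeRecord:
    """Signed standardized mean difference of one modality vs the control."""

    gene: str
    modality: str
    d: float  # +/-inf flags an undefined effect (both SDs zero, means differ)

    @property
    def undefined(self) -> bool:
        return math.isinf(self.d)


@dataclass
class GeneScreenStatus:
    gene: str
    status: str  # significant | nan_p | not_significant | missing
    responsive: bool
    hit_modalities: list[str] = field(default_factory=list)
    max_abs_d: float = float("nan")


@dataclass
class ScreenResult:
    """Panel-level screening outcome: per-gene statuses plus headline counts."""

    statuses: dict[str, GeneScreenStatus]
    effects: list[EffectSizeRecord]

    @property
    def counts(self) -> dict[str, int]:
        c = {"significant": 0, "nan_p": 0, "not_significant": 0, "missing": 0}
        for s in self.statuses.values():
            c[s.status] += 1
        c["responsive"] = sum(s.responsive for s in self.statuses.values())
        return c

    @property
    def responsive_genes(self) -> set[str]:
        return {g for g, s in self.statuses.items() if s.responsive}


def cohens_d(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> float:
    """Standardized mean difference with equal-weight pooled SD.

    Returns 0.0 when both SDs are zero and the means agree, and signed
    infinity (undefined effect) when both SDs are zero but the means differ.
    """
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    pooled = math.sqrt((sd_a * sd_a + sd_b * sd_b) / 2.0)
    diff = mean_a - mean_b
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0
        return math.copysign(math.inf, diff)
    return diff / pooled


def kruskal_wallis(groups: list[list[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-squared p across groups.

    When every value in every group is identical the tie-correction
    denominator vanishes and no test is possible; (nan, nan) is returned,
    mirroring the NaN p values the screening rule must tolerate.
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("kruskal_wallis groups must be non-empty")
    import warnings

    try:
        with warnings.catch_warnings():
            # all-identical data zeroes the tie-correction denominator; the
            # resulting NaN is the intended outcome, not a numerical accident
            warnings.simplefilter("ignore", RuntimeWarning)
            h, p = stats.kruskal(*arrays)
    except ValueError:
        return (float("nan"), float("nan"))
    return (float(h), float(p))


def effect_sizes(
    summary: pd.Series | dict,
    cfg: ScreenConfig,
    conditions: tuple[str, ...] | None = None,
    gene: str = "",
) -> list[EffectSizeRecord]:
    """Per-modality Cohen's d vs the control, from summary statistics only.

    ``summary`` maps ``<condition>_mean`` / ``<condition>_sd`` keys to values
    (one row of the summary table). Per-sample values are deliberately not
    consulted so results match what the summary-level database exposes.
    """
    if conditions is None:
        conditions = _conditions_from_keys(summary, cfg)
    ctrl = cfg.control_label
    if f"{ctrl}_mean" not in summary:
        raise ValueError(f"control condition {ctrl!r} missing from summary")
    m_c, s_c = float(summary[f"{ctrl}_mean"]), float(summary[f"{ctrl}_sd"])
    out = []
    for cond in conditions:
        if cond == ctrl:
            continue
        d = cohens_d(float(summary[f"{cond}_mean"]), float(summary[f"{cond}_sd"]), m_c, s_c)
        out.append(EffectSizeRecord(gene=gene, modality=cond, d=d))
    return out


def _conditions_from_keys(summary, cfg: ScreenConfig) -> tuple[str, ...]:
    keys = summary.index if isinstance(summary, pd.Series) else summary.keys()
    conds = [k[: -len("_mean")] for k in keys if str(k).endswith("_mean")]
    if cfg.control_label not in conds:
        raise ValueError(f"control condition {cfg.control_label!r} missing from summary")
    return tuple(conds)


def classify_gene(
    p: float,
    records: list[EffectSizeRecord],
    present: bool,
    cfg: ScreenConfig,
    gene: str = "",
) -> GeneScreenStatus:
    """Apply the significance/NaN gate and the |d| >= threshold rule."""
    if not present:
        return GeneScreenStatus(gene=gene, status="missing", responsive=False)
    if math.isnan(p):
        status = "nan_p"
    elif (p <= cfg.alpha) if cfg.alpha_inclusive else (p < cfg.alpha):
        status = "significant"
    else:
        status = "not_significant"

    hits = []
    max_abs = float("nan")
    finite = [abs(r.d) for r in records if not r.undefined]
    if finite:
        max_abs = max(finite)
    for r in records:
        if r.undefined:
            if cfg.undefined_is_hit:
                hits.append(r.modality)
        elif abs(r.d) >= cfg.d_threshold:
            hits.append(r.modality)

    gate = status in ("significant", "nan_p") if cfg.gate_on_p else True
    responsive = gate and bool(hits)
    return GeneScreenStatus(
        gene=gene, status=status, responsive=responsive,
        hit_modalities=hits, max_abs_d=max_abs,
    )


def screen_panel(
    panel: list[str] | tuple[str, ...],
    summaries: pd.DataFrame,
    cfg: ScreenConfig | None = None,
) -> ScreenResult:
    """Screen a harmonised candidate panel against a summary table.

    ``summaries`` is indexed by gene symbol with ``<cond>_mean``/``<cond>_sd``
    columns and a ``p`` column (NaN permitted). Panel genes absent from the
    table are counted ``missing``. The four status counts always partition
    the panel.
    """
    cfg = cfg or ScreenConfig()
    panel = list(panel)
    if len(set(panel)) != len(panel):
        dupes = sorted({g for g in panel if panel.count(g) > 1})
        raise ValueError(f"duplicate panel symbols (harmonise first): {dupes}")
    statuses: dict[str, GeneScreenStatus] = {}
    effects: list[EffectSizeRecord] = []
    for g in panel:
        if g not in summaries.index:
            statuses[g] = classify_gene(float("nan"), [], present=False, cfg=cfg, gene=g)
            continue
        row = summaries.loc[g]
        recs = effect_sizes(row, cfg, gene=g)
        effects.extend(recs)
        statuses[g] = classify_gene(float(row["p"]), recs, present=True, cfg=cfg, gene=g)
    return ScreenResult(statuses=statuses, effects=effects)
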