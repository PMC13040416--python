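"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* group-wise Gaussian expression on a normalised-log scale across six
  exercise conditions (one sedentary control), with planted standardized
  mean differences and optional all-constant genes that force NaN omnibus
  p-values (zero within-group variance);
* differential-expression tables in the three altitude-study dialects, with
  a planted fraction of true DEGs that pass each study's cut-offs by
  construction while every other row fails at least one criterion;
* alias tables plus a deliberately corrupted panel (historical synonyms,
  case/whitespace damage, LOC placeholders resolvable only on a second
  pass) with the intended resolution recorded;
* term annotations in which planted terms are over-sampled from a
  designated input set so their enrichment is true by construction.

Each generator draws from its own RNG stream derived from the master seed,
so adding one generator to a workflow never perturbs another's output, and
identical configurations yield identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .degfilter import MANELLA_CONTRASTS, STUDY_THRESHOLDS, DEGRow
from .enrichment import AnnotationSet
from .harmonise import AliasRecord, AliasTable
from .screen import DEFAULT_CONDITIONS, kruskal_wallis

__all__ = ["SimConfig", "TruthSet", "gen_expression", "gen_deg_tables",
           "gen_alias_table", "gen_annotations"]

# Fixed per-generator RNG stream offsets.
_STREAM_EXPRESSION = 1
_STREAM_DEG = 2
_STREAM_ALIAS = 3
_STREAM_ANNOTATION = 4


@dataclass
class SimConfig:
    """Generator parameters; defaults describe the study conditions emulated.

    ``group_sizes`` may be a single count applied to every condition or a
    per-condition mapping. 30 samples per group is the default working size
    (the real database does not publish its group sizes). ``planted_effects``
    maps gene -> (condition, standardized effect d) relative to the control.
    """

    seed: int = 0
    n_genes: int = 500
    condition_labels: tuple[str, ...] = DEFAULT_CONDITIONS
    control_label: str = "inactivity"
    group_sizes: int | dict[str, int] = 30
    planted_effects: dict[str, tuple[str, float]] = field(default_factory=dict)
    zero_variance_fraction: float = 0.0
    d_threshold: float = 0.5
    deg_fractions: dict[str, float] = field(
        default_factory=lambda: {"sutehall": 0.1, "pham": 0.1, "manella": 0.1}
    )
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 50)
    planted_terms: int = 0
    planted_term_size: int = 20
    planted_term_input_fraction: float = 0.8
    alias_noise: dict[str, float] = field(
        default_factory=lambda: {"synonym": 0.0, "case": 0.0, "loc": 0.0,
                                 "loc_unresolvable": 0.0}
    )
    panel_size: int = 50

    def __post_init__(self) -> None:
        for name, frac in [("zero_variance_fraction", self.zero_variance_fraction),
                           ("planted_term_input_fraction", self.planted_term_input_fraction),
                           *[(f"deg_fractions[{k}]", v) for k, v in self.deg_fractions.items()],
                           *[(f"alias_noise[{k}]", v) for k, v in self.alias_noise.items()]]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        unknown = set(self.deg_fractions) - set(STUDY_THRESHOLDS)
        if unknown:
            raise ValueError(f"unknown DEG dialect(s): {sorted(unknown)}")
        if self.control_label not in self.condition_labels:
            raise ValueError("control_label must appear in condition_labels")
        for cond in self.condition_labels:
            if self.group_size(cond) < 2 and self.zero_variance_fraction == 0.0:
                raise ValueError(
                    f"group size < 2 for {cond!r} without zero-variance intent"
                )

    def group_size(self, cond: str) -> int:
        if isinstance(self.group_sizes, dict):
            return int(self.group_sizes[cond])
        return int(self.group_sizes)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([stream, self.seed])

    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


@dataclass
class TruthSet:
    """Planted ground truth for recovery testing."""

    responsive_genes: set[str] = field(default_factory=set)
    planted_d: dict[str, tuple[str, float]] = field(default_factory=dict)
    zero_variance_genes: set[str] = field(default_factory=set)
    deg_sets: dict[str, set[str]] = field(default_factory=dict)
    enriched_terms: set[str] = field(default_factory=set)
    alias_map: dict[str, str | None] = field(default_factory=dict)
    alias_routes: dict[str, str] = field(default_factory=dict)


def gen_expression(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, TruthSet]:
    """Per-sample expression plus the derived summary table and truth.

    Returns ``(samples, summary, truth)``. ``samples`` is gene x sample with
    ``condition::s<i>`` column labels; ``summary`` carries per-condition
    mean/SD (ddof=1) and the omnibus rank-test p (NaN for the all-constant
    genes). Planted effects shift the condition mean by ``d x gene SD``, so
    every gene with planted ``|d| >= cfg.d_threshold`` is truly responsive.
    """
    rng = cfg.rng(_STREAM_EXPRESSION)
    genes = cfg.gene_names()
    truth = TruthSet()

    base_mean = rng.normal(5.0, 2.0, size=cfg.n_genes)
    gene_sd = rng.uniform(0.3, 1.5, size=cfg.n_genes)

    planted = dict(cfg.planted_effects)
    for g, (cond, _) in planted.items():
        if g not in set(genes):
            raise ValueError(f"planted effect for unknown gene {g!r}")
        if cond not in cfg.condition_labels or cond == cfg.control_label:
            raise ValueError(f"planted effect condition {cond!r} invalid")
    n_zero = int(round(cfg.zero_variance_fraction * cfg.n_genes))
    eligible = [g for g in genes if g not in planted]
    if n_zero > len(eligible):
        n_zero = len(eligible)
    zero_var = set(rng.choice(eligible, size=n_zero, replace=False)) if n_zero else set()

    columns = [
        f"{cond}::s{j}"
        for cond in cfg.condition_labels
        for j in range(cfg.group_size(cond))
    ]
    data = np.empty((cfg.n_genes, len(columns)))
    col = 0
    slices: dict[str, slice] = {}
    for cond in cfg.condition_labels:
        m = cfg.group_size(cond)
        slices[cond] = slice(col, col + m)
        col += m

    for i, g in enumerate(genes):
        if g in zero_var:
            data[i, :] = base_mean[i]
            continue
        for cond in cfg.condition_labels:
            mu = base_mean[i]
            if g in planted and planted[g][0] == cond:
                mu = mu + planted[g][1] * gene_sd[i]
            sl = slices[cond]
            data[i, sl] = rng.normal(mu, gene_sd[i], size=sl.stop - sl.start)

    samples = pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=columns)

    rows = {}
    for cond in cfg.condition_labels:
        block = samples.iloc[:, slices[cond]]
        rows[f"{cond}_mean"] = block.mean(axis=1)
        rows[f"{cond}_sd"] = block.std(axis=1, ddof=1)
    summary = pd.DataFrame(rows)
    pvals = []
    for i in range(cfg.n_genes):
        groups = [data[i, slices[c]].tolist() for c in cfg.condition_labels]
        pvals.append(kruskal_wallis(groups)[1])
    summary["p"] = pvals

    truth.planted_d = planted
    truth.zero_variance_genes = zero_var
    truth.responsive_genes = {
        g for g, (_, d) in planted.items() if abs(d) >= cfg.d_threshold
    }
    return samples, summary, truth


def _signed(rng: np.random.Generator, magnitude: float) -> float:
    return magnitude if rng.random() < 0.5 else -magnitude


def gen_deg_tables(cfg: SimConfig) -> tuple[dict[str, list[DEGRow]], TruthSet]:
    """One DEG table per dialect with a planted fraction of true DEGs.

    Planted rows pass their study's cut-offs by construction; every other
    row fails the effect criterion, the adjusted-p criterion, or both
    (dialects without a p criterion fail on effect).
    """
    rng = cfg.rng(_STREAM_DEG)
    genes = cfg.gene_names()
    truth = TruthSet()
    tables: dict[str, list[DEGRow]] = {}

    for dialect, frac in cfg.deg_fractions.items():
        n_true = int(round(frac * cfg.n_genes))
        true_genes = set(rng.choice(genes, size=n_true, replace=False)) if n_true else set()
        rows: list[DEGRow] = []
        for g in genes:
            is_deg = g in true_genes
            if dialect == "sutehall":
                # FC >= 1.2 (inclusive) and FDR <= 0.05 (inclusive).
                if is_deg:
                    l2 = _signed(rng, rng.uniform(math.log2(1.2), 2.0))
                    fdr = rng.uniform(0.0, 0.05)
                else:
                    mode = rng.integers(3)
                    l2 = (_signed(rng, rng.uniform(0.0, math.log2(1.2) * 0.98))
                          if mode in (0, 2) else _signed(rng, rng.uniform(math.log2(1.2), 2.0)))
                    fdr = (rng.uniform(0.051, 1.0)
                           if mode in (1, 2) else rng.uniform(0.0, 0.05))
                rows.append(DEGRow(gene=g, fc=2.0 ** l2, p_adj=fdr))
            elif dialect == "pham":
                # |log2FC| >= 1; no p criterion. Day labels split the table.
                if is_deg:
                    l2 = _signed(rng, rng.uniform(1.0, 3.0))
                else:
                    l2 = _signed(rng, rng.uniform(0.0, 0.99))
                day = "HA1" if rng.random() < 0.5 else "HA3"
                rows.append(DEGRow(gene=g, log2fc=l2, p=rng.uniform(0, 1),
                                   p_adj=rng.uniform(0, 1), contrast=day))
            elif dialect == "manella":
                # q < 0.01 (strict) and |log2FC| > 0.5 (strict).
                if is_deg:
                    l2 = _signed(rng, rng.uniform(0.51, 3.0))
                    padj = rng.uniform(0.0, 0.0099)
                else:
                    mode = rng.integers(3)
                    l2 = (_signed(rng, rng.uniform(0.0, 0.5))
                          if mode in (0, 2) else _signed(rng, rng.uniform(0.51, 3.0)))
                    padj = (rng.uniform(0.011, 1.0)
                            if mode in (1, 2) else rng.uniform(0.0, 0.0099))
                lfcse = rng.uniform(0.05, 0.3)
                rows.append(DEGRow(
                    gene=g, log2fc=l2, lfcse=lfcse, stat=l2 / lfcse,
                    base_mean=rng.uniform(10, 1000), p=padj / 2, p_adj=padj,
                    contrast=str(rng.choice(MANELLA_CONTRASTS)),
                ))
            else:  # pragma: no cover - blocked by SimConfig validation
                raise ValueError(f"unknown dialect {dialect!r}")
        tables[dialect] = rows
        truth.deg_sets[dialect] = true_genes
    return tables, truth


def gen_alias_table(
    cfg: SimConfig, panel: list[str] | None = None
) -> tuple[AliasTable, AliasTable, list[str], TruthSet]:
    """Alias tables plus a corrupted panel with its intended resolution.

    Returns ``(primary, secondary, corrupted_panel, truth)``. Corruption
    replaces a configured fraction of approved symbols with historical
    synonyms, case/whitespace damage, or LOC placeholders; LOC entries are
    resolvable only through the secondary table, except a configured
    sub-fraction left unresolvable everywhere.
    """
    rng = cfg.rng(_STREAM_ALIAS)
    approved = list(panel) if panel is not None else [f"GENE{i}" for i in range(cfg.panel_size)]
    n = len(approved)
    truth = TruthSet()

    primary_records, secondary_records = [], []
    for i, sym in enumerate(approved):
        biotype = "protein_coding" if rng.random() < 0.9 else "pseudogene"
        primary_records.append(AliasRecord(
            approved_symbol=sym, synonyms=(f"{sym}OLD",), biotype=biotype,
            description=f"synthetic locus {sym}",
            ensembl_id=f"ENSG{i:011d}", entrez_id=str(10000 + i),
        ))

    noise = cfg.alias_noise
    order = rng.permutation(n)
    n_syn = int(round(noise.get("synonym", 0.0) * n))
    n_case = int(round(noise.get("case", 0.0) * n))
    n_loc = int(round(noise.get("loc", 0.0) * n))
    syn_idx = set(order[:n_syn])
    case_idx = set(order[n_syn:n_syn + n_case])
    loc_idx = list(order[n_syn + n_case:n_syn + n_case + n_loc])
    n_loc_dead = int(round(noise.get("loc_unresolvable", 0.0) * len(loc_idx)))
    dead_loc = set(loc_idx[:n_loc_dead])

    corrupted: list[str] = []
    for i, sym in enumerate(approved):
        if i in syn_idx:
            raw, route, target = f"{sym}OLD", "synonym", sym
        elif i in case_idx:
            raw, route, target = f"  {sym.lower()} ", "approved", sym
        elif i in loc_idx:
            raw = f"LOC{100000 + i}"
            if i in dead_loc:
                route, target = "unmapped", None
            else:
                route, target = "second_pass", sym
                secondary_records.append(AliasRecord(
                    approved_symbol=sym, synonyms=(raw,),
                    biotype="pseudogene", description=f"second-pass entry for {sym}",
                ))
        else:
            raw, route, target = sym, "approved", sym
        corrupted.append(raw)
        truth.alias_map[raw] = target
        truth.alias_routes[raw] = route

    if not secondary_records:  # keep the table constructible
        secondary_records.append(AliasRecord(approved_symbol="__SENTINEL__"))
    return (AliasTable(primary_records), AliasTable(secondary_records),
            corrupted, truth)


def gen_annotations(
    cfg: SimConfig,
    universe: list[str],
    input_genes: list[str] | None = None,
) -> tuple[AnnotationSet, TruthSet]:
    """Random term annotations, with planted terms enriched by construction.

    Random terms are uniform subsets of the universe; each planted term
    draws ``planted_term_input_fraction`` of its genes from ``input_genes``
    (so it is truly over-represented there) and the rest from outside.
    """
    rng = cfg.rng(_STREAM_ANNOTATION)
    truth = TruthSet()
    lo, hi = cfg.term_size_range
    if hi > len(universe):
        raise ValueError("term sizes exceed universe size")
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for t in range(cfg.n_terms):
        size = int(rng.integers(lo, hi + 1))
        genes = frozenset(rng.choice(universe, size=size, replace=False))
        terms[f"T{t:04d}"] = (f"random term {t}", genes)
    if cfg.planted_terms:
        if input_genes is None:
            raise ValueError("planted terms require an input gene set")
        n_from_input = int(round(cfg.planted_term_input_fraction * cfg.planted_term_size))
        if n_from_input > len(input_genes):
            raise ValueError("planted term larger than input set")
        outside = [g for g in universe if g not in set(input_genes)]
        for t in range(cfg.planted_terms):
            tid = f"T_PLANTED{t:02d}"
            inside = rng.choice(input_genes, size=n_from_input, replace=False)
            rest = rng.choice(outside, size=cfg.planted_term_size - n_from_input,
                              replace=False)
            terms[tid] = (f"planted term {t}", frozenset(inside) | frozenset(rest))
            truth.enriched_terms.add(tid)
    return AnnotationSet(terms=terms), truth
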