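"""Declarative end-to-end orchestration of the specificity screen.

A single run configuration names every input file and parameter; the
pipeline then executes harmonise -> screen -> filter/union -> overlap ->
enrich, persisting each stage's outputs so every reported count can be
recomputed from the bundled intermediates. Re-running an unchanged
configuration reproduces identical outputs (the report embeds the
configuration hash and seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .degfilter import STUDY_THRESHOLDS, FilteredSet, altitude_union, filter_table
from .enrichment import build_universe, enrich
from .harmonise import harmonise_panel
from .io import (
    read_alias_tsv, read_deg_tsv, read_gene_list, read_gmt, read_summary_tsv,
    write_audit_tsv, write_enrichment_tsv, write_gene_list, write_summary_tsv,
    write_enrichment_tsv as _write_enrichment,  # noqa: F401 (re-export convenience)
)
from .overlap import GenePanel, derive_unique_panel, study_attribution, two_step_overlap
from .screen import ScreenConfig, screen_panel

__all__ = ["RunConfig", "ReportBundle", "StageError", "run_pipeline"]

log = logging.getLogger("eposcreen")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is carried for debugging."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class DEGTableSpec:
    study_id: str
    dialect: str
    path: str


@dataclass
class RunConfig:
    panel: str
    summary: str
    out_dir: str
    alias_primary: str | None = None
    alias_secondary: str | None = None
    deg_tables: list[DEGTableSpec] = field(default_factory=list)
    annotation: str | None = None
    universe_mode: str = "measured"
    universe_genes: str | None = None
    exclude_biotypes: tuple[str, ...] = ("pseudogene",)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        screen_raw = raw.pop("screen", {}) or {}
        degs = [DEGTableSpec(**d) for d in raw.pop("deg_tables", []) or []]
        cfg = cls(screen=ScreenConfig(**screen_raw), deg_tables=degs, **raw)
        return cfg

    def validate(self) -> None:
        paths = [self.panel, self.summary, self.alias_primary,
                 self.alias_secondary, self.annotation, self.universe_genes,
                 *[d.path for d in self.deg_tables]]
        for p in paths:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        ids = [d.study_id for d in self.deg_tables]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate study ids: {ids}")
        for d in self.deg_tables:
            if d.dialect not in STUDY_THRESHOLDS:
                raise ValueError(f"unknown dialect {d.dialect!r} for study {d.study_id}")

    def content_hash(self) -> str:
        blob = json.dumps({
            "panel": self.panel, "summary": self.summary,
            "alias_primary": self.alias_primary,
            "alias_secondary": self.alias_secondary,
            "deg_tables": [[d.study_id, d.dialect, d.path] for d in self.deg_tables],
            "annotation": self.annotation,
            "universe_mode": self.universe_mode,
            "universe_genes": self.universe_genes,
            "exclude_biotypes": list(self.exclude_biotypes),
            "screen": vars(self.screen), "seed": self.seed,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class ReportBundle:
    counts: dict
    outputs: dict[str, str]
    provenance: dict


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-tag with stage name
                raise StageError(name, exc) from exc
        return wrapped
    return deco


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Run every configured stage in order; see module docstring."""
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    outputs: dict[str, str] = {}

    # --- harmonise ---------------------------------------------------------
    @_stage("harmonise")
    def do_harmonise():
        raw_panel = read_gene_list(cfg.panel)
        if cfg.alias_primary is None:
            return sorted(set(raw_panel)), None, []
        primary = read_alias_tsv(cfg.alias_primary)
        secondary = read_alias_tsv(cfg.alias_secondary) if cfg.alias_secondary else None
        panel, audit, unmapped = harmonise_panel(raw_panel, primary, secondary)
        write_audit_tsv(audit, out / "harmonisation_audit.tsv")
        write_gene_list(unmapped, out / "unmapped.txt")
        outputs["harmonisation_audit"] = str(out / "harmonisation_audit.tsv")
        biotype_map = {r.resolved_symbol: r.biotype for r in audit if r.resolved_symbol}
        return panel.symbols, biotype_map, unmapped

    panel_symbols, biotype_map, unmapped = do_harmonise()
    counts["panel_size"] = len(panel_symbols)
    counts["unmapped"] = len(unmapped)
    log.info("harmonise: %d inputs -> %d symbols (%d unmapped)",
             counts["panel_size"] + counts["unmapped"], counts["panel_size"],
             counts["unmapped"])

    # --- screen ------------------------------------------------------------
    @_stage("screen")
    def do_screen():
        summary = read_summary_tsv(cfg.summary)
        result = screen_panel(panel_symbols, summary, cfg.screen)
        rows = []
        for g, s in result.statuses.items():
            rows.append({"gene": g, "status": s.status, "responsive": s.responsive,
                         "max_abs_d": s.max_abs_d,
                         "hit_modalities": ",".join(s.hit_modalities)})
        import pandas as pd
        pd.DataFrame(rows).to_csv(out / "screen.tsv", sep="\t", index=False,
                                  na_rep="NaN")
        (out / "screen_counts.json").write_text(
            json.dumps(result.counts, sort_keys=True, indent=1))
        outputs["screen"] = str(out / "screen.tsv")
        return result

    screen_result = do_screen()
    counts["screen"] = screen_result.counts
    log.info("screen: %s", counts["screen"])

    # --- filter / union ----------------------------------------------------
    @_stage("filter_degs")
    def do_filter():
        sets: list[FilteredSet] = []
        for spec in cfg.deg_tables:
            rows = read_deg_tsv(spec.path, spec.dialect)
            thr = STUDY_THRESHOLDS[spec.dialect]
            fs = filter_table(rows, thr)
            fs.study_id = spec.study_id
            sets.append(fs)
            write_gene_list(sorted(fs.genes), out / f"degs_{spec.study_id}.txt")
            log.info("filter: %s %d/%d rows pass", spec.study_id, len(fs.genes),
                     fs.n_rows)
        return sets

    filtered_sets = do_filter()
    alt_union, presence = altitude_union(filtered_sets)
    presence.to_csv(out / "altitude_presence.tsv", sep="\t")
    write_gene_list(sorted(alt_union), out / "altitude_union.txt")
    counts["altitude_union"] = len(alt_union)
    log.info("union: %d altitude-responsive genes", len(alt_union))

    # --- overlap -----------------------------------------------------------
    @_stage("overlap")
    def do_overlap():
        epo = GenePanel(name="epo", genes=set(panel_symbols))
        exercise = GenePanel(name="exercise", genes=screen_result.responsive_genes)
        ov = two_step_overlap(epo, filtered_sets, exercise)
        unique = derive_unique_panel(epo, alt_union, exercise)
        (out / "venn_regions.json").write_text(json.dumps(
            {k: sorted(v) for k, v in ov.region_genes.items()},
            sort_keys=True, indent=1))
        write_gene_list(sorted(unique.genes), out / "unique_panel.txt")
        attribution = None
        epo_alt = ov.pairwise(0, 1)
        if filtered_sets and epo_alt:
            attribution = study_attribution(
                epo_alt, {fs.study_id: fs.genes for fs in filtered_sets})
            import pandas as pd
            pd.DataFrame(attribution.rows,
                         columns=["category", "count", "note"]).to_csv(
                out / "attribution.tsv", sep="\t", index=False)
        return ov, unique, attribution

    ov, unique_panel, attribution = do_overlap()
    counts["venn_regions"] = ov.region_counts
    counts["epo_altitude_overlap"] = len(ov.pairwise(0, 1))
    counts["epo_exercise_overlap"] = len(ov.pairwise(0, 2))
    counts["unique_panel"] = len(unique_panel.genes)
    log.info("overlap: epo∩altitude=%d epo∩exercise=%d unique=%d",
             counts["epo_altitude_overlap"], counts["epo_exercise_overlap"],
             counts["unique_panel"])

    # --- enrich ------------------------------------------------------------
    if cfg.annotation is not None:
        @_stage("enrich")
        def do_enrich():
            annotation = read_gmt(cfg.annotation)
            if cfg.universe_genes is not None:
                uni_genes = read_gene_list(cfg.universe_genes)
            else:
                uni_genes = sorted({g for _, (_, gs) in annotation.terms.items()
                                    for g in gs})
            universe = build_universe(cfg.universe_mode, uni_genes)
            results, dropped = enrich(
                sorted(unique_panel.genes), annotation, universe,
                exclude_biotypes=set(cfg.exclude_biotypes),
                biotypes=biotype_map or {},
            )
            write_enrichment_tsv(results, out / "enrichment.tsv")
            return results, dropped

        results, dropped = do_enrich()
        counts["enrichment_terms_tested"] = len(results)
        counts["enrichment_input_dropped"] = len(dropped)
        counts["enrichment_significant"] = sum(r.p_adj <= 0.05 for r in results)
        log.info("enrich: %d terms tested, %d significant at FDR 0.05",
                 counts["enrichment_terms_tested"], counts["enrichment_significant"])

    provenance = {"config_hash": cfg.content_hash(), "seed": cfg.seed,
                  "version": __version__}
    report = ReportBundle(counts=counts, outputs=outputs, provenance=provenance)
    (out / "report.json").write_text(json.dumps(
        {"counts": counts, "provenance": provenance}, sort_keys=True, indent=1))
    return report
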