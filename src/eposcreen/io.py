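"""Readers and writers for every tabular schema the pipeline consumes.

All formats are plain text: TSV with a header row, GMT for gene sets,
newline-delimited gene lists, JSON for counts. Every writer/reader pair is a
round-trip identity, and a literal ``NaN`` in p-value columns survives both
directions (it encodes a non-computable test, which is information the
screening rule uses).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .degfilter import DEGRow
from .enrichment import AnnotationSet, EnrichmentResult
from .harmonise import AliasRecord, AliasTable, HarmonisationResult

__all__ = [
    "read_summary_tsv", "write_summary_tsv",
    "read_gene_list", "write_gene_list",
    "read_alias_tsv", "write_alias_tsv",
    "read_deg_tsv", "write_deg_tsv",
    "read_gmt", "write_gmt",
    "write_audit_tsv", "write_enrichment_tsv",
    "DEG_DIALECT_COLUMNS",
]

# Column contracts for the three DEG table dialects.
DEG_DIALECT_COLUMNS = {
    "sutehall": ("gene", "fc", "fdr"),
    "pham": ("gene", "log2fc", "p", "padj", "day_label"),
    "manella": ("gene", "base_mean", "log2fc", "lfcSE", "stat", "p", "padj",
                "contrast_label"),
}


def read_summary_tsv(path) -> pd.DataFrame:
    """Summary table: gene, <cond>_mean / <cond>_sd per condition, p."""
    df = pd.read_csv(path, sep="\t", index_col="gene", float_precision="round_trip")
    if "p" not in df.columns:
        raise ValueError(f"{path}: summary table lacks a 'p' column")
    return df


def write_summary_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep="NaN", index_label="gene", float_format="%.17g")


def read_gene_list(path) -> list[str]:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    genes = [ln for ln in lines if ln and not ln.startswith("#")]
    if not genes:
        warnings.warn(f"{path}: empty gene list", stacklevel=2)
    return genes


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


_ALIAS_COLUMNS = ("approved_symbol", "synonyms", "biotype", "description",
                  "ensembl_id", "entrez_id", "status")


def read_alias_tsv(path) -> AliasTable:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(_ALIAS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: alias table missing columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if not row.approved_symbol:
            raise ValueError(f"{path}, line {i}: empty approved_symbol")
        syns = tuple(s for s in row.synonyms.split("|") if s)
        records.append(AliasRecord(
            approved_symbol=row.approved_symbol, synonyms=syns,
            biotype=row.biotype, description=row.description,
            ensembl_id=row.ensembl_id, entrez_id=row.entrez_id,
            status=row.status or "approved",
        ))
    return AliasTable(records)


def write_alias_tsv(table: AliasTable, path) -> None:
    rows = [{
        "approved_symbol": r.approved_symbol,
        "synonyms": "|".join(r.synonyms),
        "biotype": r.biotype, "description": r.description,
        "ensembl_id": r.ensembl_id, "entrez_id": r.entrez_id,
        "status": r.status,
    } for r in table.records]
    pd.DataFrame(rows, columns=list(_ALIAS_COLUMNS)).to_csv(path, sep="\t", index=False)


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


def read_deg_tsv(path, dialect: str) -> list[DEGRow]:
    if dialect not in DEG_DIALECT_COLUMNS:
        raise ValueError(f"unknown DEG dialect {dialect!r}")
    cols = DEG_DIALECT_COLUMNS[dialect]
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: {dialect} table missing columns {sorted(missing)}")
    rows = []
    for i, rec in enumerate(df.to_dict("records"), start=2):
        try:
            if dialect == "sutehall":
                rows.append(DEGRow(gene=rec["gene"], fc=float(rec["fc"]),
                                   p_adj=_opt(rec["fdr"])))
            elif dialect == "pham":
                rows.append(DEGRow(gene=rec["gene"], log2fc=float(rec["log2fc"]),
                                   p=_opt(rec["p"]), p_adj=_opt(rec["padj"]),
                                   contrast=str(rec["day_label"])))
            else:
                rows.append(DEGRow(
                    gene=rec["gene"], base_mean=_opt(rec["base_mean"]),
                    log2fc=float(rec["log2fc"]), lfcse=_opt(rec["lfcSE"]),
                    stat=_opt(rec["stat"]), p=_opt(rec["p"]),
                    p_adj=_opt(rec["padj"]), contrast=str(rec["contrast_label"]),
                ))
        except (TypeError, ValueError, KeyError) as exc:
            raise ValueError(f"{path}, line {i}: malformed {dialect} row: {exc}") from exc
    return rows


def write_deg_tsv(rows: list[DEGRow], dialect: str, path) -> None:
    if dialect not in DEG_DIALECT_COLUMNS:
        raise ValueError(f"unknown DEG dialect {dialect!r}")
    recs = []
    for r in rows:
        if dialect == "sutehall":
            recs.append({"gene": r.gene, "fc": r.fc, "fdr": r.p_adj})
        elif dialect == "pham":
            recs.append({"gene": r.gene, "log2fc": r.log2fc, "p": r.p,
                         "padj": r.p_adj, "day_label": r.contrast})
        else:
            recs.append({"gene": r.gene, "base_mean": r.base_mean,
                         "log2fc": r.log2fc, "lfcSE": r.lfcse, "stat": r.stat,
                         "p": r.p, "padj": r.p_adj, "contrast_label": r.contrast})
    pd.DataFrame(recs, columns=list(DEG_DIALECT_COLUMNS[dialect])).to_csv(
        path, sep="\t", index=False, na_rep="NaN", float_format="%.17g")


def read_gmt(path) -> AnnotationSet:
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for i, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}, line {i}: GMT row needs term, description, >=1 gene")
        tid, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if tid in terms:
            raise ValueError(f"{path}, line {i}: duplicate term id {tid!r}")
        terms[tid] = (desc, frozenset(genes))
    return AnnotationSet(terms=terms)


def write_gmt(annotation: AnnotationSet, path) -> None:
    lines = []
    for tid in sorted(annotation.terms):
        desc, genes = annotation.terms[tid]
        lines.append("\t".join([tid, desc, *sorted(genes)]))
    Path(path).write_text("".join(f"{ln}\n" for ln in lines))


def write_audit_tsv(audit: list[HarmonisationResult], path) -> None:
    rows = [{
        "input_symbol": r.input_symbol, "cleaned_symbol": r.cleaned_symbol,
        "resolved_symbol": r.resolved_symbol or "", "route": r.route,
        "loc_placeholder": r.loc_placeholder, "ambiguous": r.ambiguous,
        "biotype": r.biotype, "description": r.description,
        "ensembl_id": r.ensembl_id, "entrez_id": r.entrez_id,
    } for r in audit]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_enrichment_tsv(results: list[EnrichmentResult], path) -> None:
    """Enrichment table with the conventional ORA output columns."""
    rows = [{
        "ID": r.term_id, "Description": r.name,
        "GeneRatio": f"{r.k}/{r.n}", "BgRatio": f"{r.K}/{r.N}",
        "RichFactor": r.rich_factor, "FoldEnrichment": r.fold_enrichment,
        "pvalue": r.p, "p.adjust": r.p_adj, "qvalue": r.q,
        "geneID": "/".join(r.genes), "Count": r.k,
    } for r in results]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NaN")
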