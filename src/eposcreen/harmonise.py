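"""Gene-symbol harmonisation against snapshot alias tables.

Raw identifiers from older candidate-gene lists use deprecated nomenclature
(historical aliases, provisional LOC placeholders). They are resolved to
approved symbols in two passes over supplied mapping tables: a primary table
(approved symbols, synonyms, biotype, description, stable IDs) and an
optional secondary table for identifiers the primary pass cannot place,
typically LOC placeholders with a later-assigned official name.

All matching is offline and table-driven so runs are reproducible; the
tables play the role live nomenclature services play in an interactive
workflow.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "AliasRecord",
    "AliasTable",
    "HarmonisationResult",
    "normalise_symbol",
    "resolve_symbol",
    "second_pass_resolve",
    "harmonise_panel",
]

_LOC_RE = re.compile(r"^LOC\d+$")


@dataclass(frozen=True)
class AliasRecord:
    approved_symbol: str
    synonyms: tuple[str, ...] = ()
    biotype: str = ""
    description: str = ""
    ensembl_id: str = ""
    entrez_id: str = ""
    status: str = "approved"


class AliasTable:
    """Indexed collection of alias records.

    Approved symbols are unique; a synonym may point at several approved
    symbols (ambiguity is data, resolved by the priority tiers in
    :func:`resolve_symbol`).
    """

    def __init__(self, records: list[AliasRecord]):
        self.records = list(records)
        self._by_approved: dict[str, AliasRecord] = {}
        self._by_synonym: dict[str, list[AliasRecord]] = {}
        for rec in self.records:
            key = rec.approved_symbol.upper()
            if key in self._by_approved:
                raise ValueError(f"duplicate approved symbol: {rec.approved_symbol}")
            self._by_approved[key] = rec
        for rec in self.records:
            for syn in rec.synonyms:
                self._by_synonym.setdefault(syn.upper(), []).append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def approved(self, key: str) -> AliasRecord | None:
        return self._by_approved.get(key.upper())

    def synonym_candidates(self, key: str) -> list[AliasRecord]:
        return list(self._by_synonym.get(key.upper(), []))


@dataclass
class HarmonisationResult:
    input_symbol: str
    cleaned_symbol: str
    resolved_symbol: str | None
    route: str  # approved | synonym | second_pass | unmapped
    loc_placeholder: bool = False
    ambiguous: bool = False
    biotype: str = ""
    description: str = ""
    ensembl_id: str = ""
    entrez_id: str = ""

    def _fill_metadata(self, rec: AliasRecord) -> None:
        self.biotype = rec.biotype
        self.description = rec.description
        self.ensembl_id = rec.ensembl_id
        self.entrez_id = rec.entrez_id


def normalise_symbol(raw: str) -> tuple[str, bool]:
    """Clean a raw identifier: trim, uppercase matching key, flag LOC ids.

    Returns ``(cleaned, loc_placeholder)``. Empty / whitespace-only input is
    an error rather than a silent unmapped entry.
    """
    cleaned = raw.strip().upper()
    if not cleaned:
        raise ValueError(f"invalid gene symbol: {raw!r}")
    return cleaned, bool(_LOC_RE.match(cleaned))


def resolve_symbol(cleaned: str, table: AliasTable) -> HarmonisationResult:
    """Resolve one cleaned symbol against the primary table.

    An exact approved-symbol match always wins. Otherwise synonym candidates
    are narrowed through total priority tiers -- protein_coding biotype, then
    non-empty description, then lexicographically smallest approved symbol --
    and ``ambiguous`` is set whenever more than one candidate entered the
    final tie-break. Unresolved symbols return ``route="unmapped"``.
    """
    loc = bool(_LOC_RE.match(cleaned))
    res = HarmonisationResult(
        input_symbol=cleaned, cleaned_symbol=cleaned,
        resolved_symbol=None, route="unmapped", loc_placeholder=loc,
    )
    rec = table.approved(cleaned)
    if rec is not None:
        res.resolved_symbol = rec.approved_symbol
        res.route = "approved"
        res._fill_metadata(rec)
        return res
    cands = table.synonym_candidates(cleaned)
    if not cands:
        return res
    res.ambiguous = len(cands) > 1
    tier = [c for c in cands if c.biotype == "protein_coding"] or cands
    tier = [c for c in tier if c.description] or tier
    best = min(tier, key=lambda c: c.approved_symbol)
    res.resolved_symbol = best.approved_symbol
    res.route = "synonym"
    res._fill_metadata(best)
    return res


def second_pass_resolve(
    unresolved: list[HarmonisationResult],
    secondary_table: AliasTable,
    primary_table: AliasTable,
) -> list[HarmonisationResult]:
    """Re-query unmapped entries (typically LOC placeholders) in a secondary table.

    A hit that yields a non-LOC official symbol becomes ``route="second_pass"``;
    metadata is re-populated from the primary table when the official symbol
    exists there, otherwise from the secondary record. Entries persisting
    unresolved stay ``unmapped``.
    """
    out = []
    for res in unresolved:
        if res.route != "unmapped":
            raise ValueError("second_pass_resolve expects route='unmapped' inputs")
        hit = secondary_table.approved(res.cleaned_symbol)
        if hit is None:
            cands = secondary_table.synonym_candidates(res.cleaned_symbol)
            if cands:
                res.ambiguous = res.ambiguous or len(cands) > 1
                tier = [c for c in cands if c.biotype == "protein_coding"] or cands
                tier = [c for c in tier if c.description] or tier
                hit = min(tier, key=lambda c: c.approved_symbol)
        if hit is not None and not _LOC_RE.match(hit.approved_symbol.upper()):
            res.resolved_symbol = hit.approved_symbol
            res.route = "second_pass"
            primary_rec = primary_table.approved(hit.approved_symbol)
            res._fill_metadata(primary_rec if primary_rec is not None else hit)
        out.append(res)
    return out


@dataclass
class HarmonisedPanel:
    """Resolved panel: unique symbols with per-symbol input provenance."""

    symbols: list[str]
    provenance: dict[str, set[str]] = field(default_factory=dict)


def harmonise_panel(
    panel: list[str],
    primary_table: AliasTable,
    secondary_table: AliasTable | None = None,
) -> tuple[HarmonisedPanel, list[HarmonisationResult], list[str]]:
    """Resolve every panel symbol; collapse post-resolution duplicates.

    Returns ``(harmonised_panel, audit_log, unmapped)``. The audit log has one
    row per input in input order; two inputs resolving to the same approved
    symbol collapse into one panel entry whose provenance is the union of the
    raw inputs. Symbols unresolved after both passes are listed in
    ``unmapped`` (and excluded from the panel).
    """
    if not panel:
        raise ValueError("panel is empty")
    audit: list[HarmonisationResult] = []
    for raw in panel:
        cleaned, loc = normalise_symbol(raw)
        res = resolve_symbol(cleaned, primary_table)
        res.input_symbol = raw
        res.loc_placeholder = loc
        audit.append(res)
    if secondary_table is not None:
        pending = [r for r in audit if r.route == "unmapped"]
        second_pass_resolve(pending, secondary_table, primary_table)

    symbols: list[str] = []
    provenance: dict[str, set[str]] = {}
    unmapped: list[str] = []
    for res in audit:
        if res.resolved_symbol is None:
            unmapped.append(res.input_symbol)
            continue
        if res.resolved_symbol not in provenance:
            symbols.append(res.resolved_symbol)
            provenance[res.resolved_symbol] = set()
        provenance[res.resolved_symbol].add(res.input_symbol)
    # Deterministic panel order independent of input order.
    symbols = sorted(symbols)
    return HarmonisedPanel(symbols=symbols, provenance=provenance), audit, unmapped
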