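"""Loaders for the small reference tables shipped with the package."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _data_path(name: str):
    return resources.files("eposcreen.data").joinpath(name)


def load_candidate_screen_summary() -> pd.DataFrame:
    """GEPREP-reported expression summaries for rHuEPO-candidate genes.

    One row per candidate gene that reached the screening stage (omnibus
    p < 0.05 or NaN): per-modality normalised-expression mean and SD across
    six exercise conditions (sedentary control ``inactivity``) plus the
    omnibus p value, with ``NaN`` marking genes where zero within-group
    variance made the test non-computable. Indexed by gene symbol.
    """
    with resources.as_file(_data_path("geprep_candidate_screen.tsv")) as p:
        return pd.read_csv(p, sep="\t", index_col="gene", float_precision="round_trip")


def load_epo_specific_panel() -> pd.DataFrame:
    """The 50-gene rHuEPO-specific panel (confounder-free candidates).

    Columns: ``symbol`` (as reported, including LOC placeholders),
    ``ncbi_symbol`` (second-pass official name where one exists) and
    ``biotype`` (the five LOC/pseudogene entries are excluded from
    enrichment input by convention).
    """
    with resources.as_file(_data_path("epo_specific_panel.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype=str).fillna("")
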