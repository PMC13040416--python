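from pathlib import Path

import pandas as pd
import pytest

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def screen_summary() -> pd.DataFrame:
    """Packaged GEPREP-style summary table (candidate genes, six conditions)."""
    from eposcreen import load_candidate_screen_summary

    return load_candidate_screen_summary()


@pytest.fixture(scope="session")
def reference_effect_sizes() -> pd.DataFrame:
    """Published per-modality Cohen's d values for the screened candidates."""
    return pd.read_csv(DATA / "reference_effect_sizes.tsv", sep="\t",
                       index_col="gene")
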