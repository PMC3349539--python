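import pandas as pd
import pytest

from fflscape import (
    MOTIF_IDS,
    evolvability,
    load_reference_table,
    load_reference_transitions,
)
from fflscape.stats import score_table


@pytest.fixture(scope="session")
def reference_table():
    return load_reference_table()


@pytest.fixture(scope="session")
def reference_scores(reference_table):
    return score_table(reference_table)


@pytest.fixture(scope="session")
def reference_transitions():
    return load_reference_transitions()


@pytest.fixture(scope="session")
def reference_evolvability(reference_transitions):
    return pd.Series(
        {
            m: evolvability(
                reference_transitions[(m, "single")],
                reference_transitions[(m, "accumulated")],
            )
            for m in MOTIF_IDS
        }
    )
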