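from pathlib import Path

import pandas as pd
import pytest

from credimeta import load_aed_amstar2, load_aed_comparisons

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def comparisons():
    """The 23 packaged pooled genetic comparisons."""
    return load_aed_comparisons()


@pytest.fixture(scope="session")
def amstar_records():
    """The 32 packaged AMSTAR-2 item-response rows."""
    return load_aed_amstar2()


@pytest.fixture(scope="session")
def printed():
    """Printed FPRP/BFDP cells and Venice grades, keyed like the fixture."""
    df = pd.read_csv(DATA / "printed_credibility.tsv", sep="\t", comment="#",
                     keep_default_na=False)
    return df.set_index(["study", "variant", "contrast", "subgroup"])


def printed_row(printed, rec):
    return printed.loc[(rec.study, rec.variant, rec.contrast, rec.subgroup)]
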