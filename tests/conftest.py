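import pytest

import hetrank as hr


@pytest.fixture(scope="session")
def table2_records():
    """The bundled 25-case full-face reference cohort."""
    return hr.load_table2_cases()


@pytest.fixture(scope="session")
def table2_frame():
    """The raw reference table, including the printed expected columns."""
    return hr.load_fixture("table2")


@pytest.fixture(scope="session")
def scored_table2(table2_records):
    """(table, counts, percentages) from scoring the reference cohort."""
    return hr.score_cases(table2_records)
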