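import pytest

from calscreen import reference_data


@pytest.fixture(scope="session")
def panel():
    return reference_data.load_drug_panel()


@pytest.fixture(scope="session")
def panel_by_name(panel):
    return {r.name: r for r in panel}


@pytest.fixture(scope="session")
def sig_calls():
    return reference_data.load_significance_calls()


@pytest.fixture(scope="session")
def dose_summaries():
    return reference_data.load_dose_summaries()
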