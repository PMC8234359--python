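import pytest

from zfpk import (
    ExposureSummary,
    load_reference_aucs,
    load_reference_descriptors,
    load_reference_exposure,
)


@pytest.fixture(scope="session")
def descriptors():
    """The seven-dye descriptor panel."""
    return load_reference_descriptors()


@pytest.fixture(scope="session")
def reference_aucs():
    """Published per-compartment AUCs (RFU x 1e7) for both routes."""
    return load_reference_aucs()


@pytest.fixture(scope="session")
def reference_exposure_df():
    """Published RE/RD table, indexed by compound."""
    return load_reference_exposure()


@pytest.fixture(scope="session")
def reference_exposure_summaries(reference_exposure_df):
    """Published RE/RD values as ExposureSummary records."""
    return [
        ExposureSummary(
            compound=name,
            re_wb=float(row.re_wb),
            re_rob=float(row.re_rob),
            re_yolk=float(row.re_yolk),
            rd=float(row.rd),
        )
        for name, row in reference_exposure_df.iterrows()
    ]
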