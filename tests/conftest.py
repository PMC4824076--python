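import logging

import numpy as np
import pytest

from qpid import chipsim, quantify, refdata

logging.getLogger("qpid").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def pentamer_table():
    return chipsim.synth_pentamer_table(seed=7)


@pytest.fixture(scope="session")
def printed_curve():
    """Calibration curve with the reference slope/intercept."""
    return quantify.CalibrationCurve(
        refdata.CAL_SLOPE_RFU_PER_UM, refdata.CAL_INTERCEPT_RFU, refdata.CAL_N_POINTS, 1.0
    )


@pytest.fixture(scope="session")
def dilutions():
    return chipsim.make_dilution_series(
        refdata.DILUTION_START_UM, refdata.DILUTION_END_UM, refdata.DILUTION_N
    )


@pytest.fixture(scope="session")
def small_genome():
    return chipsim.synth_genome_and_peaks(100_000, 5, 20, seed=1)


@pytest.fixture(scope="session")
def library_genome():
    """Genome large enough to fill the 34/34/34/5 library quotas."""
    return chipsim.synth_genome_and_peaks(130_000, 14, 170, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
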