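import pytest

from stpsim import FreqLawCoefficients, TraceModel


@pytest.fixture(scope="session")
def law() -> FreqLawCoefficients:
    """Calibrated frequency-law coefficients (package defaults)."""
    return FreqLawCoefficients()


@pytest.fixture(scope="session")
def trace_model() -> TraceModel:
    return TraceModel()


#: Printed per-frequency parameter cells used as literal expectations in
#: tests: (frequency, f_D, k_D, f_F, k_F); ceiling I_F = 1.582, I_D = 1.
TABLE_ROWS = [
    (1.0, 0.0038, 0.676, 0.643, 0.521),
    (10.0, 0.013, 0.604, 0.435, 0.437),
    (20.0, 0.023, 0.537, 0.310, 0.370),
    (40.0, 0.043, 0.432, 0.189, 0.290),
    (50.0, 0.053, 0.391, 0.156, 0.267),
    (62.5, 0.065, 0.349, 0.127, 0.248),
    (80.0, 0.083, 0.304, 0.099, 0.231),
    (100.0, 0.103, 0.266, 0.075, 0.222),
    (125.0, 0.128, 0.234, 0.050, 0.216),
    (142.0, 0.145, 0.219, 0.034, 0.215),
]
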