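"""Shared fixtures: packaged example norms, printed reference values, and the
two exhaustive scans (binary, second-order ternary) reused across test files."""

from __future__ import annotations

import numpy as np
import pytest

from normscan import ErrorModel, ScanConfig, run_scan
from normscan.fixtures import all_fixtures

# printed stationary shares (h_B, h_N, h_G) and cooperation level per example
PRINTED_VALUES = {
    "c1p1r1": ((0.0015, 0.0005, 0.9980), 0.9980),
    "c1p1r2": ((0.0015, 0.0020, 0.9965), 0.9945),
    "c1p2r1": ((0.0015, 0.0020, 0.9965), 0.9945),
    "c1p2r2": ((0.0015, 0.0035, 0.9950), 0.9936),
    "c2p1r1": ((0.0015, 0.0212, 0.9773), 0.9985),
    "c2p1r2": ((0.0015, 0.0420, 0.9565), 0.9967),
    "c2p2r1": ((0.0015, 0.0427, 0.9558), 0.9966),
    "c2p2r2": ((0.0016, 0.0579, 0.9406), 0.9983),
    "c3p1r1": ((0.0015, 0.4985, 0.5000), 0.9985),
    "c3p1r2": ((0.0030, 0.4978, 0.4993), 0.9955),
    "c3p2r1": ((0.0030, 0.4981, 0.4989), 0.9970),
    "c3p2r2": ((0.0061, 0.3784, 0.6155), 0.9916),
}


@pytest.fixture(scope="session")
def fixtures_by_name():
    return all_fixtures()


@pytest.fixture(scope="session")
def err_1e3():
    return ErrorModel.tied(1e-3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230913)


@pytest.fixture(scope="session")
def binary_scan():
    """Exhaustive sweep of the binary norm space (one orbit representative each)."""
    return run_scan(ScanConfig(scope="binary_full"))


@pytest.fixture(scope="session")
def second_order_scan():
    """Exhaustive sweep of the 5832 second-order ternary norms, classified."""
    return run_scan(ScanConfig(scope="ternary_second_order", classify=True))
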