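"""Shared fixtures: the calibrated spectrum and cached Monte Carlo kernels.

The Monte Carlo grids are session-scoped so the dosimetry and acceptance
tests share one transport run per geometry.  History counts are chosen so
the statistical error on windowed peak/valley estimates is a few percent
while the whole suite stays fast.
"""

import pytest

from interbeam import spectrum as sp
from interbeam import transport as tr


@pytest.fixture(scope="session")
def spectrum107():
    return sp.calibrated_spectrum()


@pytest.fixture(scope="session")
def rat_grid(spectrum107):
    cfg = tr.TransportConfig(n_histories=3_000_000, seed=42)
    return tr.simulate_single_microbeam(tr.RAT_PHANTOM, tr.MicrobeamSpec(),
                                        spectrum107, cfg)


@pytest.fixture(scope="session")
def human_grid_2mm(spectrum107):
    cfg = tr.TransportConfig(n_histories=1_500_000, seed=43)
    return tr.simulate_single_microbeam(tr.HUMAN_PHANTOM,
                                        tr.MicrobeamSpec(50.0, 2.0),
                                        spectrum107, cfg)


@pytest.fixture(scope="session")
def human_grid_10mm(spectrum107):
    cfg = tr.TransportConfig(n_histories=2_000_000, seed=44)
    return tr.simulate_single_microbeam(tr.HUMAN_PHANTOM,
                                        tr.MicrobeamSpec(50.0, 10.0),
                                        spectrum107, cfg)


@pytest.fixture(scope="session")
def human_grid_30mm(spectrum107):
    cfg = tr.TransportConfig(n_histories=800_000, seed=45)
    return tr.simulate_single_microbeam(tr.HUMAN_PHANTOM,
                                        tr.MicrobeamSpec(50.0, 30.0),
                                        spectrum107, cfg)


@pytest.fixture(scope="session")
def tiny_grid(spectrum107):
    """Small, fast rat run for determinism / conservation checks."""
    cfg = tr.TransportConfig(n_histories=50_000, seed=7)
    return tr.simulate_single_microbeam(tr.RAT_PHANTOM, tr.MicrobeamSpec(),
                                        spectrum107, cfg)
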