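import numpy as np
import pytest

from rotorlife.acquisition import AcquisitionConfig, DecayModel, make_gaussian_irf


@pytest.fixture(scope="session")
def cfg():
    """Default 80 MHz acquisition with 1024 bins (12.2 ps binning)."""
    return AcquisitionConfig(rep_rate_mhz=80.0, n_bins=1024)


@pytest.fixture(scope="session")
def cfg_fine():
    """Fine binning for closed-form phasor comparisons."""
    return AcquisitionConfig(rep_rate_mhz=80.0, n_bins=16384)


@pytest.fixture(scope="session")
def irf(cfg):
    """Gaussian IRF: 0.2 ns FWHM centred at 1 ns."""
    return make_gaussian_irf(0.2, 1.0, cfg)


@pytest.fixture(scope="session")
def delta_irf(cfg):
    """All IRF weight in the first bin (ideal excitation)."""
    from rotorlife.acquisition import IRFProfile

    w = np.zeros(cfg.n_bins)
    w[0] = 1.0
    return IRFProfile(bin_centers=cfg.bin_centers, weights=w)


@pytest.fixture(scope="session")
def mono_tau1():
    return DecayModel([(1.0, 1.0)])
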