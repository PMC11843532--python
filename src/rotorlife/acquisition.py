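"""TCSPC acquisition primitives: timing configuration, IRFs, decay models and
photon-count histograms.

Time-correlated single-photon counting (TCSPC) records, for each detected
photon, the delay since the last excitation pulse.  Accumulated over many
pulses this yields a histogram of counts per time bin spanning one laser
repetition period.  With a high-repetition-rate source (80 MHz -> 12.5 ns
period) fluorophores with lifetimes approaching the period do not fully decay
between pulses; the steady-state histogram therefore contains the geometric
sum of tails from all preceding pulses.  The forward model here treats that
carry-over exactly for exponential components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AcquisitionConfig",
    "IRFProfile",
    "DecayModel",
    "DecayHistogram",
    "make_gaussian_irf",
    "expected_curve",
    "simulate_decay",
    "sum_pixel_decays",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Timing of a periodic TCSPC acquisition.

    Parameters
    ----------
    rep_rate_mhz : float
        Pulsed-excitation repetition frequency in MHz (80 for a standard
        Ti:sapphire source).
    n_bins : int
        Number of histogram bins spanning one repetition period (>= 16).
    window_ns : float, optional
        Acquisition window in ns.  Defaults to one full period,
        ``1000 / rep_rate_mhz``.
    """

    rep_rate_mhz: float = 80.0
    n_bins: int = 4096
    window_ns: float | None = None

    def __post_init__(self) -> None:
        if self.rep_rate_mhz <= 0:
            raise ValueError("rep_rate_mhz must be positive")
        if self.n_bins < 16:
            raise ValueError("n_bins must be >= 16")
        if self.window_ns is None:
            object.__setattr__(self, "window_ns", 1000.0 / self.rep_rate_mhz)
        if self.window_ns <= 0:
            raise ValueError("window_ns must be positive")

    @property
    def angular_frequency(self) -> float:
        """Angular frequency omega = 2*pi*f in rad/ns."""
        return 2.0 * math.pi * self.rep_rate_mhz / 1000.0

    @property
    def period_ns(self) -> float:
        return 1000.0 / self.rep_rate_mhz

    @property
    def bin_width_ns(self) -> float:
        return self.window_ns / self.n_bins

    @property
    def bin_centers(self) -> np.ndarray:
        dt = self.bin_width_ns
        return (np.arange(self.n_bins) + 0.5) * dt


@dataclass(frozen=True)
class IRFProfile:
    """Instrument response function as a normalized discrete density.

    ``weights`` are unitless per-bin probabilities on the same binning as the
    acquisition config the IRF is used with; they must sum to 1.
    """

    bin_centers: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_centers", np.asarray(self.bin_centers, float))
        object.__setattr__(self, "weights", np.asarray(self.weights, float))
        if self.bin_centers.shape != self.weights.shape:
            raise ValueError("bin_centers and weights must have equal length")
        if np.any(self.weights < 0):
            raise ValueError("IRF weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("IRF weights must sum to 1 within 1e-12")

    @property
    def n_bins(self) -> int:
        return self.weights.size

    @property
    def peak_bin(self) -> int:
        return int(np.argmax(self.weights))


@dataclass(frozen=True)
class DecayModel:
    """Multi-exponential fluorescence decay: I(t) = sum_i alpha_i exp(-t/tau_i).

    Components are stored ordered by ascending lifetime.  Amplitudes are
    unitless and need not be normalized; the amplitude-weighted mean lifetime
    and phasor coordinates are invariant to their overall scale.
    """

    components: tuple[tuple[float, float], ...]

    def __init__(self, components: Sequence[tuple[float, float]]):
        comps = tuple(sorted(((float(a), float(t)) for a, t in components), key=lambda c: c[1]))
        if len(comps) < 1:
            raise ValueError("DecayModel needs at least one component")
        for a, t in comps:
            if a < 0:
                raise ValueError("amplitudes must be >= 0")
            if t <= 0:
                raise ValueError("lifetimes must be > 0")
        if not any(a > 0 for a, _ in comps):
            raise ValueError("at least one amplitude must be positive")
        object.__setattr__(self, "components", comps)

    @property
    def n(self) -> int:
        return len(self.components)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([a for a, _ in self.components])

    @property
    def lifetimes(self) -> np.ndarray:
        return np.array([t for _, t in self.components])

    def scaled(self, factor: float) -> "DecayModel":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return DecayModel([(a * factor, t) for a, t in self.components])

    def normalized(self) -> "DecayModel":
        total = float(self.amplitudes.sum())
        return self.scaled(1.0 / total)


@dataclass
class DecayHistogram:
    """Photon counts per time bin over one repetition period.

    ``counts`` are nonnegative; integer for measured/simulated data, but
    real-valued noiseless curves are accepted so analytic decays can flow
    through the same fitting and phasor paths.
    """

    bin_centers: np.ndarray
    counts: np.ndarray
    config: AcquisitionConfig
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, float)
        self.counts = np.asarray(self.counts)
        if self.counts.size != self.config.n_bins:
            raise ValueError("counts length must equal config.n_bins")
        if self.bin_centers.size != self.config.n_bins:
            raise ValueError("bin_centers length must equal config.n_bins")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin_centers must be strictly increasing")
        if self.bin_centers[0] < 0 or self.bin_centers[-1] >= self.config.window_ns:
            raise ValueError("bin_centers must span [0, window_ns)")

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())


def make_gaussian_irf(
    fwhm_ns: float, center_ns: float, config: AcquisitionConfig
) -> IRFProfile:
    """Discretized, normalized Gaussian IRF on the config's bins.

    A synthetic stand-in for a measured scatter IRF (e.g. the reflection of
    the excitation beam off a urea crystal): a narrow pulse of width
    ``fwhm_ns`` centred at ``center_ns``.
    """
    if fwhm_ns <= 0:
        raise ValueError("fwhm_ns must be positive")
    if not fwhm_ns < config.window_ns / 4:
        raise ValueError("fwhm_ns must be < window_ns/4")
    if not (0 <= center_ns < config.window_ns / 2):
        raise ValueError("center_ns must lie in [0, window_ns/2)")
    t = config.bin_centers
    sigma = fwhm_ns / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    w = np.exp(-0.5 * ((t - center_ns) / sigma) ** 2)
    w /= w.sum()
    return IRFProfile(bin_centers=t, weights=w)


def _periodic_exponential(tau: float, config: AcquisitionConfig) -> np.ndarray:
    """exp(-t/tau) wrapped over the repetition period.

    Summing the tails of all preceding pulses gives the geometric factor
    1/(1 - exp(-T/tau)); exact for an exponential under periodic excitation.
    """
    t = config.bin_centers
    period = config.period_ns
    return np.exp(-t / tau) / (1.0 - math.exp(-period / tau))


def expected_curve(
    model: DecayModel, irf: IRFProfile, config: AcquisitionConfig
) -> np.ndarray:
    """Noise-free expected counts per bin (unnormalized).

    Circular convolution of the periodically wrapped multi-exponential decay
    with the IRF density.  Circularity and the geometric pulse-tail sum
    together make the model exact for steady-state periodic excitation.
    """
    if irf.n_bins != config.n_bins:
        raise ValueError("IRF binning does not match the acquisition config")
    decay = np.zeros(config.n_bins)
    for a, tau in model.components:
        if a > 0:
            decay += a * _periodic_exponential(tau, config)
    curve = np.fft.irfft(np.fft.rfft(decay) * np.fft.rfft(irf.weights), n=config.n_bins)
    # convolution of nonnegative inputs; clip FFT round-off
    return np.maximum(curve, 0.0)


def simulate_decay(
    model: DecayModel,
    irf: IRFProfile,
    config: AcquisitionConfig,
    total_photons: int,
    seed: int,
    background: float = 0.0,
) -> DecayHistogram:
    """Draw a Poisson photon-count histogram with the model's expected shape.

    The expected curve is scaled so its sum equals ``total_photons`` (plus a
    flat ``background`` expectation per bin, default 0), then each bin is an
    independent Poisson draw.  Deterministic for a given ``seed``.
    """
    if total_photons < 0:
        raise ValueError("total_photons must be >= 0")
    rng = np.random.default_rng(seed)
    if total_photons == 0 and background == 0:
        counts = np.zeros(config.n_bins, dtype=np.int64)
    else:
        curve = expected_curve(model, irf, config)
        lam = curve * (total_photons / curve.sum()) if total_photons > 0 else np.zeros_like(curve)
        counts = rng.poisson(lam + background)
    return DecayHistogram(
        bin_centers=config.bin_centers,
        counts=counts,
        config=config,
        meta={"seed": seed, "total_photons": total_photons},
    )


def sum_pixel_decays(pixels: Sequence[DecayHistogram]) -> DecayHistogram:
    """Bin-wise sum of per-pixel decays, as done per FLIM image before fitting.

    All pixels must share one acquisition config.
    """
    if len(pixels) == 0:
        raise ValueError("need at least one pixel decay")
    cfg = pixels[0].config
    for p in pixels[1:]:
        if p.config != cfg:
            raise ValueError("all pixel decays must share one acquisition config")
    counts = np.sum([p.counts for p in pixels], axis=0)
    return DecayHistogram(
        bin_centers=cfg.bin_centers,
        counts=counts,
        config=cfg,
        meta={"n_pixels": len(pixels)},
    )
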