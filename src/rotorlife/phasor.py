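"""Phasor analysis of fluorescence decays.

The phasor transform maps a decay I(t) to the pair

    g = sum_k I(t_k) cos(omega t_k) / sum_k I(t_k)
    s = sum_k I(t_k) sin(omega t_k) / sum_k I(t_k)

evaluated at the first harmonic of the laser repetition frequency
(omega = 2*pi*f).  A single-exponential decay with lifetime tau maps onto the
"universal circle" of centre (1/2, 0) and radius 1/2 via the closed forms
g = 1/(1+(omega tau)^2), s = omega tau/(1+(omega tau)^2); any mixture of
lifetimes lands strictly inside the circle, at the intensity-weighted mean of
its components' phasors.  This makes the transform model-free: trajectories of
an aggregating sample can be read geometrically without choosing a number of
decay components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import DecayHistogram, DecayModel

__all__ = [
    "PhasorPoint",
    "phasor_from_histogram",
    "phasor_from_lifetime",
    "phasor_from_model",
    "mixture_phasor",
    "phasor_uncertainty",
    "universal_circle_distance",
]


@dataclass
class PhasorPoint:
    """A (g, s) phasor coordinate with optional 2-sigma half-width errors.

    ``g_err``/``s_err`` are ``None`` until estimated (e.g. by
    :func:`phasor_uncertainty`); estimated-but-zero is distinct from missing.
    """

    g: float
    s: float
    g_err: float | None = None
    s_err: float | None = None
    meta: dict = field(default_factory=dict)

    def with_errors(self, g_err: float, s_err: float) -> "PhasorPoint":
        return PhasorPoint(self.g, self.s, g_err, s_err, dict(self.meta))


def phasor_from_histogram(hist: DecayHistogram) -> PhasorPoint:
    """First-harmonic phasor of a count histogram (rectangle rule on bin centers).

    Uses omega from the histogram's acquisition config.  No IRF correction is
    applied; an optional monoexponential-reference calibration is available via
    :func:`calibrate_phasor`.
    """
    total = hist.counts.sum()
    if total <= 0:
        raise ValueError("histogram has zero total counts")
    omega = hist.config.angular_frequency
    t = hist.bin_centers
    g = float(np.sum(hist.counts * np.cos(omega * t)) / total)
    s = float(np.sum(hist.counts * np.sin(omega * t)) / total)
    return PhasorPoint(g=g, s=s, g_err=0.0, s_err=0.0, meta=dict(hist.meta))


def phasor_from_lifetime(tau: float, omega: float) -> PhasorPoint:
    """Closed-form phasor of a single-exponential decay.

    g = 1/(1+(omega*tau)^2), s = omega*tau/(1+(omega*tau)^2): the locus of
    these points over tau >= 0 is the universal circle.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if omega <= 0:
        raise ValueError("omega must be > 0")
    wt = omega * tau
    denom = 1.0 + wt * wt
    return PhasorPoint(g=1.0 / denom, s=wt / denom, g_err=0.0, s_err=0.0)


def mixture_phasor(
    points: list[PhasorPoint], intensity_weights: np.ndarray | list[float]
) -> PhasorPoint:
    """Intensity-weighted mean phasor of component phasors.

    Phasor algebra is linear in intensity: a decay that is a sum of components
    has the weighted-mean phasor of the components, with each component's
    weight equal to its integrated intensity (alpha_i * tau_i for exponential
    components).
    """
    w = np.asarray(intensity_weights, float)
    if w.size != len(points):
        raise ValueError("one weight per point required")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must sum to a positive value")
    g = float(np.sum(w * np.array([p.g for p in points])) / total)
    s = float(np.sum(w * np.array([p.s for p in points])) / total)
    return PhasorPoint(g=g, s=s, g_err=0.0, s_err=0.0)


def phasor_from_model(model: DecayModel, omega: float) -> PhasorPoint:
    """Exact phasor of a multi-exponential model via alpha_i*tau_i-weighted mixing."""
    pts = [phasor_from_lifetime(t, omega) for _, t in model.components]
    weights = [a * t for a, t in model.components]
    return mixture_phasor(pts, weights)


def phasor_uncertainty(
    hist: DecayHistogram, n_replicates: int = 50, seed: int = 0
) -> PhasorPoint:
    """Phasor with 2-sigma errors from parametric Poisson resampling.

    Replicate histograms are drawn with per-bin Poisson means equal to the
    observed counts — a parametric stand-in for technical repeats — and
    ``g_err``/``s_err`` are set to twice the standard deviation of the
    replicate phasors.  The centre is the observed phasor, not the replicate
    mean.
    """
    if n_replicates < 10:
        raise ValueError("n_replicates must be >= 10")
    centre = phasor_from_histogram(hist)
    rng = np.random.default_rng(seed)
    gs = np.empty(n_replicates)
    ss = np.empty(n_replicates)
    for i in range(n_replicates):
        counts = rng.poisson(hist.counts.astype(float))
        rep = DecayHistogram(hist.bin_centers, counts, hist.config)
        p = phasor_from_histogram(rep)
        gs[i], ss[i] = p.g, p.s
    return PhasorPoint(
        g=centre.g,
        s=centre.s,
        g_err=2.0 * float(gs.std(ddof=1)),
        s_err=2.0 * float(ss.std(ddof=1)),
        meta=dict(hist.meta),
    )


def universal_circle_distance(p: PhasorPoint) -> float:
    """Euclidean distance of (g, s) from the universal-circle centre (1/2, 0).

    0.5 for single-exponential decays; < 0.5 for mixtures.
    """
    return float(np.hypot(p.g - 0.5, p.s))


def calibrate_phasor(p: PhasorPoint, tau_ref: float, measured_ref: PhasorPoint, omega: float) -> PhasorPoint:
    """Reference calibration: rotate/scale by a known monoexponential standard.

    Divides the measured phasor by the measured reference in the complex plane
    and multiplies by the reference's theoretical phasor.  Off by default in
    all pipelines; flagged in metadata when applied.
    """
    z = complex(p.g, p.s)
    z_meas = complex(measured_ref.g, measured_ref.s)
    ref = phasor_from_lifetime(tau_ref, omega)
    z_true = complex(ref.g, ref.s)
    if z_meas == 0:
        raise ValueError("measured reference phasor is zero")
    out = z / z_meas * z_true
    meta = dict(p.meta)
    meta["calibrated_tau_ref_ns"] = tau_ref
    return PhasorPoint(out.real, out.imag, p.g_err, p.s_err, meta)
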