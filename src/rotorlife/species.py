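"""Synthetic aggregation experiments: species kinetics and their optical readout.

Alpha-synuclein aggregation is represented by a minimal sequential scheme

    monomer --k1--> Type-A oligomer --k2--> Type-B oligomer --k3--> fibril

with an optional autocatalytic feedback term ke*M*F accelerating monomer
consumption once fibrils exist.  Type-A oligomers are the early, low
beta-sheet species; Type-B the late, beta-sheet-rich species that structurally
resemble stabilized oligomers; fibrils form last.  The scheme is
phenomenological: rates are free preset parameters chosen to emulate the
characteristic kinetics of wild-type and variant alpha-synuclein, not fitted
to any experiment.

Each species carries an optical profile: a molecular-rotor decay signature
(monomers leave the rotor in a nonviscous environment -> short lifetime;
oligomers and fibrils progressively confine it -> longer, multi-component
decays), a photon weight (detected FLIM photons per uM) and a plate-reader
brightness (dominated by fibrils, producing the classic sigmoidal
intensity curve).  A mixture of species maps to a decay model by a
photon-weighted union of components — the readout carries no information
about which species contributed which photon, which is exactly why phasor
analysis is needed downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .acquisition import (
    AcquisitionConfig,
    DecayHistogram,
    DecayModel,
    IRFProfile,
    make_gaussian_irf,
    simulate_decay,
)
from .fit import amplitude_weighted_lifetime

__all__ = [
    "SPECIES",
    "SpeciesState",
    "SpeciesOpticalProfile",
    "KineticParams",
    "AggregationTrace",
    "integrate_kinetics",
    "species_to_decay",
    "species_to_intensity",
    "simulate_experiment",
    "preset",
    "PRESET_NAMES",
]

SPECIES = ("monomer", "type_a", "type_b", "fibril")


@dataclass(frozen=True)
class KineticParams:
    """Rates of the sequential scheme, all in 1/h (ke in 1/h/uM).

    k1: monomer -> Type-A; k2: Type-A -> Type-B; k3: Type-B -> fibril;
    ke: optional autocatalytic monomer consumption by fibrils (default 0).
    """

    k1: float
    k2: float
    k3: float
    ke: float = 0.0

    def __post_init__(self) -> None:
        if min(self.k1, self.k2, self.k3, self.ke) < 0:
            raise ValueError("all rates must be >= 0")


@dataclass
class SpeciesState:
    """Concentrations (uM, monomer equivalents) of each species at one time."""

    time_h: float
    concentrations: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(SPECIES) - set(self.concentrations)
        if missing:
            raise ValueError(f"missing species {missing}")
        if min(self.concentrations.values()) < -1e-12:
            raise ValueError("concentrations must be nonnegative")

    @property
    def total(self) -> float:
        return float(sum(self.concentrations.values()))


@dataclass(frozen=True)
class SpeciesOpticalProfile:
    """Per-species rotor decay signature, photon weight and brightness.

    ``photon_weights`` give the relative probability that a detected FLIM
    photon originated from 1 uM of that species; ``brightness`` the
    plate-reader signal per uM.
    """

    decays: dict[str, DecayModel]
    photon_weights: dict[str, float]
    brightness: dict[str, float]

    def __post_init__(self) -> None:
        for table in (self.decays, self.photon_weights, self.brightness):
            missing = set(SPECIES) - set(table)
            if missing:
                raise ValueError(f"missing species {missing}")
        if min(self.photon_weights.values()) < 0 or min(self.brightness.values()) < 0:
            raise ValueError("weights and brightness must be nonnegative")


def _rates(params: KineticParams, y: np.ndarray) -> np.ndarray:
    m, a, b, f = y
    dm = -params.k1 * m - params.ke * m * f
    da = params.k1 * m + params.ke * m * f - params.k2 * a
    db = params.k2 * a - params.k3 * b
    df = params.k3 * b
    return np.array([dm, da, db, df])


def integrate_kinetics(
    params: KineticParams, m0: float, timepoints: np.ndarray | list[float]
) -> list[SpeciesState]:
    """Integrate the scheme from M(0)=m0 with fixed-step RK4.

    The step is capped at 0.01/max-rate so that the smooth, non-stiff system
    is resolved far below truncation error; mass (M+A+B+F) is conserved by
    construction of the rate equations and checked on output.
    """
    if m0 <= 0:
        raise ValueError("m0 must be positive")
    tp = np.asarray(timepoints, float)
    if tp.size == 0:
        raise ValueError("need at least one timepoint")
    if np.any(tp < 0) or np.any(np.diff(tp) < 0):
        raise ValueError("timepoints must be sorted and nonnegative")
    max_rate = max(params.k1, params.k2, params.k3, params.ke * m0, 1e-12)
    h_max = 0.01 / max_rate

    y = np.array([m0, 0.0, 0.0, 0.0])
    t = 0.0
    out: list[SpeciesState] = []
    for target in tp:
        span = target - t
        if span > 0:
            n_steps = max(int(math.ceil(span / h_max)), 1)
            h = span / n_steps
            for _ in range(n_steps):
                k1 = _rates(params, y)
                k2 = _rates(params, y + 0.5 * h * k1)
                k3 = _rates(params, y + 0.5 * h * k2)
                k4 = _rates(params, y + h * k3)
                y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t = target
        y = np.maximum(y, 0.0)
        if abs(y.sum() - m0) > 1e-6 * m0:
            raise RuntimeError("mass conservation violated beyond 1e-6 relative")
        out.append(SpeciesState(time_h=float(target), concentrations=dict(zip(SPECIES, y))))
    return out


def species_to_decay(state: SpeciesState, profile: SpeciesOpticalProfile) -> DecayModel:
    """Map a species mixture to one rotor decay model.

    Each species contributes its decay components with amplitudes scaled by
    concentration x photon weight; components at identical lifetimes merge;
    the result is renormalized to sum(alpha) = 1.
    """
    contrib: dict[float, float] = {}
    for sp in SPECIES:
        scale = state.concentrations[sp] * profile.photon_weights[sp]
        if scale <= 0:
            continue
        model = profile.decays[sp].normalized()
        for a, tau in model.components:
            contrib[tau] = contrib.get(tau, 0.0) + scale * a
    total = sum(contrib.values())
    if total <= 0:
        raise ValueError("no species contributes photons in this state")
    return DecayModel([(a / total, tau) for tau, a in contrib.items()])


def species_to_intensity(state: SpeciesState, profile: SpeciesOpticalProfile) -> float:
    """Bulk (plate-reader) intensity: sum of concentration x brightness."""
    return float(
        sum(state.concentrations[sp] * profile.brightness[sp] for sp in SPECIES)
    )


@dataclass
class AggregationTrace:
    """Time course of one synthetic aggregation run.

    ``tau_m_model`` is the exact amplitude-weighted lifetime of the underlying
    mixture model (the noiseless lifetime channel); ``tau_m`` is filled by the
    fitting stage of a pipeline run.  ``decays`` is None for noiseless runs
    (no photon budget).
    """

    time_h: np.ndarray
    states: list[SpeciesState]
    models: list[DecayModel]
    intensity: np.ndarray
    tau_m_model: np.ndarray
    decays: list[DecayHistogram] | None = None
    tau_m: np.ndarray | None = None
    phasors: list | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.time_h.size
        if not (len(self.states) == len(self.models) == self.intensity.size == self.tau_m_model.size == n):
            raise ValueError("all trace series must share the time axis")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be nonnegative")

    @property
    def n_timepoints(self) -> int:
        return int(self.time_h.size)


def simulate_experiment(
    params: KineticParams,
    profile: SpeciesOpticalProfile,
    timepoints: np.ndarray | list[float],
    config: AcquisitionConfig | None = None,
    photons_per_timepoint: int | None = 100_000,
    seed: int = 0,
    m0: float = 100.0,
    irf: IRFProfile | None = None,
    intensity_noise_sigma: float = 0.0,
) -> AggregationTrace:
    """End-to-end synthetic aggregation experiment.

    Per timepoint: integrate the kinetics, build the mixture decay model and
    bulk intensity, and (if ``photons_per_timepoint`` is set) draw a Poisson
    TCSPC histogram.  Sub-seeds fan out from ``seed`` by a counter scheme:
    timepoint i uses ``SeedSequence([seed, i])``; the intensity-noise stream
    uses ``SeedSequence([seed, 999983])``.  The intensity channel is noiseless
    unless ``intensity_noise_sigma`` > 0 (lognormal multiplicative noise).
    """
    config = config or AcquisitionConfig()
    tp = np.asarray(timepoints, float)
    states = integrate_kinetics(params, m0, tp)
    models = [species_to_decay(st, profile) for st in states]
    intensity = np.array([species_to_intensity(st, profile) for st in states])
    tau_m_model = np.array([amplitude_weighted_lifetime(m) for m in models])

    decays = None
    if photons_per_timepoint:
        irf = irf or make_gaussian_irf(0.2, 1.0, config)
        decays = []
        for i, model in enumerate(models):
            sub = np.random.SeedSequence([seed, i])
            h = simulate_decay(model, irf, config, photons_per_timepoint, seed=sub)
            h.meta.update(timepoint_index=i, time_h=float(tp[i]))
            decays.append(h)
    if intensity_noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 999983]))
        intensity = intensity * rng.lognormal(0.0, intensity_noise_sigma, intensity.size)

    return AggregationTrace(
        time_h=tp,
        states=states,
        models=models,
        intensity=intensity,
        tau_m_model=tau_m_model,
        decays=decays,
        meta={"seed": seed, "m0_uM": m0, "photons_per_timepoint": photons_per_timepoint},
    )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

# ThT-like rotor signatures.  Monomeric protein leaves the rotor free in
# solution (single short component); Type-A oligomers confine it mildly;
# Type-B oligomers and fibrils give progressively longer, two-component
# decays.  Photon weights grow with confinement (rotor quantum yield rises);
# plate-reader brightness is dominated by fibrils (amyloid switch-on).
_THT_LIKE_PROFILE = SpeciesOpticalProfile(
    decays={
        "monomer": DecayModel([(1.0, 0.07)]),
        "type_a": DecayModel([(1.0, 0.25)]),
        "type_b": DecayModel([(0.5, 0.25), (0.5, 0.9)]),
        "fibril": DecayModel([(0.4, 0.5), (0.6, 2.0)]),
    },
    photon_weights={"monomer": 1.0, "type_a": 2.0, "type_b": 9.0, "fibril": 14.0},
    brightness={"monomer": 0.02, "type_a": 0.02, "type_b": 0.06, "fibril": 1.0},
)

# All presets share a weak autocatalytic feedback (ke): primary oligomer
# formation (k1) seeds the pathway slowly, and fibril-catalysed monomer
# consumption then drives a lag + sharp-sigmoid conversion, the
# characteristic shape of nucleated amyloid growth.
#
# Wild-type-like: oligomers detectable within the first ~2-3 h (early
# lifetime onset) and fibril-driven intensity half-rise near ~25 h.
_WT_PARAMS = KineticParams(k1=0.006, k2=2.0, k3=0.02, ke=0.03)
# A30P-like: identical oligomer formation, 4x slower oligomer->fibril
# conversion -- lifetime onset unchanged, intensity t50 strongly delayed.
_A30P_PARAMS = KineticParams(k1=0.006, k2=2.0, k3=0.005, ke=0.03)
# dP1-like (P1-region deletion): strongly delayed oligomer formation
# (much smaller k1, smaller k2) and much slower conversion (much smaller
# k3) -- both channels delayed, the intensity channel more so.
_DP1_PARAMS = KineticParams(k1=5e-5, k2=0.07, k3=0.005, ke=0.03)

_PRESETS = {
    "wt_like": _WT_PARAMS,
    "a30p_like": _A30P_PARAMS,
    "dp1_like": _DP1_PARAMS,
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str) -> tuple[KineticParams, SpeciesOpticalProfile]:
    """Kinetic parameters and optical profile for a named phenotype.

    Known names: ``wt_like``, ``a30p_like``, ``dp1_like``.
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; known: {sorted(_PRESETS)}")
    return _PRESETS[name], _THT_LIKE_PROFILE
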