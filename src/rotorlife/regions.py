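"""Reference-overlap classification of phasor trajectories.

An aggregation trajectory in phasor space is compared against reference
phasor sets measured (here: simulated) for pure-species titrations — rotor +
preformed fibrils, and rotor + stabilized oligomers (the structural analogue
of Type-B oligomers).  Classification follows an error-bar overlap rule: two
points overlap when their 2-sigma error intervals intersect in BOTH the g and
s directions, and a trajectory segment belongs to a reference's region when
at least 60% of its points overlap some reference point.  Segments that
clearly deviate from both references are labelled Type-A oligomeric — the
early species structurally distinct from both stabilized oligomers and
fibrils.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import AcquisitionConfig, DecayModel, IRFProfile, make_gaussian_irf, simulate_decay
from .phasor import PhasorPoint, phasor_from_histogram
from .species import SpeciesOpticalProfile

__all__ = [
    "ReferencePhasorSet",
    "RegionLabel",
    "points_overlap",
    "overlap_fraction",
    "assign_regions",
    "build_reference_set",
    "OVERLAP_THRESHOLD",
    "DEVIATION_THRESHOLD",
]

OVERLAP_THRESHOLD = 0.60
DEVIATION_THRESHOLD = 0.40
LABELS = ("fibrillar", "type_b_oligomeric", "type_a_oligomeric", "unassigned")


@dataclass
class ReferencePhasorSet:
    """Titration phasors of one reference species, with 2-sigma errors."""

    label: str
    points: list[PhasorPoint]
    concentrations: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in ("fibril", "stabilized_oligomer"):
            raise ValueError("label must be 'fibril' or 'stabilized_oligomer'")
        if len(self.points) < 3:
            raise ValueError("a reference set needs at least 3 points")
        for p in self.points:
            if p.g_err is None or p.s_err is None or p.g_err <= 0 or p.s_err <= 0:
                raise ValueError("all reference points must carry positive errors")
        if self.concentrations and len(self.concentrations) != len(self.points):
            raise ValueError("one concentration per point required")


@dataclass
class RegionLabel:
    """Label of one contiguous trajectory segment.

    ``segment`` is a half-open index range [start, stop).  Both overlap
    fractions are always reported; ``tie`` flags a segment that qualified for
    both the fibrillar and Type-B regions (fibrillar wins).
    """

    segment: tuple[int, int]
    label: str
    overlap_fibril: float
    overlap_oligomer: float
    tie: bool = False

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        for frac in (self.overlap_fibril, self.overlap_oligomer):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("overlap fractions must lie in [0, 1]")


def points_overlap(p: PhasorPoint, q: PhasorPoint) -> bool:
    """True iff the error intervals intersect in both the g and s directions.

    Overlap in a single direction is not sufficient.
    """
    for pt in (p, q):
        if pt.g_err is None or pt.s_err is None:
            raise ValueError("both points must carry g and s errors")
    return (abs(p.g - q.g) <= p.g_err + q.g_err) and (abs(p.s - q.s) <= p.s_err + q.s_err)


def overlap_fraction(
    segment_points: list[PhasorPoint], reference: ReferencePhasorSet
) -> float:
    """Fraction of segment points overlapping at least one reference point."""
    if not segment_points:
        raise ValueError("segment must be non-empty")
    hits = sum(
        1
        for p in segment_points
        if any(points_overlap(p, q) for q in reference.points)
    )
    return hits / len(segment_points)


def _segments(n: int, window: int) -> list[tuple[int, int]]:
    """Contiguous [start, stop) windows with stride = window; a short remainder
    is merged into the last full segment."""
    bounds = list(range(0, n, window))
    segs = [(b, min(b + window, n)) for b in bounds]
    if len(segs) > 1 and segs[-1][1] - segs[-1][0] < window:
        last = segs.pop()
        segs[-1] = (segs[-1][0], last[1])
    return segs


def assign_regions(
    trajectory: list[PhasorPoint],
    fibril_ref: ReferencePhasorSet,
    oligomer_ref: ReferencePhasorSet | None = None,
    window: int = 5,
    threshold: float = OVERLAP_THRESHOLD,
    deviation_threshold: float = DEVIATION_THRESHOLD,
) -> list[RegionLabel]:
    """Partition a time-ordered phasor trajectory into labelled segments.

    Per segment of ``window`` consecutive points the overlap fraction against
    each reference is computed; the segment is *fibrillar* if the fibril
    fraction >= ``threshold``, else *Type-B oligomeric* if the stabilized-
    oligomer fraction >= ``threshold``, else *Type-A oligomeric* if BOTH
    fractions are <= ``deviation_threshold`` (clear deviation from both
    references), else *unassigned*.  When both fractions reach the threshold
    the fibrillar label wins and the tie is flagged — stabilized oligomers are
    known to partially overlap fibril phasors, so ambiguity is surfaced, not
    hidden.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    if len(trajectory) < window:
        raise ValueError("trajectory shorter than the window")
    labels: list[RegionLabel] = []
    for start, stop in _segments(len(trajectory), window):
        seg = trajectory[start:stop]
        f_frac = overlap_fraction(seg, fibril_ref)
        o_frac = overlap_fraction(seg, oligomer_ref) if oligomer_ref is not None else 0.0
        tie = False
        if f_frac >= threshold:
            label = "fibrillar"
            tie = o_frac >= threshold
        elif o_frac >= threshold:
            label = "type_b_oligomeric"
        elif f_frac <= deviation_threshold and o_frac <= deviation_threshold:
            label = "type_a_oligomeric"
        else:
            label = "unassigned"
        labels.append(
            RegionLabel(
                segment=(start, stop),
                label=label,
                overlap_fibril=f_frac,
                overlap_oligomer=o_frac,
                tie=tie,
            )
        )
    return labels


def _mixture_model(mono, target, frac: float) -> DecayModel:
    comps = [(a * (1 - frac), t) for a, t in mono.components if (1 - frac) * a > 0]
    comps += [(a * frac, t) for a, t in target.components if frac * a > 0]
    return DecayModel(comps)


#: default titration grids (photon fraction of the reference species).  The
#: fibril grid starts higher: at low fractions a fibril titration is optically
#: indistinguishable from free dye, and including such points would let the
#: monomeric head of a trajectory "overlap fibrils" spuriously.
FIBRIL_FRACTIONS = tuple(np.round(np.concatenate([np.arange(0.20, 1.0, 0.05), [1.0]]), 3))
OLIGOMER_FRACTIONS = tuple(np.round(np.concatenate([np.arange(0.12, 1.0, 0.05), [1.0]]), 3))


def build_reference_set(
    species: str,
    profile: SpeciesOpticalProfile,
    config: AcquisitionConfig,
    photon_fractions: tuple[float, ...] | None = None,
    photons: int = 100_000,
    n_replicates: int = 25,
    fraction_jitter: float = 0.1,
    tau_jitter: float = 0.05,
    seed: int = 0,
    irf: IRFProfile | None = None,
) -> ReferencePhasorSet:
    """Simulate a titration reference set from pure-species decay models.

    Emulates measuring the rotor with increasing concentrations of preformed
    fibrils (``species='fibril'``) or stabilized oligomers
    (``species='type_b'``): at each titration step a fraction of the detected
    photons comes from the reference species and the remainder from rotor
    free in solution (the monomer signature).

    Error bars are the 2-sigma scatter of simulated technical repeats.  Each
    repeat redraws the photon counts (Poisson), the reference-species photon
    fraction (lognormal with shape ``fraction_jitter``, emulating well-to-well
    pipetting and binding variability) and a common lifetime scale factor
    (lognormal with shape ``tau_jitter``, emulating temperature/viscosity and
    batch variation between repeats).  In realistic titrations these
    compositional and environmental terms dominate, so the error bars are
    much wider than shot noise alone — as in measured technical repeats.
    """
    if species not in ("fibril", "type_b"):
        raise ValueError("species must be 'fibril' or 'type_b'")
    if n_replicates < 10:
        raise ValueError("n_replicates must be >= 10")
    if photon_fractions is None:
        photon_fractions = FIBRIL_FRACTIONS if species == "fibril" else OLIGOMER_FRACTIONS
    label = "fibril" if species == "fibril" else "stabilized_oligomer"
    irf = irf or make_gaussian_irf(0.2, 1.0, config)
    mono = profile.decays["monomer"].normalized()
    target = profile.decays[species].normalized()
    points = []
    for i, frac in enumerate(photon_fractions):
        centre_hist = simulate_decay(
            _mixture_model(mono, target, frac), irf, config, photons,
            seed=np.random.SeedSequence([seed, i]),
        )
        centre = phasor_from_histogram(centre_hist)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1000 + i]))
        gs, ss = np.empty(n_replicates), np.empty(n_replicates)
        for r in range(n_replicates):
            f = min(frac * rng.lognormal(0.0, fraction_jitter), 1.0)
            tau_scale = rng.lognormal(0.0, tau_jitter)
            mono_r = DecayModel([(a, t * tau_scale) for a, t in mono.components])
            target_r = DecayModel([(a, t * tau_scale) for a, t in target.components])
            rep = simulate_decay(
                _mixture_model(mono_r, target_r, f), irf, config, photons,
                seed=np.random.SeedSequence([seed, 1000 + i, r]),
            )
            p = phasor_from_histogram(rep)
            gs[r], ss[r] = p.g, p.s
        point = PhasorPoint(
            g=centre.g,
            s=centre.s,
            g_err=2.0 * float(gs.std(ddof=1)),
            s_err=2.0 * float(ss.std(ddof=1)),
            meta={"reference": label, "photon_fraction": frac},
        )
        points.append(point)
    # pseudo-concentrations: photon fraction mapped to uM of reference species
    return ReferencePhasorSet(label=label, points=points, concentrations=list(photon_fractions))
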