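# rotorlife

Fluorescence-lifetime analysis of molecular-rotor probes during amyloid
aggregation: TCSPC decay simulation and fitting, phasor analysis, and
reference-overlap classification of aggregation trajectories.

## The problem

Thioflavin-T and related molecular rotors report on their local
microenvironment: free in solution their excited state relaxes quickly
through intramolecular rotation (lifetime of tens of picoseconds), while
crowding or binding by protein aggregates restricts that rotation and
lengthens the fluorescence lifetime. During α-synuclein aggregation the
amplitude-weighted mean lifetime of the rotor therefore rises hours before
the classical fibril-driven intensity increase, and the *shape* of the decay
carries information about which aggregate species — early Type-A oligomers,
β-sheet-rich Type-B oligomers, or mature fibrils — dominate the signal.

`rotorlife` implements that analysis end to end for time-correlated
single-photon-counting (TCSPC) data:

- **Decay model.** A measured histogram is fitted by reconvolution,

  `C(t) = [ Σᵢ αᵢ exp(−t/τᵢ) ] ⊛ IRF + b`,  n ∈ {1, 2, 3},

  with circular (periodic) convolution and exact geometric summation of
  incomplete decays between 80 MHz pulses, Neyman-weighted least squares,
  multi-start initialisation, and automatic model-order selection. The
  scalar readout is the amplitude-weighted mean lifetime
  `τ_m = Σ αᵢτᵢ / Σ αᵢ`.

- **Phasor analysis.** Each decay maps to
  `g = Σ I(t_k) cos(ωt_k) / Σ I(t_k)`, `s = Σ I(t_k) sin(ωt_k) / Σ I(t_k)`
  at the first harmonic of the laser repetition rate (ω = 2πf). Single
  exponentials obey `g = 1/(1+(ωτ)²)`, `s = ωτ/(1+(ωτ)²)` and lie on the
  universal circle of center (1/2, 0); mixtures lie strictly inside at
  intensity-weighted means. Uncertainties are 2σ parametric bootstrap.

- **Region classification.** Trajectories are compared against fibril and
  stabilized-oligomer titration references: two phasor points overlap when
  their 2σ error bars intersect in *both* the g and s directions, and a
  trajectory segment is assigned to a reference region when ≥ 60% of its
  points overlap that reference; clear deviation from both references marks
  the Type-A oligomeric region.

- **Kinetics.** Per-run descriptors (τ_m onset time, intensity lag and
  half-rise time t₅₀) and cross-variant deltas reproduce the characteristic
  phenotypes of wild-type, A30P (delayed oligomer→fibril conversion only)
  and ΔP1 (delayed oligomer formation, more-delayed conversion) α-synuclein.

- **Synthetic data.** A first-class generator produces whole experiments:
  a four-species kinetic scheme (monomer → Type-A → Type-B → fibril, with
  optional fibril-catalysed feedback), species-specific rotor decay
  signatures, Poisson photon statistics under periodic excitation, and
  fibril-driven sigmoidal bulk intensity.

## Worked example

```python
import numpy as np
from rotorlife import (
    AcquisitionConfig, DecayModel, make_gaussian_irf, simulate_decay,
    select_model, phasor_from_histogram,
)

acq = AcquisitionConfig(rep_rate_mhz=80.0, n_bins=1024)   # 12.5 ns window
irf = make_gaussian_irf(fwhm_ns=0.2, center_ns=1.0, config=acq)

# a rotor decay in an aggregating mixture: short free-dye component plus a
# longer confined component
truth = DecayModel([(0.55, 0.25), (0.45, 1.6)])
hist = simulate_decay(truth, irf, acq, total_photons=1_000_000, seed=42)

result = select_model(hist, irf, max_n=3)
print(result.summary())
```

prints

```
Exponential reconvolution fit
==============================================
components requested/reported : 2/2
reduced chi-square            : 1.101
background (counts/bin)       : 1.716e-18
converged                     : True
fit range start bin           : 81
----------------------------------------------
 i        alpha     tau (ns)    se(tau)
 1       7879.1      0.24558      0.003
 2       6440.4       1.5919    0.00343
----------------------------------------------
tau_m (amplitude-weighted)    : 0.85112 ns
```

The selected model has two components with lifetimes 0.246 and 1.592 ns
(truth: 0.25 and 1.6 ns) at near-equal amplitude fractions, reduced χ² ≈ 1.1,
and an amplitude-weighted mean lifetime of 0.851 ns — between the free-dye
and confined values, as expected for a mixture. `phasor_from_histogram(hist)`
maps the same decay to a single (g, s) point without assuming any decay
model.

A whole synthetic aggregation experiment, including fitting, phasors,
classification and kinetics, is one call (or `rotorlife run` from a shell):

```python
from rotorlife import RunConfig, run_pipeline
result = run_pipeline(RunConfig(preset="wt_like", seed=1, out_dir="wt_run"))
print(result["summary"].tau_m_onset_h, result["summary"].intensity_t50_h)
```

For the wild-type preset the lifetime channel turns on at ≈ 3.5 h while the
intensity half-rise sits at ≈ 41 h, and the phasor trajectory is labelled
Type-A oligomeric → Type-B oligomeric → fibrillar along time.

## Command line

`rotorlife` exposes `simulate`, `fit`, `phasor`, `classify`, `kinetics` and
`run` subcommands; each documents itself with `--help`. All inputs and
outputs are plain CSV/JSON (see `docs/methods.md` for the schemas).

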