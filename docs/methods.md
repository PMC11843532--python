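# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `rotorlife`, in the spirit of a package methods section:
what is computed, with which defaults, and what the synthetic experiments do
and do not establish about real data.

## TCSPC forward model

A decay histogram covers one repetition period of the pulsed laser
(default 80 MHz → 12.5 ns window) with `n_bins` bins (default 4096 for the
core simulator; the pipeline default is 1024, which keeps reconvolution
fitting fast at a 12 ps bin width that still oversamples the 200 ps IRF).
Times are bin centers. The expected (noise-free) curve of a
multi-exponential emitter is the *circular* convolution of the IRF density
with the periodically wrapped decay

    d(t) = Σᵢ αᵢ exp(−t/τᵢ) / (1 − exp(−T/τᵢ)),   0 ≤ t < T,

where the geometric factor sums the tails of all preceding pulses exactly
(for exponentials). At 80 MHz this matters: a 2 ns component retains ~0.2%
of its amplitude at the next pulse, and the classifier and fitter both rely
on curve shapes near the percent level. Photon noise is independent Poisson
per bin with the curve scaled to a total photon budget. A constant
background expectation is supported and defaults to 0.

The synthetic IRF is a discretized Gaussian (default FWHM 0.2 ns centred at
1 ns), standing in for a measured scatter IRF; measured IRFs can be
imported through the decay CSV format (`# kind=irf`).

## Reconvolution fitting and τ_m

Fits minimise the Neyman-weighted residual `(C − model)/√max(C, 1)` over
bins from the IRF peak onward (the rising edge is excluded by default),
with amplitudes ≥ 0, lifetimes in [0.01, 50] ns, and a non-negative
constant background fitted by default. Lifetime bounds are physical: no
realistic TCSPC system resolves below 10 ps, and nothing in the
molecular-rotor range approaches 50 ns. Without an initial guess, the
optimiser is restarted from a five-point lifetime grid spanning
0.05–5 ns (components spread geometrically around each anchor); ties are
broken by χ². Fitted components closer than a 1.2× lifetime ratio are
merged (amplitude-summed, amplitude-weighted lifetime) before reporting —
an over-parameterised fit otherwise reports one physical component split
in two.

Model order is selected as the smallest n ∈ {1,2,3} with reduced χ² < 1.3;
failing that, the smallest n whose increment improves χ² by < 5% relative;
failing that, the maximum order. The amplitude-weighted mean lifetime
`τ_m = Σ αᵢτᵢ / Σ αᵢ` is the per-timepoint scalar used everywhere
downstream; it is invariant to amplitude rescaling and bracketed by the
extreme component lifetimes.

For time courses, `fit_tau_m_series` selects the order incrementally along
the run and warm-starts each fit from the previous timepoint. Two
safeguards matter for onset detection: (i) the monomeric baseline is fitted
at n = 1 — an n = 2 fit of a monoexponential decay lets a tiny
long-lifetime amplitude inflate τ_m by several percent, and warm starts
would correlate that inflation across consecutive points; (ii) a
warm-started fit whose lifetime pins at a bound or whose χ² exceeds 2 is
re-fitted from the cold grid.

## Phasor analysis

Phasors use the rectangle rule over bin centers at the first harmonic
ω = 2πf (f the repetition rate): treating the histogram as counts-per-bin,
the discretisation error is O(bin width) and ≤ 10⁻³ at default binning
(verified against the closed forms). No IRF correction is applied by
default — the phasor of a measured decay is the true phasor multiplied by
the IRF's Fourier phase, which rotates/scales *all* points (trajectory and
references) identically, so overlap classification is unaffected. An
optional single-reference calibration (divide by a measured monoexponential
standard in the complex plane) is available and flagged in metadata when
used. Uncertainties are 2× the SD of phasors over parametric Poisson
resamples of the observed counts. Only the first harmonic is computed.

## Synthetic aggregation experiments

The generator emulates the joint FLIM/plate-reader experiment: at each
timepoint a species mixture is mapped to one rotor decay model and one bulk
intensity, and a TCSPC histogram is drawn.

**Kinetic scheme.** Four species in monomer-equivalent concentration (μM):

    dM/dt = −k₁M − kₑMF,  dA/dt = k₁M + kₑMF − k₂A,
    dB/dt = k₂A − k₃B,    dF/dt = k₃B.

Integration is fixed-step RK4 with step ≤ 0.01/max-rate; mass conservation
is checked at every output (≤ 10⁻⁶ relative) and the kₑ = 0 linear chain is
verified against the closed-form Bateman solution. The scheme is
phenomenological: Type-A oligomers are the early species, Type-B the late
β-sheet-rich species, fibrils terminal; the kₑMF term is the minimal
autocatalytic feedback that produces the lag + sharp sigmoid of nucleated
amyloid growth. No rate is fitted to any experiment.

**Optical profiles** (ThT-like defaults). Monomer: single 0.07 ns
component (rotor free in solution); Type-A: 0.25 ns; Type-B: 0.25/0.9 ns at
equal amplitude (τ_m 0.575 ns); fibril: 0.5/2.0 ns at 0.4/0.6 (τ_m 1.4 ns).
Photon weights 1 : 2 : 9 : 14 per μM encode the rotor's rising quantum
yield with confinement; plate-reader brightness 0.02 : 0.02 : 0.06 : 1.0
per μM encodes the fibril-specific switch-on of the intensity channel. The
intensity channel is noiseless by default (optional lognormal multiplicative
noise); the decay channel always carries Poisson noise.

**Presets.** All presets share kₑ = 0.03 /h/μM and m₀ = 100 μM:

| preset | k₁ (/h) | k₂ (/h) | k₃ (/h) | phenotype |
|---|---|---|---|---|
| `wt_like` | 6×10⁻³ | 2.0 | 0.02 | onset ≈ 3.5 h, t₅₀ ≈ 41 h |
| `a30p_like` | 6×10⁻³ | 2.0 | 0.005 | same onset, t₅₀ +≈12 h |
| `dp1_like` | 5×10⁻⁵ | 0.07 | 0.005 | onset +1…+8 h, t₅₀ +≈41 h |

`a30p_like` differs from wild type only in the conversion rate k₃ (slower
oligomer→fibril conversion); `dp1_like` additionally slows primary oligomer
formation (k₁, k₂). Rates were chosen once to reproduce the qualitative
phenotypes — an early lifetime onset hours before the intensity half-rise
for wild type, an unchanged lifetime onset but extended intensity lag for
A30P, and a delayed-in-both, intensity-more phenotype for ΔP1 — at the
default sampling (0.5 h over 0–96 h, 1.5×10⁵ photons/timepoint).

**A structural point about onset detection.** The onset rule (below) is
affine-invariant by design, which makes it *scale-free* on noiseless
series: any power-law early rise crosses its own baseline-derived threshold
at a time that does not depend on the rate constants. Rate-dependent onsets
— the phenomenon the experiments show — therefore require a noise floor,
exactly as in the real measurement, where the floor is photon-counting
noise in the fitted lifetimes. Phenotype comparisons are accordingly run on
the default photon-sampled decays (fitted τ_m) with the exactly noiseless
intensity channel. Slow variants whose early lifetime drift sits below the
fit-noise floor (the `dp1_like` preset) get genuinely late onsets; variants
sharing the oligomer-formation rates (wild type vs A30P) get onsets equal
to within a sampling interval.

## Kinetic descriptors

- **Onset**: first time the series exceeds baseline mean + k·SD for m
  consecutive samples, linearly interpolated; `detect_onset` defaults to
  baseline = first 3 samples, k = 3, m = 2. Whole-trace summaries use a
  6-sample baseline and m = 3: on photon-limited fitted series the longer
  baseline stabilises the SD estimate and the longer run suppresses false
  onsets from isolated noise excursions (chosen by simulation before the
  headline runs). NaN marks "no onset".
- **t₅₀**: first crossing of baseline + ½(plateau − baseline), with
  baseline/plateau the means of the first/last 10% of samples; robust to
  non-logistic shapes and needs no fitting. For runs truncated before the
  plateau, t₅₀ is the half-rise of the observed span and is biased early —
  cross-variant *deltas* remain interpretable.
- Both are equivariant under time shifts and invariant under positive
  affine value transforms.

## Reference sets and region classification

Titration references emulate measuring the rotor with increasing
concentrations of preformed fibrils or stabilized oligomers (the
structural analogue of Type-B): at titration step f, a fraction f of
detected photons carries the reference-species signature and 1 − f the
free-dye signature. Default grids are f = 0.20–1.0 (fibril) and
0.12–1.0 (oligomer) in 0.05 steps; the fibril floor is higher because a
low-concentration fibril titration is optically indistinguishable from
free dye, and including such points would let the monomeric head of any
trajectory "overlap fibrils".

Error bars are the 2σ scatter of simulated technical repeats. Each repeat
redraws the photon counts (Poisson), the photon fraction (lognormal,
shape 0.1 — well-to-well pipetting/binding variability) and a common
lifetime scale factor (lognormal, shape 0.05 — temperature, viscosity and
batch variation). The compositional and environmental terms dominate shot
noise, as they do in measured technical repeats; with shot noise alone the
error bars would be ~10⁻³ and the overlap rule would label almost nothing.

Classification follows the two-direction overlap rule: points overlap iff
their 2σ intervals intersect in both g and s; a segment (sliding window of
5 consecutive trajectory points, stride = window, remainder merged into the
last segment) is *fibrillar* if ≥ 60% of its points overlap some fibril
reference point, else *Type-B oligomeric* by the same rule against the
oligomer reference, else *Type-A oligomeric* if both overlap fractions are
≤ 40% (clear deviation from both references), else *unassigned*. When a
segment qualifies for both regions the fibrillar label wins and the tie is
flagged — stabilized oligomers partially overlap fibril phasors, so the
ambiguity is surfaced rather than hidden. Both fractions are always
reported. The window, 60% threshold and 40% deviation cutoff are
parameters; the numbers above are the defaults.

Note on label sequences: between the Type-B phase and the fibrillar phase
an aggregation trajectory is a B + F mixture that genuinely deviates from
*both* single-species titration lines, so intermediate windows label as
Type-A-like deviation. The meaningful temporal statement, and the one the
pipeline checks, is that the *first occurrences* of the labels order as
Type-A → Type-B → fibrillar.

## Pipeline, formats, reproducibility

`run_pipeline` chains simulate (or ingest) → fit → phasor → classify →
kinetics, writing plain-text outputs (decay CSVs with a commented header;
`trace/fit/phasor/regions/kinetics` CSVs; config and stage log as JSON)
tagged with a config hash. Sub-seeds derive from the run seed by a fixed
counter scheme (`SeedSequence([seed, counter])`), so runs are
byte-reproducible, and externally supplied decay CSVs flow through the
identical downstream path. Default problem sizes — 193 timepoints at
1.5×10⁵ photons, 1024 bins, 25-replicate references, 50-replicate phasor
bootstraps — run in well under a minute per experiment on one core.

## Limitations

- The species→decay mixing model assumes each species contributes a fixed
  decay signature weighted by concentration; the real rotor photophysics
  (binding equilibria, heterogeneous microenvironments) is richer, and the
  real data cannot distinguish microviscosity from binding-mode changes.
  The simulator encodes the species-mixture reading as an assumption.
- The kinetic scheme is sequential with a single feedback term; secondary
  nucleation, fragmentation and seeding pathways are out of scope, and no
  rates are inferred from experimental curves.
- Passing synthetic tests shows the analysis chain is correct and
  internally consistent under Poisson statistics and the stated mixture
  model; it does not validate the biological parameter values, which are
  qualitative emulations of the published phenotypes.
- Pixel-resolved phasor imaging, multi-harmonic phasors and vendor TCSPC
  file formats are not implemented; pixel decays are supported only as
  collections to be summed per image before analysis.
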