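import numpy as np
import pytest
from scipy.stats import spearmanr

from rotorlife.acquisition import AcquisitionConfig, DecayModel, make_gaussian_irf
from rotorlife.fit import amplitude_weighted_lifetime
from rotorlife.pipeline import fit_tau_m_series
from rotorlife.species import (
    KineticParams,
    SpeciesState,
    integrate_kinetics,
    preset,
    simulate_experiment,
    species_to_decay,
    species_to_intensity,
)


def bateman_chain(k1, k2, k3, m0, t):
    """Independent closed-form oracle for the linear chain M->A->B->F.

    Standard Bateman equations for distinct, positive rates; F by mass
    balance.
    """
    t = np.asarray(t, float)
    M = m0 * np.exp(-k1 * t)
    A = m0 * k1 * (np.exp(-k1 * t) - np.exp(-k2 * t)) / (k2 - k1)
    B = m0 * k1 * k2 * (
        np.exp(-k1 * t) / ((k2 - k1) * (k3 - k1))
        + np.exp(-k2 * t) / ((k1 - k2) * (k3 - k2))
        + np.exp(-k3 * t) / ((k1 - k3) * (k2 - k3))
    )
    F = m0 - M - A - B
    return M, A, B, F


class TestIntegrateKinetics:
    def test_no_dynamics_when_all_rates_zero(self):
        states = integrate_kinetics(KineticParams(0, 0, 0), 50.0, [0, 5, 10])
        for st in states:
            assert st.concentrations["monomer"] == pytest.approx(50.0)
            assert st.concentrations["fibril"] == 0.0

    @pytest.mark.parametrize(
        "rates", [(0.3, 0.7, 0.1), (0.05, 0.5, 0.9), (1.2, 0.4, 0.02)]
    )
    def test_matches_bateman_closed_form(self, rates):
        k1, k2, k3 = rates
        m0 = 100.0
        tp = np.linspace(0, 40, 100)
        states = integrate_kinetics(KineticParams(k1, k2, k3), m0, tp)
        M, A, B, F = bateman_chain(k1, k2, k3, m0, tp)
        got = np.array(
            [[s.concentrations[k] for k in ("monomer", "type_a", "type_b", "fibril")] for s in states]
        )
        expected = np.column_stack([M, A, B, F])
        assert np.max(np.abs(got - expected)) / m0 < 1e-6

    def test_mass_conserved_with_feedback(self):
        tp = np.linspace(0, 60, 50)
        states = integrate_kinetics(KineticParams(0.01, 0.5, 0.05, ke=0.05), 100.0, tp)
        totals = np.array([s.total for s in states])
        assert np.max(np.abs(totals - 100.0)) / 100.0 < 1e-6

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(-0.1, 0.5, 0.1)

    def test_unsorted_timepoints_rejected(self):
        with pytest.raises(ValueError):
            integrate_kinetics(KineticParams(0.1, 0.1, 0.1), 10.0, [5.0, 1.0])


class TestSpeciesToDecay:
    @pytest.fixture()
    def profile(self):
        return preset("wt_like")[1]

    def test_pure_monomer_returns_monomer_decay(self, profile):
        state = SpeciesState(0.0, dict(monomer=10.0, type_a=0.0, type_b=0.0, fibril=0.0))
        model = species_to_decay(state, profile)
        assert model.amplitudes.sum() == pytest.approx(1.0)
        assert model.lifetimes.tolist() == profile.decays["monomer"].lifetimes.tolist()

    def test_balanced_two_species_mix_splits_amplitude(self, profile):
        # equal photon-weighted contributions of two single-tau species
        state = SpeciesState(
            0.0,
            dict(
                monomer=10.0,
                type_a=10.0 * profile.photon_weights["monomer"] / profile.photon_weights["type_a"],
                type_b=0.0,
                fibril=0.0,
            ),
        )
        model = species_to_decay(state, profile)
        assert model.amplitudes == pytest.approx([0.5, 0.5])

    def test_mixture_tau_m_between_pure_species(self, profile):
        params, _ = preset("wt_like")
        states = integrate_kinetics(params, 100.0, [15.0])
        tau_mix = amplitude_weighted_lifetime(species_to_decay(states[0], profile))
        tau_mono = amplitude_weighted_lifetime(profile.decays["monomer"])
        tau_fib = amplitude_weighted_lifetime(profile.decays["fibril"])
        assert tau_mono < tau_mix < tau_fib

    def test_continuity_in_concentrations(self, profile):
        base = dict(monomer=50.0, type_a=5.0, type_b=20.0, fibril=25.0)
        tau0 = amplitude_weighted_lifetime(
            species_to_decay(SpeciesState(0.0, dict(base)), profile)
        )
        eps = 1e-6
        perturbed = dict(base, type_b=base["type_b"] + eps)
        tau1 = amplitude_weighted_lifetime(
            species_to_decay(SpeciesState(0.0, perturbed), profile)
        )
        assert abs(tau1 - tau0) < 1e-4 * eps / 1e-6

    def test_all_zero_concentrations_rejected(self, profile):
        state = SpeciesState(0.0, dict(monomer=0.0, type_a=0.0, type_b=0.0, fibril=0.0))
        with pytest.raises(ValueError):
            species_to_decay(state, profile)


class TestSpeciesToIntensity:
    @pytest.fixture()
    def profile(self):
        return preset("wt_like")[1]

    def test_zero_state_gives_zero(self, profile):
        state = SpeciesState(0.0, dict(monomer=0.0, type_a=0.0, type_b=0.0, fibril=0.0))
        assert species_to_intensity(state, profile) == 0.0

    def test_linear_in_concentrations(self, profile):
        base = dict(monomer=10.0, type_a=1.0, type_b=5.0, fibril=30.0)
        i1 = species_to_intensity(SpeciesState(0.0, base), profile)
        i2 = species_to_intensity(
            SpeciesState(0.0, {k: 2 * v for k, v in base.items()}), profile
        )
        assert i2 == pytest.approx(2 * i1)

    def test_fibril_brightness_dominates(self, profile):
        no_fib = SpeciesState(0.0, dict(monomer=100.0, type_a=0.0, type_b=0.0, fibril=0.0))
        fib = SpeciesState(0.0, dict(monomer=0.0, type_a=0.0, type_b=0.0, fibril=100.0))
        assert species_to_intensity(fib, profile) > 10 * species_to_intensity(no_fib, profile)


class TestPresets:
    def test_a30p_differs_from_wt_only_in_conversion_rate(self):
        wt, _ = preset("wt_like")
        a30p, _ = preset("a30p_like")
        assert a30p.k1 == wt.k1 and a30p.k2 == wt.k2 and a30p.ke == wt.ke
        assert a30p.k3 < wt.k3

    def test_dp1_slows_oligomer_formation_and_conversion(self):
        wt, _ = preset("wt_like")
        dp1, _ = preset("dp1_like")
        assert dp1.k1 < wt.k1 and dp1.k2 < wt.k2 and dp1.k3 < wt.k3
        assert dp1.ke == wt.ke

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            preset("e46k_like")


class TestSimulateExperiment:
    def test_same_seed_gives_identical_trace(self):
        params, profile = preset("wt_like")
        cfg = AcquisitionConfig(n_bins=256)
        tp = np.arange(0, 10, 1.0)
        tr1 = simulate_experiment(params, profile, tp, config=cfg, photons_per_timepoint=10**4, seed=9)
        tr2 = simulate_experiment(params, profile, tp, config=cfg, photons_per_timepoint=10**4, seed=9)
        for h1, h2 in zip(tr1.decays, tr2.decays):
            assert np.array_equal(h1.counts, h2.counts)
        assert np.array_equal(tr1.intensity, tr2.intensity)

    def test_noiseless_mode_has_no_decays(self):
        params, profile = preset("wt_like")
        tr = simulate_experiment(params, profile, np.arange(0, 20, 1.0), photons_per_timepoint=None)
        assert tr.decays is None
        assert np.all(np.diff(tr.tau_m_model) > -1e-9)

    def test_intensity_noise_option_perturbs_channel(self):
        params, profile = preset("wt_like")
        tp = np.arange(0, 20, 1.0)
        clean = simulate_experiment(params, profile, tp, photons_per_timepoint=None)
        noisy = simulate_experiment(
            params, profile, tp, photons_per_timepoint=None, intensity_noise_sigma=0.1, seed=4
        )
        assert not np.allclose(clean.intensity, noisy.intensity)
        assert np.all(noisy.intensity >= 0)

    def test_fitted_tau_m_rises_monotonically_with_aggregation(self):
        # Spearman correlation of the fitted lifetime series against time
        params, profile = preset("wt_like")
        cfg = AcquisitionConfig(n_bins=1024)
        irf = make_gaussian_irf(0.2, 1.0, cfg)
        tp = np.arange(0, 40, 1.6)
        tr = simulate_experiment(
            params, profile, tp, config=cfg, photons_per_timepoint=10**6, seed=17, irf=irf
        )
        tau_m, _ = fit_tau_m_series(tr.decays, irf, max_n=2)
        rho = spearmanr(tp, tau_m).statistic
        assert rho > 0.9
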