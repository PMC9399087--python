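"""Two-phase binding model, steady-state fitting, normalization, decay."""

import itertools

import numpy as np
import pytest

from cysbond.covalent_kinetics import (
    InjectionSchedule,
    KineticParams,
    decompose_dissociation,
    fit_steady_state,
    normalization_factor,
    normalized_ru,
    persistent_fraction,
    simulate_sensorgram,
    simulate_tetramer_decay,
)
from conftest import closed_form_at, closed_form_states

RMAX = 100.0


class TestSimulator:
    @pytest.mark.parametrize(
        "kon,koff,kcov",
        list(itertools.product([1e3, 1e4, 1e5], [0.1, 0.7, 2.0], [0.0, 1e-3, 1e-2])),
    )
    def test_matches_matrix_exponential_closed_form(self, kon, koff, kcov):
        """The integrated sensorgram agrees with the piecewise
        matrix-exponential solution of the linear two-state system to
        1e-3 * rmax across the full rate grid."""
        params = KineticParams(kon=kon, koff=koff, kcov=kcov, rmax=RMAX)
        schedule = InjectionSchedule(
            (( 30e-6, 60.0), (100e-6, 60.0)), dissociation_duration=120.0
        )
        sg = simulate_sensorgram(params, schedule, dt=0.5)
        ref = closed_form_at(params, schedule, sg.time)
        assert np.max(np.abs(sg.response - ref)) < 1e-3 * RMAX

    def test_dtt_mode_returns_to_baseline(self):
        """With kcov = 0 (reducing conditions) the response decays below
        1e-3 * rmax once dissociation has run for >= 10 noncovalent
        half-lives."""
        params = KineticParams(kon=1e4, koff=0.7, kcov=0.0, rmax=RMAX)
        schedule = InjectionSchedule.single(100e-6, 60.0, dissociation=10 / 0.7)
        sg = simulate_sensorgram(params, schedule, dt=0.05)
        assert sg.response[-1] < 1e-3 * RMAX

    def test_langmuir_plateau_without_conversion(self):
        """Long constant injection with kcov = 0 plateaus at
        rmax * C / (K_eq + C)."""
        params = KineticParams(kon=1e4, koff=0.5, kcov=0.0, rmax=RMAX)
        C = 40e-6
        sg = simulate_sensorgram(params, InjectionSchedule.single(C, 200.0), dt=0.1)
        expected = RMAX * C / (params.keq + C)
        assert sg.response[-1] == pytest.approx(expected, rel=1e-4)

    def test_conservation_and_monotone_covalent_accumulation(self):
        params = KineticParams(kon=1e4, koff=0.7, kcov=5e-3, rmax=RMAX)
        schedule = InjectionSchedule.single(100e-6, 300.0, dissociation=300.0)
        sg = simulate_sensorgram(params, schedule, dt=0.2)
        total = sg.bound_noncovalent + sg.bound_covalent
        assert np.all(total <= RMAX * (1 + 1e-9))
        assert np.all(np.diff(sg.bound_covalent) >= -1e-9 * RMAX)

    def test_covalent_plateau_matches_closed_form_after_dissociation(self):
        params = KineticParams(kon=1e4, koff=0.7, kcov=1e-3, rmax=RMAX)
        schedule = InjectionSchedule.single(100e-6, 300.0, dissociation=60.0)
        sg = simulate_sensorgram(params, schedule, dt=0.2)
        # closed form: propagate through injection then dissociation
        inj = closed_form_states(params, 100e-6, (0.0, 0.0), [300.0])[0]
        end = closed_form_states(params, 0.0, inj, [60.0])[0]
        assert abs(sg.response[-1] - end.sum()) < 1e-3 * RMAX


class TestPersistentFraction:
    PARAMS = KineticParams(kon=1e4, koff=0.7, kcov=1e-3, rmax=RMAX)

    def test_zero_without_covalent_conversion(self):
        p = KineticParams(kon=1e4, koff=0.7, kcov=0.0, rmax=RMAX)
        assert persistent_fraction(p, 60.0, 100e-6) == 0.0

    def test_short_injection_approaches_conversion_probability(self):
        """For a brief injection nearly all bound material is noncovalent,
        so the persistent fraction approaches the per-event conversion
        probability kcov/(koff + kcov) ~= 1.43e-3."""
        frac = persistent_fraction(self.PARAMS, 0.01, 100e-6)
        p_event = 1e-3 / (0.7 + 1e-3)
        assert frac == pytest.approx(p_event, rel=0.02)

    def test_strictly_increases_with_injection_duration(self):
        """Longer injections accumulate more covalent complexes: the
        persistent fraction rises across 1, 5 and 20 minute injections."""
        fracs = [persistent_fraction(self.PARAMS, t, 100e-6)
                 for t in (60.0, 300.0, 1200.0)]
        assert fracs[0] < fracs[1] < fracs[2]

    def test_increases_with_kcov(self):
        fracs = [
            persistent_fraction(
                KineticParams(kon=1e4, koff=0.7, kcov=kc, rmax=RMAX), 300.0, 100e-6
            )
            for kc in (1e-4, 1e-3, 1e-2)
        ]
        assert fracs[0] < fracs[1] < fracs[2]


CONCS_UM = np.array([1.5, 4.4, 13.3, 40.0, 120.0])


class TestSteadyStateFit:
    def test_noise_free_recovery(self):
        """Noise-free equilibria at the five-point concentration series
        return the generating K_eq to 0.1%."""
        keq = 12.3e-6
        C = CONCS_UM * 1e-6
        R = RMAX * C / (keq + C)
        fit = fit_steady_state(C, R)
        assert fit.status == "ok"
        assert fit.keq == pytest.approx(keq, rel=1e-3)
        assert fit.rmax == pytest.approx(RMAX, rel=1e-3)

    def test_recovers_simulated_equilibrium_affinity(self):
        """Equilibrium plateaus simulated with kcov = 0 recover koff/kon."""
        params = KineticParams(kon=1e4, koff=0.25, kcov=0.0, rmax=RMAX)
        C = CONCS_UM * 1e-6
        eq = []
        for c in C:
            sg = simulate_sensorgram(params, InjectionSchedule.single(c, 400.0), dt=0.5)
            eq.append(sg.response[-1])
        fit = fit_steady_state(C, eq)
        assert fit.keq == pytest.approx(params.keq, rel=1e-3)

    def test_flat_responses_flagged_degenerate(self):
        fit = fit_steady_state(CONCS_UM * 1e-6, np.full(5, 50.0))
        assert fit.status == "degenerate"

    def test_median_error_under_two_percent_noise(self):
        """200 noisy replicates (2% multiplicative) keep the median
        relative K_eq error under 10%."""
        keq = 12.3e-6
        C = CONCS_UM * 1e-6
        R0 = RMAX * C / (keq + C)
        rng = np.random.default_rng(17)
        errors = []
        for _ in range(200):
            R = R0 * (1 + 0.02 * rng.standard_normal(R0.shape))
            fit = fit_steady_state(C, R)
            errors.append(abs(fit.keq - keq) / keq)
        assert np.median(errors) < 0.10


class TestNormalization:
    def test_printed_worked_example(self):
        """K_eq = 64.1 uM at 100 uM analyte gives the occupancy factor
        1.641."""
        assert normalization_factor(64.1e-6, 100e-6) == pytest.approx(1.641)

    def test_saturation_limit(self):
        assert normalization_factor(64.1e-6, 1.0) == pytest.approx(1.0, abs=1e-4)

    def test_half_occupancy(self):
        assert normalization_factor(50e-6, 50e-6) == pytest.approx(2.0)

    def test_zero_concentration_rejected(self):
        with pytest.raises(ValueError):
            normalization_factor(64.1e-6, 0.0)

    def test_normalizes_responses_to_occupancy(self):
        factor, norm = normalized_ru(50.0, 64.1e-6, 100e-6, responses=[82.05])
        assert factor == pytest.approx(1.641)
        assert norm[0] == pytest.approx(82.05 / (1.641 * 50.0))


class TestDissociationDecomposition:
    def test_exact_on_constructed_biexponential(self):
        from cysbond.covalent_kinetics import Sensorgram

        t = np.linspace(0, 12, 600)
        sg = Sensorgram(time=t, response=50 * np.exp(-0.7 * t) + 20.0,
                        injection_end=0.0)
        dec = decompose_dissociation(sg)
        assert dec.fast_amplitude == pytest.approx(50.0, rel=1e-6)
        assert dec.decay_rate == pytest.approx(0.7, rel=1e-6)
        assert dec.persistent_plateau == pytest.approx(20.0, rel=1e-6)
        assert dec.half_life == pytest.approx(np.log(2) / 0.7, rel=1e-6)

    def test_no_plateau_without_conversion(self):
        params = KineticParams(kon=1e4, koff=0.7, kcov=0.0, rmax=RMAX)
        sg = simulate_sensorgram(
            params, InjectionSchedule.single(100e-6, 60.0, dissociation=30.0), dt=0.02
        )
        dec = decompose_dissociation(sg)
        assert dec.persistent_plateau < 1e-3 * RMAX

    def test_recovers_subsecond_half_life(self):
        """A dissociation rate giving ln2/koff < 1 s is recovered within
        2% from the simulated trace."""
        koff = 0.9  # half-life 0.77 s
        params = KineticParams(kon=1e4, koff=koff, kcov=1e-3, rmax=RMAX)
        sg = simulate_sensorgram(
            params, InjectionSchedule.single(100e-6, 60.0, dissociation=20.0), dt=0.01
        )
        dec = decompose_dissociation(sg)
        assert dec.half_life < 1.0
        assert dec.half_life == pytest.approx(np.log(2) / (koff + 1e-3), rel=0.02)

    def test_rising_tail_flagged(self):
        from cysbond.covalent_kinetics import Sensorgram

        t = np.linspace(0, 10, 100)
        sg = Sensorgram(time=t, response=20 + t, injection_end=0.0)
        assert decompose_dissociation(sg).status == "warning"


class TestTetramerDecay:
    def test_reduces_to_pure_exponential(self):
        params = KineticParams(kon=0.0, koff=0.01, kcov=0.0)
        t = np.array([10.0, 30.0, 60.0])
        out = simulate_tetramer_decay(params, t, f_cov=0.0)
        assert out == pytest.approx(100 * np.exp(-0.01 * t * 60))

    def test_covalent_floor(self):
        params = KineticParams(kon=0.0, koff=0.05, kcov=0.0)
        out = simulate_tetramer_decay(params, [10, 30, 60, 1e6], f_cov=0.5)
        assert np.all(out >= 50.0 - 1e-9)

    def test_conversion_dominates_pure_decay_at_every_timepoint(self):
        """With kcov > 0 more staining remains at 10/30/60 min than the
        kcov = 0 curve predicts, term by term."""
        t = [10.0, 30.0, 60.0]
        base = simulate_tetramer_decay(KineticParams(kon=0.0, koff=2e-3, kcov=0.0), t)
        cov = simulate_tetramer_decay(KineticParams(kon=0.0, koff=2e-3, kcov=5e-4), t)
        assert np.all(cov > base)
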