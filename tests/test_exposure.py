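"""Closed-form infusion kinetics: ODE cross-check, linearity, dosing rules."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from txasim import (DoseRegimen, SamplingGrid, Subject, auc_infinity,
                    concentration_at, disposition_constants,
                    individual_parameters, profiles_to_frame, resolve_dose,
                    simulate_cohort, simulate_profile, to_nonmem_dataset)
from txasim.exposure import frame_to_profiles
from conftest import random_individuals


def ode_profile(ind, dose_mg, duration, times):
    """Independent oracle: adaptive integration of the two-compartment ODEs."""
    k10, k12, k21 = ind.cl / ind.v1, ind.q / ind.v1, ind.q / ind.v2
    rate = dose_mg / duration

    def rhs(t, y, inp):
        return [inp - (k10 + k12) * y[0] + k21 * y[1],
                k12 * y[0] - k21 * y[1]]

    # integrate the infusion and decay phases separately (input discontinuity)
    t_in = np.unique(np.concatenate([[0.0, duration],
                                     times[times <= duration]]))
    sol1 = solve_ivp(rhs, (0, duration), [0.0, 0.0], args=(rate,),
                     t_eval=t_in, rtol=1e-11, atol=1e-12, method="LSODA")
    y_end = sol1.y[:, -1]
    t_out = times[times > duration]
    central = dict(zip(t_in, sol1.y[0]))
    if len(t_out):
        sol2 = solve_ivp(rhs, (duration, times[-1]), y_end, args=(0.0,),
                         t_eval=t_out, rtol=1e-11, atol=1e-12, method="LSODA")
        central.update(zip(t_out, sol2.y[0]))
    return np.array([central[t] for t in times]) / ind.v1 * 1000.0


class TestResolveDose:
    def test_per_kg_below_cap(self):
        reg = DoseRegimen(label="25", dose_per_kg=25.0)
        s = Subject(id="s", weight=58.2, plt=300, nirs=70, il8=20)
        assert resolve_dose(reg, s) == pytest.approx(1455.0)

    def test_per_kg_capped_at_2g(self):
        reg = DoseRegimen(label="25", dose_per_kg=25.0)
        s = Subject(id="s", weight=100.0, plt=300, nirs=70, il8=20)
        assert resolve_dose(reg, s) == 2000.0

    def test_absolute_dose_ignores_weight(self):
        reg = DoseRegimen(label="2g", dose_mg=2000.0)
        for wt in (20.0, 80.1, 150.0):
            s = Subject(id="s", weight=wt, plt=300, nirs=70, il8=20)
            assert resolve_dose(reg, s) == 2000.0

    def test_regimen_validation(self):
        with pytest.raises(ValueError):
            DoseRegimen(label="both", dose_per_kg=25.0, dose_mg=2000.0)
        with pytest.raises(ValueError):
            DoseRegimen(label="neither")
        with pytest.raises(ValueError):
            DoseRegimen(label="bad", dose_mg=2000.0, dose_times=(10.0, 0.0))


class TestConcentrationAt:
    def test_zero_at_time_zero_and_before(self, params, adult_median_subject):
        ind = individual_parameters(adult_median_subject, params)
        c = concentration_at(ind, 2000.0, 1.0, np.array([-5.0, 0.0, 1.0]))
        assert c[0] == 0.0 and c[1] == 0.0 and c[2] > 0

    def test_bolus_limit_is_dose_over_v1(self, params, adult_median_subject):
        ind = individual_parameters(adult_median_subject, params)
        c = concentration_at(ind, 2000.0, 1e-3, np.array([1e-3]))
        assert c[0] == pytest.approx(2000.0 / ind.v1 * 1000.0, rel=1e-4)

    def test_matches_ode_oracle_random_sets(self):
        """Analytic solution vs adaptive ODE integration, rel tol 1e-6."""
        times = np.array([0.5, 1.0, 2.0, 5.0, 10.0, 30.0, 60.0, 120.0,
                          240.0, 480.0])
        for ind in random_individuals(100, seed=21):
            analytic = concentration_at(ind, 1500.0, 1.0, times)
            oracle = ode_profile(ind, 1500.0, 1.0, times)
            assert np.allclose(analytic, oracle, rtol=1e-6)

    def test_matches_ode_oracle_long_infusion(self, params,
                                              adult_median_subject):
        times = np.array([1.0, 5.0, 9.9, 10.0, 10.1, 20.0, 60.0, 480.0])
        ind = individual_parameters(adult_median_subject, params)
        analytic = concentration_at(ind, 2000.0, 10.0, times)
        oracle = ode_profile(ind, 2000.0, 10.0, times)
        assert np.allclose(analytic, oracle, rtol=1e-6)

    def test_continuous_at_infusion_end(self, params, adult_median_subject):
        ind = individual_parameters(adult_median_subject, params)
        t = np.array([1.0 - 1e-9, 1.0, 1.0 + 1e-9])
        c = concentration_at(ind, 2000.0, 1.0, t)
        assert c[0] == pytest.approx(c[2], rel=1e-6)

    def test_linear_in_dose(self):
        times = np.linspace(0, 480, 97)
        for ind in random_individuals(20, seed=3):
            c1 = concentration_at(ind, 700.0, 1.0, times)
            c2 = concentration_at(ind, 1400.0, 1.0, times)
            assert np.allclose(c2, 2.0 * c1, rtol=1e-12)

    def test_longer_infusion_never_raises_peak(self):
        times = np.linspace(0, 480, 2000)
        for ind in random_individuals(20, seed=4):
            peaks = [concentration_at(ind, 1000.0, d, times).max()
                     for d in (1.0, 5.0, 10.0, 30.0)]
            assert np.all(np.diff(peaks) <= 0)

    def test_auc_infinity_equals_dose_over_cl(self):
        """Closed-form AUC (A/alpha + B/beta) vs dose/CL, rel err < 1e-9."""
        for ind in random_individuals(1000, seed=17):
            dc = disposition_constants(ind)
            auc_macro = 1500.0 * (dc.coef_a / dc.alpha +
                                  dc.coef_b / dc.beta) * 1000.0
            assert auc_macro == pytest.approx(auc_infinity(ind, 1500.0),
                                              rel=1e-9)


class TestSimulateProfile:
    def test_noiseless_obs_equal_true(self, params, adult_median_subject,
                                      grid):
        reg = DoseRegimen(label="2g", dose_mg=2000.0)
        p = simulate_profile(adult_median_subject, params, reg, grid,
                             error_mode=False)
        assert np.array_equal(p.c_obs, p.c_true)
        assert p.c_true[0] == 0.0
        assert np.all(p.c_true >= 0)

    def test_superposition_two_half_doses(self, params, adult_median_subject,
                                          grid):
        one = simulate_profile(adult_median_subject, params,
                               DoseRegimen(label="2g", dose_mg=2000.0),
                               grid, error_mode=False)
        two = simulate_profile(
            adult_median_subject, params,
            DoseRegimen(label="2x1g", dose_mg=1000.0,
                        dose_times=(0.0, 0.0)), grid, error_mode=False)
        assert np.allclose(one.c_true, two.c_true, rtol=1e-12)

    def test_superposition_time_shift(self, params, adult_median_subject):
        grid = SamplingGrid(times=np.linspace(0, 480, 481))
        single = simulate_profile(adult_median_subject, params,
                                  DoseRegimen(label="1g", dose_mg=1000.0),
                                  grid, error_mode=False).c_true
        double = simulate_profile(
            adult_median_subject, params,
            DoseRegimen(label="1g x2", dose_mg=1000.0,
                        dose_times=(0.0, 60.0)), grid, error_mode=False).c_true
        shifted = np.concatenate([np.zeros(60), single[:-60]])
        assert np.allclose(double, single + shifted, rtol=1e-10, atol=1e-12)

    def test_proportional_error_sd(self, params, adult_median_subject):
        """SD of c_obs/c_true recovers sqrt(sigma2_prop) ~ 0.154."""
        grid = SamplingGrid(times=np.linspace(0, 480, 20_001))
        reg = DoseRegimen(label="2g", dose_mg=2000.0)
        p = simulate_profile(adult_median_subject, params, reg, grid,
                             error_mode=True, rng=np.random.default_rng(2))
        ratio = p.c_obs[1:] / p.c_true[1:]
        assert ratio.std() == pytest.approx(np.sqrt(0.0238), rel=0.03)

    def test_error_mode_requires_rng(self, params, adult_median_subject, grid):
        reg = DoseRegimen(label="2g", dose_mg=2000.0)
        with pytest.raises(ValueError, match="rng"):
            simulate_profile(adult_median_subject, params, reg, grid,
                             error_mode=True)


class TestSimulateCohort:
    def test_deterministic_and_order_stable(self, params, grid):
        subjects = [Subject(id=f"s{i}", weight=30 + i, plt=300, nirs=70,
                            il8=20) for i in range(6)]
        reg = DoseRegimen(label="25", dose_per_kg=25.0)
        a = simulate_cohort(subjects, params, reg, grid, seed=5)
        b = simulate_cohort(subjects, params, reg, grid, seed=5)
        assert [p.subject_id for p in a] == [s.id for s in subjects]
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.c_obs, pb.c_obs)

    def test_empty_cohort(self, params, grid):
        reg = DoseRegimen(label="25", dose_per_kg=25.0)
        assert simulate_cohort([], params, reg, grid, seed=0) == []

    def test_profile_frame_roundtrip(self, params, grid):
        subjects = [Subject(id=f"s{i}", weight=40, plt=300, nirs=70, il8=20)
                    for i in range(3)]
        reg = DoseRegimen(label="25", dose_per_kg=25.0)
        profiles = simulate_cohort(subjects, params, reg, grid, seed=1)
        back = frame_to_profiles(profiles_to_frame(profiles))
        assert [p.subject_id for p in back] == [p.subject_id for p in profiles]
        for pa, pb in zip(profiles, back):
            assert np.allclose(pa.c_obs, pb.c_obs, rtol=1e-12)
            assert pa.dose_mg == pb.dose_mg


class TestNonmemExport:
    def test_dataset_layout(self, params, grid):
        subjects = [Subject(id="a", weight=40, plt=300, nirs=70, il8=20),
                    Subject(id="b", weight=50, plt=250, nirs=60, il8=10)]
        reg = DoseRegimen(label="25", dose_per_kg=25.0)
        profiles = simulate_cohort(subjects, params, reg, grid, seed=0)
        df = to_nonmem_dataset(profiles, subjects, reg)
        assert set(df.columns) >= {"ID", "TIME", "AMT", "RATE", "DV", "EVID",
                                   "WT", "PLT", "NIRS", "IL8"}
        doses = df[df.EVID == 1]
        assert len(doses) == 2
        assert doses.iloc[0].AMT == pytest.approx(25.0 * 40)
        assert doses.iloc[0].RATE == pytest.approx(25.0 * 40 / 1.0)
        obs = df[(df.ID == 1) & (df.EVID == 0)]
        assert len(obs) == len(grid.times)
        # dose row precedes the t=0 observation for each subject
        first = df[df.ID == 1].iloc[0]
        assert first.EVID == 1
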