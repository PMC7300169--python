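"""Monte-Carlo engine: RMSE algebra, pooling, oracle agreement, search logic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ossdosim as od
from ossdosim.search import simulate_deviations
from conftest import make_monoexp_patient

LN2 = math.log(2.0)


def hybrid(times, anchor=None):
    planar = od.PlanarSchedule(tuple(float(t) for t in times))
    if anchor is None:
        anchor = planar.n_tp - 2
    return od.HybridSchedule(planar=planar, spect_anchor_index=anchor)


class TestRmseAlgebra:
    @pytest.mark.parametrize("mu, sigma, expected_2sf", [
        (-2.8, 6.4, 7.0),   # single SPECT/CT at 52 h, kidneys
        (-6.1, 9.1, 11.0),  # single SPECT/CT at 72 h, kidneys
        (-7.8, 8.8, 12.0),  # single SPECT/CT at 72 h, tumours
    ])
    def test_printed_value_pairs(self, mu, sigma, expected_2sf):
        val = od.rmse(mu, sigma)
        assert float(f"{val:.2g}") == expected_2sf

    def test_unbiased_case(self):
        assert od.rmse(0.0, 5.5) == 5.5

    @given(mu=st.floats(-50, 50), sigma=st.floats(0, 50))
    @settings(derandomize=True, max_examples=200)
    def test_rmse_dominates_components(self, mu, sigma):
        val = od.rmse(mu, sigma)
        assert val >= abs(mu) - 1e-12 and val >= sigma - 1e-12

    def test_joint_rmse_table_example(self):
        assert od.joint_rmse(6.4, 6.3, 2.0) == pytest.approx(19.1)

    def test_joint_rmse_trivial_weight(self):
        assert od.joint_rmse(4.2, 0.0, 1.0) == 4.2

    @given(a=st.floats(0, 30), b=st.floats(0, 30), d=st.floats(0.001, 5))
    @settings(derandomize=True, max_examples=100)
    def test_joint_rmse_monotone(self, a, b, d):
        assert od.joint_rmse(a + d, b, 2.0) > od.joint_rmse(a, b, 2.0)
        assert od.joint_rmse(a, b + d, 2.0) > od.joint_rmse(a, b, 2.0)


class TestScheduleMetrics:
    def test_pooling_counts(self, pinned_cohort):
        """13 patients x n_reps kidney samples; 2 lesions x 13 x n_reps tumour."""
        cfg = od.SearchConfig(n_reps=25, method="hybrid", seed=3)
        m = od.schedule_metrics(pinned_cohort, hybrid((3, 96, 192)), cfg,
                                od.NoiseConfig())
        assert m.n_kidney_samples == 13 * 25
        assert m.n_tumour_samples == 26 * 25

    def test_rmse_identity_holds(self, pinned_cohort):
        cfg = od.SearchConfig(n_reps=50, method="hybrid", seed=3)
        m = od.schedule_metrics(pinned_cohort, hybrid((3, 96, 192)), cfg,
                                od.NoiseConfig())
        assert m.rmse_k ** 2 == pytest.approx(m.mu_k ** 2 + m.sigma_k ** 2,
                                              rel=1e-12)
        assert m.rmse_t ** 2 == pytest.approx(m.mu_t ** 2 + m.sigma_t ** 2,
                                              rel=1e-12)
        assert m.rmse_joint == pytest.approx(2 * m.rmse_k + m.rmse_t, rel=1e-12)

    def test_deterministic_and_order_independent(self, pinned_cohort):
        """A schedule's metrics do not depend on what else was evaluated."""
        cfg = od.SearchConfig(n_reps=40, method="hybrid", seed=9)
        noise = od.NoiseConfig()
        target = hybrid((20, 96, 192))
        alone = od.schedule_metrics(pinned_cohort, target, cfg, noise)
        batch = od.evaluate_schedules(
            pinned_cohort, [hybrid((1, 2, 3), 0), target, hybrid((4, 44, 168))],
            cfg, noise)
        assert batch[1] == alone
        again = od.schedule_metrics(pinned_cohort, target, cfg, noise)
        assert again == alone

    def test_zero_noise_monoexp_truth_gives_zero_rmse(self, monoexp_cohort):
        """Exact estimators: every hybrid schedule recovers the true TIAC when
        the truth is mono-exponential and all noise is off."""
        noiseless = od.NoiseConfig(cv_planar_total=0.0, cv_spect=0.0)
        cfg = od.SearchConfig(n_reps=2, method="hybrid", seed=0)
        grid = od.TimeGrid((1, 4, 24, 96, 192))
        for sched in od.enumerate_hybrid_schedules(grid, 2):
            m = od.schedule_metrics(monoexp_cohort, sched, cfg, noiseless)
            assert abs(m.rmse_k) < 1e-9 and abs(m.rmse_t) < 1e-9

    def test_systematic_planar_bias_fully_corrected(self, monoexp_cohort):
        """f_syst = 1 with noiseless SPECT on mono-exponential truth: the
        hybrid rescaling cancels the shared factor, deviations are all zero."""
        noise = od.NoiseConfig(cv_planar_total=0.2, cv_spect=0.0, f_syst=1.0)
        patient = monoexp_cohort[0]
        rng = np.random.default_rng(5)
        deltas, n_clamped = simulate_deviations(
            patient, patient.kidney, hybrid((3, 96, 192)), "hybrid", noise,
            1000, rng)
        assert np.max(np.abs(deltas)) < 1e-9
        assert n_clamped == 0

    def test_incompatible_method_schedule_rejected(self, pinned_cohort):
        cfg = od.SearchConfig(n_reps=5, method="hybrid", seed=0)
        with pytest.raises(ValueError):
            od.schedule_metrics(pinned_cohort, od.SingleTPSchedule(52.0), cfg,
                                od.NoiseConfig())
        cfg1 = od.SearchConfig(n_reps=5, method="single_tp", seed=0)
        with pytest.raises(ValueError):
            od.schedule_metrics(pinned_cohort, hybrid((3, 96, 192)), cfg1,
                                od.NoiseConfig())


class TestBruteForceOracle:
    def test_two_tp_hybrid_matches_independent_monte_carlo(self):
        """One patient, mono-exponential truth, 2-TP hybrid, purely stochastic
        noise: pooled kidney moments agree with a from-scratch Monte-Carlo
        that composes the estimator formulas directly (within 3 SE)."""
        patient = make_monoexp_patient("solo", a0=7000.0, kidney_t_eff=40.0)
        t1, t2 = 20.0, 192.0
        sched = hybrid((t1, t2), anchor=0)
        noise = od.NoiseConfig(cv_planar_total=0.2, cv_spect=0.05, f_syst=0.0)
        n = 200_000

        # --- independent oracle: no shared simulation code ---
        rng = np.random.default_rng(987654)
        lam_eff = LN2 / 40.0
        c = patient.kidney.amplitude
        sig_p = math.sqrt(math.log(1 + 0.2 ** 2))
        sig_s = math.sqrt(math.log(1 + 0.05 ** 2))
        m1 = np.exp(sig_p * rng.standard_normal(n))
        m2 = np.exp(sig_p * rng.standard_normal(n))
        ms = np.exp(sig_s * rng.standard_normal(n))
        a_1 = c * math.exp(-lam_eff * t1) * m1
        a_2 = c * math.exp(-lam_eff * t2) * m2
        lam_fit = np.log(a_1 / a_2) / (t2 - t1)
        lam_fit = np.maximum(lam_fit, od.LAMBDA_PHYS)  # clamp rule
        a1_fit = a_1 * np.exp(lam_fit * t1)
        t_sp = t1 + 0.5
        a_sp = c * math.exp(-lam_eff * t_sp) * ms
        tiac = (a_sp / (a1_fit * np.exp(-lam_fit * t_sp))) * a1_fit \
            / (patient.a0 * lam_fit)
        truth = c / (patient.a0 * lam_eff)
        oracle = 100.0 * (tiac - truth) / truth

        cfg = od.SearchConfig(n_reps=n, method="hybrid", seed=13)
        m = od.schedule_metrics([patient], sched, cfg, noise)

        se_mu = math.sqrt(oracle.var() / n + m.sigma_k ** 2 / n)
        assert m.mu_k == pytest.approx(oracle.mean(), abs=3 * se_mu)
        se_sigma = oracle.std() / math.sqrt(n)  # conservative for two runs
        assert m.sigma_k == pytest.approx(oracle.std(), abs=3 * 2 * se_sigma)


class TestTrends:
    def test_rmse_decreases_with_f_syst(self, pinned_cohort):
        """At fixed 20 % total planar noise the hybrid method corrects a larger
        systematic share, so RMSE falls as f_syst rises 25 -> 50 -> 75 %."""
        sched = hybrid((3, 96, 192))
        cfg = od.SearchConfig(n_reps=2000, method="hybrid", seed=21)
        vals = []
        for f_syst in (0.25, 0.50, 0.75):
            m = od.schedule_metrics(pinned_cohort, sched, cfg,
                                    od.NoiseConfig(f_syst=f_syst))
            vals.append((m.rmse_k, m.rmse_t))
        tol = 3 * vals[0][0] / math.sqrt(2 * 13 * 2000)  # ~3 SE of the RMSE
        assert vals[0][0] > vals[1][0] - tol > vals[2][0] - 2 * tol
        assert vals[0][1] > vals[1][1] - tol > vals[2][1] - 2 * tol

    @pytest.mark.parametrize("param, levels", [
        ("cv_spect", (0.0, 0.05, 0.10)),
        ("cv_planar_total", (0.10, 0.20, 0.30)),
    ])
    def test_rmse_monotone_in_noise_level(self, pinned_cohort, param, levels):
        sched = hybrid((3, 96, 192))
        cfg = od.SearchConfig(n_reps=2000, method="hybrid", seed=22)
        vals = [
            od.schedule_metrics(pinned_cohort, sched, cfg,
                                od.NoiseConfig(**{param: lv})).rmse_k
            for lv in levels
        ]
        tol = 3 * max(vals) / math.sqrt(2 * 13 * 2000)
        assert vals[0] <= vals[1] + tol <= vals[2] + 2 * tol

    def test_single_tp_underestimates_tumours_at_52h(self, pinned_cohort):
        """Tumour effective half-lives mostly exceed 52 h, so the single-TP
        approximation underestimates the pooled tumour TIACs."""
        cfg = od.SearchConfig(n_reps=1000, method="single_tp", seed=23)
        m = od.schedule_metrics(pinned_cohort, od.SingleTPSchedule(52.0), cfg,
                                od.NoiseConfig())
        assert m.mu_t < 0


class TestFindOss:
    def _metrics(self, joint, t_last, times=(3.0, 96.0)):
        return od.ScheduleMetrics(
            schedule=od.HybridSchedule(od.PlanarSchedule((times[0], t_last)), 0),
            method="hybrid", mu_k=0, sigma_k=0, rmse_k=joint / 3,
            mu_t=0, sigma_t=0, rmse_t=joint / 3, rmse_joint=joint,
            n_reps=1, n_clamped_fits=0)

    def test_lowest_joint_first(self):
        ranked = od.find_oss([self._metrics(20.0, 192.0),
                              self._metrics(19.1, 192.0)])
        assert ranked[0].rmse_joint == 19.1

    def test_tie_broken_by_earlier_last_tp(self):
        ranked = od.find_oss([self._metrics(19.1, 192.0),
                              self._metrics(19.1, 96.0)])
        assert ranked[0].t_last == 96.0

    def test_ranking_invariant_under_permutation(self):
        ms = [self._metrics(j, t) for j, t in
              ((20.0, 192.0), (19.1, 96.0), (25.0, 48.0), (19.1, 192.0))]
        assert od.find_oss(ms) == od.find_oss(list(reversed(ms)))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            od.find_oss([])


@pytest.fixture(scope="module")
def small_metrics(pinned_cohort):
    grid = od.TimeGrid((4, 24, 48, 96, 192))
    cfg = od.SearchConfig(n_reps=100, method="hybrid", seed=31)
    return od.evaluate_schedules(
        pinned_cohort, od.enumerate_hybrid_schedules(grid, 2), cfg,
        od.NoiseConfig())


@pytest.fixture(scope="module")
def var_table(pinned_cohort):
    grid = od.TimeGrid((3, 24, 96, 144, 192))
    base = hybrid((3, 96, 192))
    cfg = od.SearchConfig(n_reps=60, method="hybrid", seed=41)
    return base, grid, od.vary_last_two(base, grid, pinned_cohort, cfg,
                                        od.NoiseConfig())


class TestConstrainedSearch:
    def test_full_limit_matches_unconstrained(self, small_metrics):
        table = od.constrained_search(small_metrics, [192.0])
        best = od.find_oss(small_metrics)[0]
        assert table.loc[0, "best_rmse_joint"] == pytest.approx(best.rmse_joint)
        assert table.loc[0, "n_schedules"] == len(small_metrics)

    def test_best_scores_non_increasing_in_t_last(self, small_metrics):
        table = od.constrained_search(small_metrics, [24.0, 48.0, 96.0, 192.0])
        for col in ("best_rmse_k", "best_rmse_t", "best_rmse_joint"):
            vals = table[col].to_numpy()
            assert np.all(np.diff(vals) <= 1e-12)

    def test_limit_excluding_everything_gives_empty_row(self, small_metrics):
        table = od.constrained_search(small_metrics, [2.0, 192.0])
        assert table.loc[0, "n_schedules"] == 0
        assert math.isnan(table.loc[0, "best_rmse_joint"])

    def test_unsorted_limits_rejected(self, small_metrics):
        with pytest.raises(ValueError):
            od.constrained_search(small_metrics, [96.0, 48.0])


class TestVaryLastTwo:
    def test_base_cell_matches_schedule_metrics(self, var_table, pinned_cohort):
        base, grid, table = var_table
        cfg = od.SearchConfig(n_reps=60, method="hybrid", seed=41)
        m = od.schedule_metrics(pinned_cohort, base, cfg, od.NoiseConfig())
        cell = table[(table.t_penultimate == 96) & (table.t_last == 192)]
        assert cell.iloc[0]["rmse_k"] == pytest.approx(m.rmse_k)
        assert cell.iloc[0]["rmse_t"] == pytest.approx(m.rmse_t)

    def test_only_ordered_pairs_present(self, var_table):
        _, _, table = var_table
        assert (table.t_penultimate < table.t_last).all()
        # the fixed first time (3 h) is excluded from the varied positions
        assert (table.t_penultimate > 3).all()

    def test_matrix_minimum_not_above_base_cell(self, var_table):
        _, _, table = var_table
        base_cell = table[(table.t_penultimate == 96) & (table.t_last == 192)]
        assert table["rmse_joint"].min() <= base_cell.iloc[0]["rmse_joint"]

    def test_sorted_long_format(self, var_table):
        _, _, table = var_table
        keys = list(zip(table.t_penultimate, table.t_last))
        assert keys == sorted(keys)
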