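"""Mismatch distributions, sudden-expansion fitting, neutrality tests."""

import math
from fractions import Fraction

import numpy as np
import pytest

import mitogeo as mg
from mitogeo.demography import (
    MismatchHistogram,
    _fs_from_counts,
    ewens_prob_k_at_least,
    neutral_coalescent_stats,
    raggedness,
    tajima_constants,
)


class TestMismatchHistogram:
    def test_two_identical_sequences(self):
        aln = mg.Alignment.from_sequences(["a", "b"], ["ACGT", "ACGT"])
        h = mg.mismatch_histogram(mg.pairwise_diff_matrix(aln))
        assert h.counts.tolist() == [1]

    def test_three_sequences_distances(self):
        m = np.array([[0, 1, 1], [1, 0, 2], [1, 2, 0]])
        h = mg.mismatch_histogram(m)
        assert h.counts.tolist() == [0, 2, 1]

    def test_mass_conservation(self, rng):
        n = 9
        m = np.zeros((n, n), dtype=int)
        iu = np.triu_indices(n, 1)
        m[iu] = rng.integers(0, 6, size=len(iu[0]))
        m += m.T
        h = mg.mismatch_histogram(m)
        assert h.counts.sum() == n * (n - 1) // 2

    def test_raw_modality_sees_planted_dip(self):
        h = MismatchHistogram(np.array([210, 150, 245, 150, 25]), 40)
        assert h.n_modes(smooth=False) == 2
        # the 3-point smoother cannot resolve modes one dip class apart
        assert h.n_modes(smooth=True) == 1


class TestExpectedMismatch:
    @pytest.mark.parametrize("theta", [0.5, 2.0, 10.0])
    def test_equilibrium_closed_form(self, theta):
        i = np.arange(51, dtype=float)
        exact = theta**i / (1 + theta) ** (i + 1)
        for tau in (0.7, 3.7, 12.0):
            F = mg.expected_mismatch(tau, theta, theta, 50)
            assert np.abs(F - exact).max() < 1e-10

    def test_tau_zero_is_theta0_equilibrium(self):
        i = np.arange(31, dtype=float)
        F = mg.expected_mismatch(0.0, 0.5, 50.0, 30)
        assert np.allclose(F, 0.5**i / 1.5 ** (i + 1), atol=1e-12)

    def test_nonnegative_and_renormalized_sum(self):
        F = mg.expected_mismatch(4.0, 0.5, 50.0, 40, renormalize=True)
        assert (F >= 0).all()
        assert F.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_monte_carlo_pair_simulation(self):
        # independent oracle: simulate 1e5 coalescent pairs directly
        tau, th0, th1 = 5.0, 1.0, 100.0
        rng = np.random.default_rng(7)
        n = 100_000
        t_recent = rng.exponential(th1, size=n)
        t = np.where(t_recent < tau, t_recent,
                     tau + rng.exponential(th0, size=n))
        diffs = rng.poisson(t)
        i_max = 40
        emp = np.bincount(np.clip(diffs, 0, i_max + 1), minlength=i_max + 2)
        emp = emp[: i_max + 1] / n
        F = mg.expected_mismatch(tau, th0, th1, i_max)
        se = np.sqrt(F * (1 - F) / n) + 1e-4
        assert (np.abs(emp - F) < 5 * se).all()

    def test_invalid_parameters_error(self):
        with pytest.raises(ValueError):
            mg.expected_mismatch(-1.0, 1.0, 1.0, 10)
        with pytest.raises(ValueError):
            mg.expected_mismatch(float("nan"), 1.0, 1.0, 10)


class TestRaggedness:
    def test_uniform_five_class_value(self):
        assert raggedness([0.2] * 5) == pytest.approx(0.08)

    def test_spike_is_maximal_on_same_support(self, rng):
        spike = np.zeros(6)
        spike[3] = 1.0
        r_spike = raggedness(spike)
        for _ in range(50):
            x = rng.dirichlet(np.ones(6))
            assert raggedness(x) <= r_spike + 1e-12


class TestFit:
    def test_equilibrium_histogram_gives_theta0_close_to_theta1(self):
        F = mg.expected_mismatch(0.0, 3.0, 3.0, 40)
        fit = mg.fit_sudden_expansion(F)
        assert fit.ssd < 1e-10
        # equilibrium is parameter-degenerate in tau; the two sizes must
        # bracket the true equilibrium theta at the fitted tau
        exp = mg.expected_mismatch(fit.tau, fit.theta0, fit.theta1, 40)
        assert np.abs(exp - F).max() < 1e-5

    def test_translation_moves_tau_up(self):
        base = mg.expected_mismatch(3.0, 0.3, 60.0, 60)[:40]
        taus = []
        for shift in (0, 4, 8):
            shifted = np.concatenate([np.zeros(shift), base])[:60]
            taus.append(mg.fit_sudden_expansion(shifted).tau)
        assert taus[0] < taus[1] < taus[2]

    def test_degenerate_histogram_flagged(self):
        h = MismatchHistogram(np.array([10]), 5)
        fit = mg.fit_sudden_expansion(h)
        assert fit.degenerate and fit.tau == 0.0

    def test_model_results_summary_and_expected(self):
        aln, _ = mg.make_star_expansion(n=30, n_tip_haplotypes=8, seed=5)
        model = mg.SuddenExpansionModel.from_alignment(aln)
        res = model.fit()
        assert "tau" in res.summary()
        assert res.expected().size == model.hist.counts.size


class TestExpansionGof:
    def test_bootstrap_pvalues_in_range_and_reproducible(self):
        aln, _ = mg.sudden_expansion_demography(0.5, 50.0, 4.0, 30, 866, seed=9)
        model = mg.SuddenExpansionModel.from_alignment(aln)
        r1 = model.fit(n_boot=20, seed=4)
        r2 = model.fit(n_boot=20, seed=4)
        assert 0.0 <= r1.fit.p_ssd <= 1.0 and 0.0 <= r1.fit.p_rg <= 1.0
        assert r1.fit.p_ssd == r2.fit.p_ssd and r1.fit.rg == r2.fit.rg

    def test_small_n_boot_warns(self):
        aln, _ = mg.sudden_expansion_demography(0.5, 20.0, 3.0, 20, 866, seed=2)
        model = mg.SuddenExpansionModel.from_alignment(aln)
        with pytest.warns(UserWarning):
            model.fit(n_boot=5, seed=1)


class TestTajimasD:
    def test_s_zero_undefined(self):
        d, p = mg.tajimas_d(0, 0.0, 10)
        assert math.isnan(d) and p is None

    def test_zero_numerator(self):
        c = tajima_constants(10)
        d, _ = mg.tajimas_d(5, 5 / c["a1"], 10, reps=100, seed=1)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_dual_implementation_oracle(self):
        # independently coded textbook-constant computation
        n, S, kbar = 20, 16, 3.0
        a1 = sum(1.0 / i for i in range(1, n))
        a2 = sum(1.0 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        expected = (kbar - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
        d, _ = mg.tajimas_d(S, kbar, n, reps=100, seed=1)
        assert d == pytest.approx(expected, abs=1e-10)

    def test_beta_approximation_agrees_roughly_with_simulation(self):
        d_sim, p_sim = mg.tajimas_d(10, 1.2, 25, reps=20_000, seed=5)
        d_beta, p_beta = mg.tajimas_d(10, 1.2, 25, method="beta")
        assert d_sim == d_beta
        assert abs(p_sim - p_beta) < 0.15


class TestFusFs:
    def test_k_obs_one_flagged_infinite(self):
        fs, p = mg.fus_fs(10, 2.0, 1)
        assert math.isinf(fs) and p is None

    def test_exact_rational_ewens_oracle(self):
        def stirling_table(n):
            s = {(0, 0): 1}
            for m in range(1, n + 1):
                for k in range(m + 1):
                    s[(m, k)] = s.get((m - 1, k - 1), 0) + (m - 1) * s.get((m - 1, k), 0)
            return s

        for n in range(3, 13):
            tab = stirling_table(n)
            for theta in (0.5, 1.0, 5.0):
                th = Fraction(theta)
                denom = sum(tab[(n, k)] * th**k for k in range(1, n + 1))
                for k_obs in range(1, n + 1):
                    num = sum(tab[(n, k)] * th**k for k in range(k_obs, n + 1))
                    exact = float(num / denom)
                    got = ewens_prob_k_at_least(n, k_obs, theta)
                    assert got == pytest.approx(exact, abs=1e-12)

    def test_star_fixture_strongly_negative(self):
        aln, _ = mg.make_star_expansion(n=50, n_tip_haplotypes=12, seed=8)
        ns = mg.neutrality_tests(aln, reps=200, seed=1)
        assert ns.Fs < -5

    def test_pvalue_reproducible(self):
        a = mg.fus_fs(20, 3.0, 10, reps=2000, seed=11)
        b = mg.fus_fs(20, 3.0, 10, reps=2000, seed=11)
        assert a == b


class TestNullEngine:
    def test_moments_match_msprime_cross_check(self):
        """Dual-route check of the vectorized null engine against msprime."""
        n, theta = 15, 4.0
        rng = np.random.default_rng(3)
        S, kbar, K = neutral_coalescent_stats(n, theta, 4000, rng)
        ms_S, ms_kbar, ms_K = [], [], []
        for r in range(400):
            aln, _ = mg.constant_population(theta, n, 2000, seed=5000 + r)
            ms_S.append(mg.segregating_sites(aln))
            ms_kbar.append(mg.mean_pairwise_differences(aln))
            ht = mg.collapse_haplotypes(aln)
            ms_K.append(ht.h)
        assert np.mean(S) == pytest.approx(np.mean(ms_S), rel=0.1)
        assert np.mean(kbar) == pytest.approx(np.mean(ms_kbar), rel=0.1)
        assert np.mean(K) == pytest.approx(np.mean(ms_K), rel=0.1)

    def test_fs_array_matches_scalar_path(self):
        rng = np.random.default_rng(1)
        _, kbar, K = neutral_coalescent_stats(12, 3.0, 50, rng)
        arr = _fs_from_counts(12, kbar, K)
        for i in range(50):
            if K[i] > 1 and kbar[i] > 0:
                sp = ewens_prob_k_at_least(12, int(K[i]), float(kbar[i]))
                expected = math.log(sp / (1 - sp))
                assert arr[i] == pytest.approx(expected, rel=1e-8)


class TestNeutralitySummary:
    def test_group_report_fields(self):
        aln, table = mg.make_star_expansion(seed=2)
        ns = mg.neutrality_tests(aln, reps=500, seed=9)
        assert ns.n == aln.n and ns.S > 0
        assert 0 <= ns.p_D <= 1 and 0 <= ns.p_Fs <= 1
        assert ns.fs_significant in (True, False)
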