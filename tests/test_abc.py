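"""ABC: priors, summary statistics, reference tables, model choice."""

import numpy as np
import pytest

import mitogeo as mg
from mitogeo.abc import (
    PriorSpec,
    _stats_from_matrix,
    build_reference_table,
    estimate_parameters,
    model_choice,
    sample_priors,
    stat_names,
    summary_statistics,
    to_years,
)
from mitogeo.coalsim import SCENARIO_KINDS

from conftest import oracle_indices, oracle_pair_diff, oracle_usable_cols


class TestPriors:
    def test_draws_within_bounds(self):
        spec = PriorSpec()
        rng = np.random.default_rng(1)
        for _ in range(200):
            scen, mu = sample_priors(spec, "sudden_trifurcation", rng)
            assert all(10 <= x <= 10_000 for x in scen.ne)
            assert 10 <= scen.ne_ancestral <= 10_000
            assert 10 <= scen.t1 <= 10_000
            assert 1e-8 <= mu <= 1e-6

    def test_gradual_times_ordered_always(self):
        spec = PriorSpec()
        rng = np.random.default_rng(2)
        for _ in range(500):
            scen, _ = sample_priors(spec, "gradual_north_derived", rng)
            assert scen.t1 < scen.t2

    def test_ne_mean_matches_uniform_moment(self):
        spec = PriorSpec()
        rng = np.random.default_rng(3)
        draws = [sample_priors(spec, "sudden_trifurcation", rng)[0].ne[0]
                 for _ in range(10_000)]
        se = np.std(draws) / np.sqrt(len(draws))
        assert abs(np.mean(draws) - 5005.0) < 4 * se

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(ne_bounds=(100.0, 100.0))


class TestSummaryStatistics:
    def _table(self, aln, sizes):
        rows, k = [], 0
        for g, n in zip(("A", "B", "C")[: len(sizes)], sizes):
            for _ in range(n):
                rows.append((aln.sample_ids[k], "x", g, ""))
                k += 1
        return mg.SampleTable.from_records(rows)

    def test_all_identical_degenerate_conventions(self):
        aln = mg.Alignment.from_sequences([f"s{i}" for i in range(6)],
                                          ["ACGT"] * 6)
        v = summary_statistics(aln, self._table(aln, (3, 3)))
        s = v.as_series()
        assert s["A_h"] == 1 and s["B_h"] == 1
        assert s["A_S"] == 0 and s["A|B_FST"] == 0.0 and s["A|B_B"] == 0.0

    def test_fixed_difference_fst_one(self):
        aln = mg.Alignment.from_sequences(
            [f"s{i}" for i in range(6)],
            ["ACGTAA"] * 3 + ["TCGTAC"] * 3,  # fixed at 2 sites
        )
        v = summary_statistics(aln, self._table(aln, (3, 3)))
        s = v.as_series()
        assert s["A|B_FST"] == 1.0 and s["A|B_B"] == 2.0 and s["A|B_W"] == 0.0

    def test_private_segregating_sites(self):
        aln = mg.Alignment.from_sequences(
            [f"s{i}" for i in range(6)],
            ["AAAA", "AAAT", "AAAA", "CCAA", "CGAA", "CCAA"],
        )
        s = summary_statistics(aln, self._table(aln, (3, 3))).as_series()
        assert s["A_privS"] == 1  # column 4 segregates only in A
        assert s["B_privS"] == 1  # column 2 segregates only in B

    def test_matches_brute_force_oracle(self, rng):
        from conftest import random_toy_alignment

        aln = random_toy_alignment(rng, 12, 25)
        sizes = (4, 4, 4)
        table = self._table(aln, sizes)
        v = summary_statistics(aln, table).as_series()
        seqs = [aln.sequence(i) for i in range(12)]
        cols = oracle_usable_cols(seqs)
        groups = {"A": seqs[:4], "B": seqs[4:8], "C": seqs[8:]}
        for g, gs in groups.items():
            exp = oracle_indices(gs)
            assert v[f"{g}_h"] == exp["h"]
            assert v[f"{g}_S"] == exp["S"]
            assert v[f"{g}_kbar"] == pytest.approx(exp["kbar"])
            # private segregating: segregating in g, invariant elsewhere
            priv = 0
            for j in cols:
                if len({s[j] for s in gs}) > 1 and all(
                    len({s[j] for s in og}) == 1
                    for og_name, og in groups.items() if og_name != g
                ):
                    priv += 1
            assert v[f"{g}_privS"] == priv
        for a, b in (("A", "B"), ("A", "C"), ("B", "C")):
            ga, gb = groups[a], groups[b]
            cross = [oracle_pair_diff(x, y, cols) for x in ga for y in gb]
            within = [oracle_pair_diff(x, y, cols)
                      for grp in (ga, gb)
                      for i, x in enumerate(grp) for y in grp[i + 1:]]
            B = np.mean(cross)
            W = np.mean(within)
            assert v[f"{a}|{b}_B"] == pytest.approx(B)
            assert v[f"{a}|{b}_W"] == pytest.approx(W)
            fst = float(np.clip(1 - W / B, 0, 1)) if B > 0 else 0.0
            assert v[f"{a}|{b}_FST"] == pytest.approx(fst)

    def test_group_too_small_errors(self):
        aln = mg.Alignment.from_sequences([f"s{i}" for i in range(3)],
                                          ["ACGT"] * 3)
        table = mg.SampleTable.from_records(
            [("s0", "x", "A", ""), ("s1", "x", "A", ""), ("s2", "x", "B", "")])
        with pytest.raises(ValueError, match="n < 2"):
            summary_statistics(aln, table)


class TestReferenceTable:
    def test_row_counts_and_determinism(self):
        rt1 = build_reference_table(SCENARIO_KINDS, PriorSpec(), 10, (4, 4, 4),
                                    200, seed=5)
        rt2 = build_reference_table(SCENARIO_KINDS, PriorSpec(), 10, (4, 4, 4),
                                    200, seed=5)
        assert rt1.n_rows == 30
        assert rt1.frame.equals(rt2.frame)
        assert sorted(rt1.frame["scenario"].unique()) == [1, 2, 3]

    def test_t2_only_for_gradual_scenarios(self):
        rt = build_reference_table(SCENARIO_KINDS, PriorSpec(), 5, (3, 3, 3),
                                   200, seed=1)
        assert rt.frame.loc[rt.frame.scenario == 3, "t2"].isna().all()
        assert rt.frame.loc[rt.frame.scenario != 3, "t2"].notna().all()

    def test_concat_combines_disjoint_seeds(self):
        a = build_reference_table(["sudden_trifurcation"], PriorSpec(), 5,
                                  (3, 3, 3), 200, seed=1)
        b = build_reference_table(["sudden_trifurcation"], PriorSpec(), 5,
                                  (3, 3, 3), 200, seed=2)
        both = mg.ReferenceTable.concat([a, b])
        assert both.n_rows == 10


@pytest.fixture(scope="module")
def small_rt():
    return build_reference_table(SCENARIO_KINDS, PriorSpec(), 300, (8, 8, 8),
                                 866, seed=99)


class TestModelChoice:
    def test_probabilities_sum_to_one(self, small_rt):
        obs = small_rt.stats()[17]
        mc = model_choice(obs, small_rt, n_closest=90)
        assert mc.table["prob"].sum() == pytest.approx(1.0, abs=1e-6)
        assert set(mc.table["scenario"]) == {1, 2, 3}

    def test_ci_contains_point_estimate(self, small_rt):
        obs = small_rt.stats()[3]
        mc = model_choice(obs, small_rt, n_closest=90)
        for _, r in mc.table.iterrows():
            assert r["lo"] - 1e-9 <= r["prob"] <= r["hi"] + 1e-9 or r["prob"] == 0.0

    def test_invariant_under_row_duplication(self, small_rt):
        obs = small_rt.stats()[11]
        dup = mg.ReferenceTable.concat([small_rt, small_rt])
        a = model_choice(obs, small_rt, n_closest=60)
        b = model_choice(obs, dup, n_closest=120)
        assert np.allclose(a.table["prob"], b.table["prob"], atol=1e-6)

    def test_invariant_under_affine_rescaling(self, small_rt):
        obs = small_rt.stats()[5].copy()
        scaled = small_rt.frame.copy()
        col = small_rt.stat_names[2]
        scaled[col] = scaled[col] * 37.0 + 11.0
        j = small_rt.stat_names.index(col)
        obs2 = obs.copy()
        obs2[j] = obs2[j] * 37.0 + 11.0
        rt2 = mg.ReferenceTable(scaled, small_rt.stat_names, small_rt.priors,
                                small_rt.sample_sizes, small_rt.L)
        a = model_choice(obs, small_rt, n_closest=60)
        b = model_choice(obs2, rt2, n_closest=60)
        assert np.allclose(a.table["prob"], b.table["prob"], atol=1e-6)

    def test_symmetric_reference_gives_uniform_probabilities(self):
        # all scenarios generated from the identical model -> ~1/3 each
        rng = np.random.default_rng(4)
        m = 900
        stats = rng.normal(size=(m, 5))
        frame_rows = []
        for i in range(m):
            row = {"scenario": (i % 3) + 1, "ne1": 1.0, "ne2": 1.0, "ne3": 1.0,
                   "ne_anc": 1.0, "t1": 1.0, "t2": 1.0, "mu": 1e-7}
            row.update({f"st{j}": stats[i, j] for j in range(5)})
            frame_rows.append(row)
        import pandas as pd

        rt = mg.ReferenceTable(pd.DataFrame(frame_rows),
                               tuple(f"st{j}" for j in range(5)),
                               PriorSpec(), (4, 4, 4), 100)
        probs = []
        for r in range(30):
            mc = model_choice(rng.normal(size=5), rt, n_closest=300)
            probs.append([mc.probabilities[s] for s in (1, 2, 3)])
        mean = np.mean(probs, axis=0)
        assert np.allclose(mean, 1 / 3, atol=0.1)

    def test_n_closest_cannot_exceed_rows(self, small_rt):
        with pytest.raises(ValueError):
            model_choice(small_rt.stats()[0], small_rt, n_closest=10_000)


class TestEstimateParameters:
    def test_homogeneous_table_collapses_to_value(self, small_rt):
        import pandas as pd

        frame = small_rt.frame[small_rt.frame.scenario == 3].copy()
        for p in ("ne1", "ne2", "ne3", "ne_anc", "t1", "mu"):
            frame[p] = 123.0 if p != "mu" else 1e-7
        rt = mg.ReferenceTable(frame.reset_index(drop=True), small_rt.stat_names,
                               small_rt.priors, small_rt.sample_sizes, small_rt.L)
        est = estimate_parameters(rt, 3, small_rt.stats()[0], n_closest=50)
        row = est[est.param == "ne1"].iloc[0]
        assert row["median"] == pytest.approx(123.0)
        assert row["q2.5"] == pytest.approx(123.0)

    def test_zero_slope_equals_rejection_percentiles(self, small_rt):
        # evaluating at a point whose accepted stats are symmetric noise with
        # no linear trend leaves the adjustment a no-op up to regression noise
        obs = small_rt.stats()[7]
        est = estimate_parameters(small_rt, 1, obs, n_closest=80)
        assert (est["q2.5"] <= est["median"]).all()
        assert (est["median"] <= est["q97.5"]).all()

    def test_recovery_covers_truth(self):
        from mitogeo.abc import _stats_from_matrix
        from mitogeo.coalsim import Scenario, SimParams, simulate_matrix

        rt = build_reference_table(["sudden_trifurcation"], PriorSpec(), 1500,
                                   (10, 10, 10), 866, seed=17)
        truth = Scenario("sudden_trifurcation", ("P1", "P2", "P3"),
                         (3000.0, 3000.0, 3000.0), 3000.0, 1500.0)
        hits = 0
        for r in range(10):
            G = simulate_matrix(truth, SimParams(3e-7, (10, 10, 10), 866,
                                                 seed=700 + r))
            obs = _stats_from_matrix(G, (10, 10, 10), ("P1", "P2", "P3"))
            est = estimate_parameters(rt, 3, obs, n_closest=100)
            row = est[est.param == "t1"].iloc[0]
            hits += row["q2.5"] <= 1500.0 <= row["q97.5"]
        assert hits >= 8


class TestYears:
    @pytest.mark.parametrize("gens, years", [(0, 0), (770, 7_700), (1_200, 12_000)])
    def test_generation_time_conversion(self, gens, years):
        assert to_years(gens) == years

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            to_years(-1)


class TestABCModelFacade:
    def test_end_to_end_on_pseudoobs(self):
        from mitogeo.coalsim import Scenario

        truth = Scenario("sudden_trifurcation", ("P1", "P2", "P3"),
                         (2000.0, 2000.0, 2000.0), 2000.0, 1000.0)
        aln, table, rec = mg.make_pseudoobs(truth, (8, 8, 8), 5e-7, seed=13)
        model = mg.ABCModel.from_alignment(aln, table)
        model.simulate_reference(200, seed=8)
        res = model.fit()
        assert res.scenario_table["prob"].sum() == pytest.approx(1.0, abs=1e-6)
        assert res.selected_scenario in (1, 2, 3)
        assert "scenario" in res.summary()
        assert not res.times_in_years().empty

    def test_fit_before_reference_errors(self):
        obs = mg.SummaryStatVector(np.zeros(3), ("a", "b", "c"), ("P1", "P2"))
        model = mg.ABCModel(obs, (4, 4))
        with pytest.raises(RuntimeError):
            model.fit()
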