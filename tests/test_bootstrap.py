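"""The distance statistic, bootstrap null, empirical p-value, and FDR control."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dynagsea import (
    AnalysisConfig,
    BootstrapSetEnrichment,
    ContractError,
    GeneSet,
    GeneSetCollection,
    NullDistribution,
    Profile,
    adjust_pvalues,
    background_profile,
    distance_to_background,
    exact_p,
    p_value,
    run_analysis,
    sample_null,
    write_results,
)
from dynagsea.bootstrap_test import derive_set_seed
from dynagsea.synthetic_data import SetSpec, SyntheticConfig, simulate_dataset

from conftest import collection, make_matrix, random_scaled


def profile(values):
    values = np.asarray(values, dtype=float)
    return Profile(tuple(f"t{j}" for j in range(values.size)), values, 1)


def null_from(distances):
    return NullDistribution(np.asarray(distances, float), 3, 0, "without_replacement")


class TestDistance:
    def test_identical_profiles(self):
        p = profile([0.1, -0.2, 0.1])
        assert distance_to_background(p, p) == 0.0

    def test_three_four_five(self):
        a = profile([3.0, 4.0, 0.0, 0.0])
        b = profile([0.0, 0.0, 0.0, 0.0])
        assert distance_to_background(a, b) == 5.0

    def test_mismatched_labels_rejected(self):
        a = profile([1.0, 2.0])
        b = Profile(("x", "y"), np.array([1.0, 2.0]), 1)
        with pytest.raises(ContractError):
            distance_to_background(a, b)

    def test_matches_elementwise_oracle(self, rng):
        a, b = profile(rng.normal(size=9)), profile(rng.normal(size=9))
        oracle = sum((x - y) ** 2 for x, y in zip(a.values, b.values)) ** 0.5
        assert distance_to_background(a, b) == pytest.approx(oracle, rel=1e-12)


class TestPValue:
    @pytest.mark.parametrize("exceed, want", [
        (0, Fraction(1, 1001)),
        (500, Fraction(501, 1001)),
        (1000, Fraction(1001, 1001)),
    ])
    def test_plus_one_correction_exact(self, exceed, want):
        distances = np.concatenate([
            np.full(exceed, 2.0), np.full(1000 - exceed, 0.5)
        ])
        p = p_value(1.0, null_from(distances))
        assert Fraction(p).limit_denominator(2002) == want

    def test_d_zero_with_positive_null_gives_one(self):
        assert p_value(0.0, null_from(np.linspace(0.1, 1, 1000))) == 1.0

    def test_all_ties_hit_lower_bound(self):
        # strict exceedance: d0 == d never counts, so p = 1/(B+1)
        p = p_value(1.0, null_from(np.full(99, 1.0)))
        assert Fraction(p).limit_denominator(200) == Fraction(1, 100)

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(0, 10), min_size=1, max_size=200))
    def test_bounds_and_monotonicity(self, distances):
        null = null_from(distances)
        b = null.n_boot
        grid = np.linspace(-1, 11, 25)
        ps = [p_value(d, null) for d in grid]
        assert all(1 / (b + 1) <= p <= 1 for p in ps)
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))  # nonincreasing in d


class TestSampleNull:
    def test_whole_universe_sample_has_zero_distance(self, rng):
        scaled = random_scaled(rng, 6, 5)
        cfg = AnalysisConfig(n_boot=50, seed=1)
        null = sample_null(scaled, set_size=6, config=cfg)
        np.testing.assert_allclose(null.distances, 0.0, atol=1e-12)

    def test_reproducible_for_same_seed(self, rng):
        scaled = random_scaled(rng, 30, 6)
        cfg = AnalysisConfig(n_boot=200, seed=9)
        a = sample_null(scaled, 5, cfg, set_name="s")
        b = sample_null(scaled, 5, cfg, set_name="s")
        np.testing.assert_array_equal(a.distances, b.distances)
        c = sample_null(scaled, 5, cfg, set_name="other")
        assert not np.array_equal(a.distances, c.distances)

    def test_oversized_set_rejected_without_replacement(self, rng):
        scaled = random_scaled(rng, 4, 5)
        with pytest.raises(ContractError):
            sample_null(scaled, 5, AnalysisConfig(n_boot=10))

    def test_with_replacement_mode_runs(self, rng):
        scaled = random_scaled(rng, 4, 5)
        cfg = AnalysisConfig(n_boot=100, sampling="with_replacement", seed=3)
        null = sample_null(scaled, 8, cfg)  # multiset larger than universe is fine
        assert null.n_boot == 100 and (null.distances >= 0).all()

    def test_matches_enumeration_distribution(self, rng):
        """Empirical null on a 6-gene universe, sets of 2, vs all 15 subsets."""
        scaled = random_scaled(rng, 6, 9)
        background = background_profile(scaled)
        from itertools import combinations
        exact = np.sort([
            float(np.linalg.norm(scaled.values[list(c)].mean(axis=0)
                                 - background.values))
            for c in combinations(range(6), 2)
        ])
        null = sample_null(scaled, 2, AnalysisConfig(n_boot=1000, seed=5))
        # KS distance between the empirical sample and the exact discrete CDF;
        # evaluate just above each atom so float jitter at ties cannot bias it
        ecdf = np.searchsorted(np.sort(null.distances), exact + 1e-9) / 1000
        cdf = np.arange(1, 16) / 15
        assert np.max(np.abs(ecdf - cdf)) < 0.07  # DKW bound at B=1000


class TestExactP:
    def test_denominator_is_subsets_plus_one(self, rng):
        scaled = random_scaled(rng, 6, 4)
        p = exact_p(scaled, {"g0", "g3"})
        assert (p * (comb(6, 2) + 1)) == pytest.approx(round(p * 16), abs=1e-12)

    def test_whole_universe_gives_one_half(self, rng):
        scaled = random_scaled(rng, 5, 4)
        assert exact_p(scaled, set(scaled.gene_ids)) == 0.5

    def test_cap_exceeded(self, rng):
        scaled = random_scaled(rng, 30, 4)
        with pytest.raises(ContractError, match="cap"):
            exact_p(scaled, {"g0", "g1", "g2", "g3", "g4"}, cap=100)

    def test_bootstrap_agrees_with_enumeration(self, rng):
        scaled = random_scaled(rng, 8, 5)
        members = {"g1", "g4", "g6"}
        truth = exact_p(scaled, members)
        c = comb(8, 3)
        q = (truth * (c + 1) - 1) / c  # exceedance probability K/C
        cfg = AnalysisConfig(n_boot=20_000, seed=11)
        null = sample_null(scaled, 3, cfg)
        from dynagsea import set_profile
        d = distance_to_background(
            set_profile(scaled, members), background_profile(scaled)
        )
        boot = p_value(d, null)
        expected = (cfg.n_boot * q + 1) / (cfg.n_boot + 1)
        se = (q * (1 - q) / cfg.n_boot) ** 0.5
        assert abs(boot - expected) <= 3 * se


class TestAdjustPValues:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_pvalues([0.03]), [0.03])

    def test_bh_step_up_hand_computed(self):
        # 0.01*3/1, 0.02*3/2, 0.03*3/3 -> all 0.03 after the step-up pass
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-12
        )

    def test_equal_inputs_stay_equal(self):
        out = adjust_pvalues([0.2, 0.2, 0.2, 0.2])
        np.testing.assert_allclose(out, 0.2)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.5], [np.nan]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ContractError):
            adjust_pvalues(bad)

    def test_bonferroni_and_holm(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.04], method="bonferroni"), [0.02, 0.08]
        )
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.04], method="holm"), [0.02, 0.04]
        )

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    def test_bh_monotone_and_dominates_raw(self, ps):
        adj = adjust_pvalues(ps)
        assert np.all(adj <= 1.0 + 1e-12)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)


def small_benchmark(seed=3):
    sets = (SetSpec("hot", 30, "late_sustained", 3.0),) + tuple(
        SetSpec(f"null_{i}", 25) for i in range(5)
    )
    return simulate_dataset(SyntheticConfig(n_genes=400, sets=sets, seed=seed))


class TestRunAnalysis:
    def test_injected_set_ranks_first(self):
        ds = small_benchmark()
        res = run_analysis(ds.matrix, ds.sets, AnalysisConfig(n_boot=500, seed=3))
        best = min((r for r in res if r.testable), key=lambda r: (r.p_raw, r.set_name))
        assert best.set_name == "hot"
        assert best.p_adj < 0.05

    def test_deterministic_results_table(self, tmp_path):
        ds = small_benchmark()
        cfg = AnalysisConfig(n_boot=300, seed=8)
        for name in ("a.tsv", "b.tsv"):
            write_results(run_analysis(ds.matrix, ds.sets, cfg), tmp_path / name)
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_untestable_set_carried_not_dropped(self, rng):
        scaled_src = make_matrix(rng.normal(size=(10, 5)))
        sets = collection(
            ("big", [f"g{i}" for i in range(6)]),
            ("tiny", ["g0", "absent_x", "absent_y"]),
        )
        res = run_analysis(scaled_src, sets, AnalysisConfig(n_boot=100, seed=1))
        by_name = {r.set_name: r for r in res}
        assert by_name["big"].testable and by_name["big"].p_adj is not None
        tiny = by_name["tiny"]
        assert not tiny.testable and tiny.p_raw is None and tiny.overlap == 1

    def test_per_set_seed_stable_under_collection_changes(self, rng):
        mat = make_matrix(rng.normal(size=(50, 6)))
        both = collection(("A", [f"g{i}" for i in range(5)]),
                          ("B", [f"g{i}" for i in range(10, 16)]))
        only_a = collection(("A", [f"g{i}" for i in range(5)]))
        cfg = AnalysisConfig(n_boot=200, seed=4)
        p_with = {r.set_name: r.p_raw for r in run_analysis(mat, both, cfg)}
        p_without = {r.set_name: r.p_raw for r in run_analysis(mat, only_a, cfg)}
        assert p_with["A"] == p_without["A"]

    def test_multiplicity_counts_testable_sets_only(self, rng):
        mat = make_matrix(rng.normal(size=(30, 6)))
        sets = collection(
            ("A", [f"g{i}" for i in range(4)]),
            ("B", [f"g{i}" for i in range(5, 9)]),
            ("skip", ["absent"]),
        )
        res = run_analysis(mat, sets, AnalysisConfig(n_boot=100, seed=2))
        testable = [r for r in res if r.testable]
        raw = [r.p_raw for r in testable]
        np.testing.assert_allclose(
            [r.p_adj for r in testable], adjust_pvalues(raw)
        )

    def test_estimator_interface(self):
        ds = small_benchmark()
        est = BootstrapSetEnrichment(n_boot=200, random_state=1)
        params = est.get_params()
        assert params["n_boot"] == 200 and params["adjust"] == "fdr_bh"
        est.set_params(n_boot=150)
        est.fit(ds.matrix.to_frame(), ds.sets)
        frame = est.results_frame()
        assert len(frame) == len(ds.sets)
        assert est.n_testable_ == len(ds.sets)
        assert "hot" in est.significant_sets()


def test_derived_seeds_are_stable_and_31_bit():
    s1 = derive_set_seed(42, "HH")
    assert s1 == derive_set_seed(42, "HH")
    assert 0 <= s1 < 2**31
    assert s1 != derive_set_seed(43, "HH") != derive_set_seed(43, "WNT")
    assert derive_set_seed(7, None) == 7
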