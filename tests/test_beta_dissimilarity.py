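import numpy as np
import pytest

from divgrad.beta_dissimilarity import (
    TRANSITIONS,
    _transition_blocks,
    between_habitat_pairs,
    bootstrap_se,
    sorensen,
    transition_code,
    transition_means,
    within_habitat_pairs,
)
from divgrad.synthetic_data import LandscapeConfig, generate_landscape

from conftest import make_matrix, make_meta, one_location_design


class TestSorensen:
    def test_identical_plots(self):
        pc = sorensen([1, 1, 1, 1], [1, 1, 1, 1])
        assert pc.S == 1.0 and pc.beta == 0.0 and pc.C == 4

    def test_disjoint_plots(self):
        pc = sorensen([1, 1, 1, 0, 0], [0, 0, 0, 1, 1])
        assert (pc.A, pc.B, pc.C) == (3, 2, 0)
        assert pc.S == 0.0 and pc.beta == 1.0

    def test_partial_overlap_forced_by_formula(self):
        a = [1, 1, 1, 1, 0, 0, 0]
        b = [1, 1, 1, 0, 1, 1, 1]
        pc = sorensen(a, b)
        assert (pc.A, pc.B, pc.C) == (4, 6, 3)
        assert pc.S == pytest.approx(0.6) and pc.beta == pytest.approx(0.4)

    def test_both_empty_is_undefined(self):
        pc = sorensen([0, 0], [0, 0])
        assert not pc.defined

    def test_one_empty_is_full_dissimilarity(self):
        pc = sorensen([1, 0], [0, 0])
        assert pc.beta == 1.0

    def test_symmetry_range_and_set_oracle_on_random_pairs(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = rng.integers(1, 30)
            a = rng.integers(0, 2, n)
            b = rng.integers(0, 2, n)
            pc = sorensen(a, b)
            rev = sorensen(b, a)
            sa, sb = {i for i in range(n) if a[i]}, {i for i in range(n) if b[i]}
            if not sa and not sb:
                assert not pc.defined
                continue
            assert pc.beta == rev.beta == pytest.approx(
                1 - 2 * len(sa & sb) / (len(sa) + len(sb))
            )
            assert 0.0 <= pc.beta <= 1.0
            assert (pc.beta == 0.0) == (sa == sb)
            assert (pc.beta == 1.0) == (not (sa & sb))


class TestComparisonSchemes:
    def test_within_five_plots_is_ten_pairs(self):
        plot_ids, meta = one_location_design()
        m = make_matrix(np.ones((15, 4), dtype=int), plots=plot_ids)
        pairs = within_habitat_pairs(m, meta, "L", "OG")
        assert len(pairs) == 10
        assert all(p.beta == 0.0 for p in pairs)
        # each plot takes part in exactly 4 comparisons
        counts = {}
        for p in pairs:
            counts[p.plot_a] = counts.get(p.plot_a, 0) + 1
            counts[p.plot_b] = counts.get(p.plot_b, 0) + 1
        assert set(counts.values()) == {4}

    def test_within_two_plots_is_one_pair(self):
        m = make_matrix([[1, 0], [1, 1]])
        meta = make_meta(m.plot_ids, ["L", "L"], ["OG", "OG"])
        assert len(within_habitat_pairs(m, meta, "L", "OG")) == 1

    def test_within_single_plot_rejected(self):
        m = make_matrix([[1, 0]])
        meta = make_meta(m.plot_ids, ["L"], ["OG"])
        with pytest.raises(ValueError, match=">=2 plots"):
            within_habitat_pairs(m, meta, "L", "OG")

    def test_between_is_full_cross_product(self):
        plot_ids, meta = one_location_design()
        m = make_matrix(np.ones((15, 4), dtype=int), plots=plot_ids)
        pairs = between_habitat_pairs(m, meta, "L", "OG", "SE")
        assert len(pairs) == 25
        assert all(p.beta == 0.0 for p in pairs)

    def test_between_disjoint_habitats_all_one(self):
        plot_ids, meta = one_location_design(n_per_habitat=2)
        X = np.zeros((6, 4), dtype=int)
        X[:2, :2] = 1  # OG species
        X[2:4, 2:] = 1  # DE species
        X[4:, 2:] = 1
        m = make_matrix(X, plots=plot_ids)
        pairs = between_habitat_pairs(m, meta, "L", "OG", "DE")
        assert all(p.beta == 1.0 for p in pairs)

    def test_same_habitat_twice_rejected(self):
        plot_ids, meta = one_location_design()
        m = make_matrix(np.ones((15, 2), dtype=int), plots=plot_ids)
        with pytest.raises(ValueError, match="distinct"):
            between_habitat_pairs(m, meta, "L", "OG", "OG")

    def test_pair_counts_per_location_default_design(self, default_landscape):
        m, meta = default_landscape.matrix, default_landscape.meta
        within = sum(
            len(within_habitat_pairs(m, meta, "L2500", h)) for h in ("OG", "DE", "SE")
        )
        between = sum(
            len(between_habitat_pairs(m, meta, "L2500", a, b))
            for a, b in (("OG", "DE"), ("OG", "SE"), ("DE", "SE"))
        )
        assert within == 30 and between == 75

    def test_transition_code_canonical(self):
        assert transition_code("SE", "OG") == "OG-SE"
        assert transition_code("OG", "SE") == "OG-SE"
        assert transition_code("DE", "DE") == "DE-DE"


class TestBootstrap:
    def _blocks(self, matrix, meta, transition):
        return _transition_blocks(matrix, meta, transition)[0]

    def test_no_variance_gives_zero_se(self):
        plot_ids, meta = one_location_design()
        m = make_matrix(np.ones((15, 6), dtype=int), plots=plot_ids)
        blocks = self._blocks(m, meta, "OG-OG")
        assert bootstrap_se(blocks, reps=100, seed=1) == 0.0

    def test_same_seed_reproduces_se(self):
        ls = generate_landscape(LandscapeConfig(seed=5, pool_size=60, mat=None, map=None))
        blocks = self._blocks(ls.matrix, ls.meta, "OG-SE")
        a = bootstrap_se(blocks, reps=200, seed=9)
        b = bootstrap_se(blocks, reps=200, seed=9)
        assert a == b and a > 0

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError, match="reps"):
            bootstrap_se([], reps=1, seed=0)

    def test_bootstrap_converges_with_reps(self):
        """SE estimate stabilizes: 4000-rep value within 10% of 1000-rep."""
        ls = generate_landscape(LandscapeConfig(seed=5, pool_size=60, mat=None, map=None))
        blocks = self._blocks(ls.matrix, ls.meta, "DE-DE")
        se1 = bootstrap_se(blocks, reps=1000, seed=3)
        se2 = bootstrap_se(blocks, reps=4000, seed=4)
        assert abs(se1 - se2) / se2 < 0.10

    def test_value_resampling_scheme_also_works(self):
        ls = generate_landscape(LandscapeConfig(seed=5, pool_size=60, mat=None, map=None))
        blocks = self._blocks(ls.matrix, ls.meta, "OG-DE")
        se = bootstrap_se(blocks, reps=500, seed=2, resample="values")
        assert se > 0


class TestTransitionMeans:
    def test_identical_landscape_all_zero(self):
        plot_ids, meta = one_location_design()
        m = make_matrix(np.ones((15, 5), dtype=int), plots=plot_ids)
        tm = transition_means(m, meta, reps=20, seed=0)
        assert list(tm["transition"]) == list(TRANSITIONS)
        assert np.allclose(tm["mean_beta"], 0.0)
        assert np.allclose(tm["se"], 0.0)
        assert list(tm["n_pairs"]) == [10, 10, 10, 25, 25, 25]

    def test_habitat_contrast_separates_between_from_within(self):
        aff = np.full((3, 3), 0.2) + np.eye(3) * 0.8
        ls = generate_landscape(
            LandscapeConfig(seed=6, pool_size=120, habitat_affinity=aff, mat=None, map=None)
        )
        tm = transition_means(ls.matrix, ls.meta, exclude_locations=["L50"],
                              reps=50, seed=1).set_index("transition")
        within = tm.loc[["OG-OG", "DE-DE", "SE-SE"], "mean_beta"]
        between = tm.loc[["OG-DE", "OG-SE", "DE-SE"], "mean_beta"]
        assert between.min() > within.max()

    def test_excluded_location_absent_from_pooling(self, default_landscape):
        m, meta = default_landscape.matrix, default_landscape.meta
        tm = transition_means(m, meta, exclude_locations=["L50"], reps=10, seed=0)
        assert all("L50" not in used.split(",") for used in tm["locations_used"])
        n_loc = meta["location"].nunique() - 1
        assert list(tm["n_pairs"]) <= [10 * n_loc] * 3 + [25 * n_loc] * 3
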