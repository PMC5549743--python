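import numpy as np
import pytest

from divgrad.hill_profiles import (
    DEFAULT_Q_GRID,
    IncidenceFrequencies,
    asymptotic_hill,
    asymptotic_hill_profile,
    chao2_richness,
    empirical_hill,
    incidence_frequencies,
)

from conftest import make_matrix, make_meta


def random_freq(rng, t_max=15, s_max=40):
    T = int(rng.integers(2, t_max + 1))
    S = int(rng.integers(1, s_max))
    Y = rng.integers(1, T + 1, size=S)
    return IncidenceFrequencies(T=T, Y=Y)


class TestFrequencies:
    def test_counts_from_matrix(self):
        m = make_matrix([[1, 1, 0], [1, 0, 0], [1, 0, 1]])
        meta = make_meta(m.plot_ids, ["L"] * 3, ["OG"] * 3)
        f = incidence_frequencies(m, meta, "location")["L"]
        assert f.T == 3 and f.s_obs == 3
        assert sorted(f.Y.tolist()) == [1, 1, 3]
        assert f.Q[3] == 1 and f.Q1 == 2

    def test_bookkeeping_identity(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            f = random_freq(rng)
            Q = f.Q
            assert sum(k * Q[k] for k in range(len(Q))) == f.U
            assert Q.sum() == f.s_obs

    def test_default_design_location_has_T_15(self, default_landscape):
        freqs = incidence_frequencies(
            default_landscape.matrix, default_landscape.meta, "location"
        )
        assert all(f.T == 15 for f in freqs.values())

    def test_habitat_grouping_has_T_5(self, default_landscape):
        freqs = incidence_frequencies(
            default_landscape.matrix, default_landscape.meta, "habitat"
        )
        assert len(freqs) == 24 and all(f.T == 5 for f in freqs.values())


class TestEmpirical:
    def test_equal_incidences_give_richness_at_all_orders(self):
        f = IncidenceFrequencies(T=5, Y=np.full(7, 3))
        for q in DEFAULT_Q_GRID:
            assert empirical_hill(f, q) == pytest.approx(7.0)

    def test_order_zero_is_observed_richness(self):
        f = IncidenceFrequencies(T=5, Y=np.array([5, 1, 2, 4]))
        assert empirical_hill(f, 0) == pytest.approx(4.0)

    def test_hand_computed_simpson(self):
        # Y = (4, 1): 2D = 1 / ((4/5)^2 + (1/5)^2) = 25/17
        f = IncidenceFrequencies(T=5, Y=np.array([4, 1]))
        assert empirical_hill(f, 2) == pytest.approx(25 / 17)

    def test_negative_order_rejected(self):
        f = IncidenceFrequencies(T=2, Y=np.array([1]))
        with pytest.raises(ValueError, match="q"):
            empirical_hill(f, -0.5)

    def test_profile_non_increasing_in_q(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            f = random_freq(rng)
            prof = [empirical_hill(f, q) for q in DEFAULT_Q_GRID]
            assert all(a >= b - 1e-9 for a, b in zip(prof, prof[1:]))


class TestAsymptotic:
    def test_no_singletons_no_correction(self):
        f = IncidenceFrequencies(T=4, Y=np.array([2, 3, 4, 2]))
        assert asymptotic_hill(f, 0) == pytest.approx(f.s_obs)

    def test_hand_computed_chao2(self):
        # T=5, S_obs=10, Q1=4, Q2=2 -> 10 + (4/5) * (4*3) / (2*3) = 11.6
        Y = np.array([1, 1, 1, 1, 2, 2, 3, 3, 4, 5])
        f = IncidenceFrequencies(T=5, Y=Y)
        assert chao2_richness(f) == pytest.approx(11.6)
        assert asymptotic_hill(f, 0) == pytest.approx(11.6)

    def test_order_two_matches_classic_unbiased_estimator(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            f = random_freq(rng)
            classic = (f.U / f.T) ** 2 / np.sum(
                f.Y * (f.Y - 1) / (f.T * (f.T - 1))
            ) if np.sum(f.Y * (f.Y - 1)) > 0 else None
            if classic is None:
                continue
            assert asymptotic_hill(f, 2) == pytest.approx(classic, rel=1e-9)

    def test_continuity_at_order_one(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            f = random_freq(rng)
            at1 = asymptotic_hill(f, 1.0)
            below = asymptotic_hill(f, 1.0 - 1e-6)
            above = asymptotic_hill(f, 1.0 + 1e-6)
            assert at1 == pytest.approx(below, rel=1e-4)
            assert at1 == pytest.approx(above, rel=1e-4)
        # and the empirical limit too
        f = IncidenceFrequencies(T=6, Y=np.array([1, 2, 3, 6]))
        assert empirical_hill(f, 1.0) == pytest.approx(
            empirical_hill(f, 1.0 - 1e-9), rel=1e-6
        )

    def test_richness_estimate_never_below_observed(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            f = random_freq(rng)
            assert asymptotic_hill(f, 0) >= f.s_obs - 1e-9

    def test_invariant_to_relabeling_and_plot_order(self):
        m = make_matrix([[1, 0, 1], [1, 1, 0], [0, 1, 1], [1, 0, 0]])
        meta = make_meta(m.plot_ids, ["L"] * 4, ["OG"] * 4)
        f1 = incidence_frequencies(m, meta, "location")["L"]
        shuffled = m.subset(["p2", "p0", "p3", "p1"])
        relabeled = make_matrix(
            shuffled.data.to_numpy()[:, ::-1], plots=shuffled.plot_ids
        )
        f2 = incidence_frequencies(relabeled, meta, "location")["L"]
        for q in DEFAULT_Q_GRID:
            assert asymptotic_hill(f1, q) == pytest.approx(asymptotic_hill(f2, q))

    def test_profile_frame_layout(self, default_landscape):
        freqs = incidence_frequencies(
            default_landscape.matrix, default_landscape.meta, "location"
        )
        prof = asymptotic_hill_profile(freqs["L2500"], group="L2500")
        df = prof.to_frame()
        assert list(df.columns) == ["group", "q", "empirical", "asymptotic"]
        assert len(df) == 13
        assert df["empirical"].iloc[0] == pytest.approx(freqs["L2500"].s_obs)
        assert df["asymptotic"].iloc[0] >= df["empirical"].iloc[0]

    def test_single_unit_falls_back_to_empirical_with_warning(self):
        f = IncidenceFrequencies(T=1, Y=np.array([1, 1]))
        with pytest.warns(UserWarning, match="T < 2"):
            prof = asymptotic_hill_profile(f)
        assert np.allclose(prof.asymptotic, prof.empirical)


def test_chao2_recovers_truth_better_than_observed_richness():
    """Simulation oracle with known pool: under undersampling the corrected
    richness estimate should land nearer the true pool size than S_obs in
    >=90% of replicates."""
    rng = np.random.default_rng(99)
    pool = 60
    wins = 0
    n_rep = 100
    for _ in range(n_rep):
        # heterogeneous detection probabilities induce unseen species
        theta = rng.beta(0.6, 3.0, size=pool)
        T = 8
        X = rng.random((T, pool)) < theta
        Y = X.sum(axis=0)
        f = IncidenceFrequencies(T=T, Y=Y)
        if f.s_obs == 0:
            continue
        est = chao2_richness(f)
        if abs(est - pool) < abs(f.s_obs - pool):
            wins += 1
    assert wins >= 0.9 * n_rep
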