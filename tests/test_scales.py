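"""Windowed spectral correlations, MI estimation, nulls and hierarchy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adaptscales.scales import (
    MIProfile,
    PairSample,
    WindowSpec,
    make_windows,
    mi_from_joint,
    mi_profile,
    mutual_information,
    null_profile,
    rank_hierarchy,
    sample_pairs,
    spectral_depth,
    window_correlations,
)
from adaptscales.spectral import SpectralDecomposition


def mi_bruteforce(joint):
    """Independent plug-in MI oracle: explicit double sum over table cells."""
    joint = np.asarray(joint, dtype=float)
    n = joint.sum()
    mi = 0.0
    for b in range(joint.shape[0]):
        for c in range(joint.shape[1]):
            p = joint[b, c] / n
            if p > 0:
                pb = joint[b, :].sum() / n
                pc = joint[:, c].sum() / n
                mi += p * np.log2(p / (pb * pc))
    return mi


def make_decomposition(U, s):
    U = np.asarray(U, dtype=float)
    s = np.asarray(s, dtype=float)
    n, K = U.shape
    return SpectralDecomposition(
        U=U, s=s, V=np.eye(10)[:, :K] if K <= 10 else np.eye(K),
        total_variance=float(np.sum(s**2)), centered=False,
        cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
        gene_ids=np.array([f"g{j}" for j in range(10)], dtype=object),
    )


class TestMakeWindows:
    def test_default_coverage_of_thirty_components(self):
        ws = make_windows(30)
        assert len(ws) == 28
        assert (ws[0].start, ws[0].stop) == (1, 3)
        assert (ws[-1].start, ws[-1].stop) == (28, 30)

    def test_minimal_k_single_window(self):
        assert len(make_windows(3)) == 1

    def test_nonoverlapping_stride(self):
        ws = make_windows(9, width=3, stride=3, max_pc=9)
        assert [(w.start, w.stop) for w in ws] == [(1, 3), (4, 6), (7, 9)]

    def test_width_exceeding_k_raises(self):
        with pytest.raises(ValueError):
            make_windows(2, width=3)


class TestPairSample:
    def test_exhaustive_when_budget_allows(self):
        p = sample_pairs(10, budget=100)
        assert p.exhaustive and p.n_pairs == 45
        assert np.all(p.i < p.j)

    def test_sampled_pairs_distinct_and_within_budget(self):
        p = sample_pairs(300, budget=1000, seed=4)
        assert not p.exhaustive and p.n_pairs == 1000
        keys = p.i * 300 + p.j
        assert len(np.unique(keys)) == 1000
        assert np.all((p.i >= 0) & (p.j < 300) & (p.i < p.j))

    def test_deterministic_given_seed(self):
        a = sample_pairs(500, budget=400, seed=9)
        b = sample_pairs(500, budget=400, seed=9)
        assert np.array_equal(a.i, b.i) and np.array_equal(a.j, b.j)


class TestWindowCorrelations:
    # hand-written 3-component scores for 4 cells; all 6 pair inner
    # products verified by hand
    P = np.array([[1.0, 0.0, 2.0],
                  [1.0, 0.0, 2.0],
                  [0.0, 1.0, 0.0],
                  [-1.0, 0.0, -2.0]])
    HAND_RAW = {(0, 1): 5.0, (0, 2): 0.0, (0, 3): -5.0,
                (1, 2): 0.0, (1, 3): -5.0, (2, 3): 0.0}

    def _decomp(self):
        return make_decomposition(self.P, np.ones(3))

    def _pairs(self):
        i, j = np.triu_indices(4, k=1)
        return PairSample(i, j, 4, 100, 0, True)

    def test_hand_fixture_raw_inner_products(self):
        c = window_correlations(self._decomp(), WindowSpec(1, 3), self._pairs())
        for k, (i, j) in enumerate(zip(c.values, zip(*np.triu_indices(4, 1)))):
            pass
        got = dict(zip(zip(*map(list, np.triu_indices(4, 1))), c.values))
        for (i, j), v in self.HAND_RAW.items():
            assert got[(i, j)] == pytest.approx(v, abs=1e-12)

    def test_identical_cells_cosine_one_raw_norm_squared(self):
        c_raw = window_correlations(self._decomp(), WindowSpec(1, 3),
                                    self._pairs(), normalization="raw")
        c_cos = window_correlations(self._decomp(), WindowSpec(1, 3),
                                    self._pairs(), normalization="cosine")
        assert c_raw.values[0] == pytest.approx(5.0)   # ||v||^2
        assert c_cos.values[0] == pytest.approx(1.0)
        assert c_cos.values[2] == pytest.approx(-1.0)  # antiparallel pair
        assert np.all(np.abs(c_cos.values) <= 1 + 1e-12)

    def test_zero_norm_projection_cosine_flagged(self):
        P = np.vstack([self.P, np.zeros(3)])
        d = make_decomposition(P, np.ones(3))
        i, j = np.triu_indices(5, k=1)
        pairs = PairSample(i, j, 5, 100, 0, True)
        c = window_correlations(d, WindowSpec(1, 3), pairs,
                                normalization="cosine")
        assert c.n_degenerate == 4
        got = dict(zip(zip(i.tolist(), j.tolist()), c.values))
        assert got[(0, 4)] == 0.0

    def test_singular_value_weighting(self):
        d = make_decomposition(self.P, np.array([2.0, 1.0, 1.0]))
        c = window_correlations(d, WindowSpec(1, 3), self._pairs(),
                                weighting="scores")
        # pair (0,1): 2^2*1 + 1*0 + 1*4 = 8
        assert c.values[0] == pytest.approx(8.0)
        u = window_correlations(d, WindowSpec(1, 3), self._pairs(),
                                weighting="unit")
        assert u.values[0] == pytest.approx(5.0)


class TestMutualInformation:
    def test_perfectly_predictive_balanced_bins_one_bit(self):
        values = np.concatenate([np.zeros(64), np.ones(64)])
        labels = np.concatenate([np.zeros(64), np.ones(64)])
        assert mutual_information(values, labels, n_bins=2) == 1.0

    def test_identical_class_conditional_histograms_zero(self):
        values = np.tile([0.0, 1.0, 2.0, 3.0], 24)
        labels = np.repeat([0, 1], 48)
        assert mutual_information(values, labels, n_bins=4) == 0.0

    def test_worked_joint_table_matches_bruteforce(self):
        joint = np.array([[30, 10], [10, 50]])
        assert mi_from_joint(joint) == pytest.approx(
            mi_bruteforce(joint), abs=1e-12
        )

    def test_single_class_and_constant_values_are_zero(self):
        assert mutual_information(np.arange(10.0), np.zeros(10)) == 0.0
        assert mutual_information(np.zeros(10), np.repeat([0, 1], 5)) == 0.0

    def test_more_than_two_classes_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(np.arange(6.0), np.array([0, 1, 2, 0, 1, 2]))

    @given(
        st.lists(
            st.tuples(st.integers(0, 60), st.integers(0, 60)),
            min_size=1, max_size=16,
        ).filter(lambda rows: sum(a + b for a, b in rows) >= 2)
    )
    @settings(max_examples=200, deadline=None)
    def test_plugin_equals_bruteforce_on_any_table(self, rows):
        joint = np.array(rows, dtype=float)
        assert mi_from_joint(joint) == pytest.approx(
            mi_bruteforce(joint), abs=1e-12
        )

    @given(
        st.lists(
            st.tuples(st.integers(0, 40), st.integers(0, 40)),
            min_size=2, max_size=16,
        ).filter(lambda rows: sum(a + b for a, b in rows) >= 2),
        st.integers(0, 14),
    )
    @settings(max_examples=150, deadline=None)
    def test_merging_adjacent_bins_never_increases_mi(self, rows, at):
        joint = np.array(rows, dtype=float)
        at = min(at, joint.shape[0] - 2)
        merged = np.vstack(
            [joint[:at], joint[at] + joint[at + 1], joint[at + 2:]]
        )
        assert mi_from_joint(merged) <= mi_from_joint(joint) + 1e-12

    def test_bounded_by_label_entropy(self, rng):
        for _ in range(30):
            v = rng.normal(size=200)
            y = rng.integers(0, 2, size=200)
            p1 = y.mean()
            h = -sum(p * np.log2(p) for p in (p1, 1 - p1) if p > 0)
            mi = mutual_information(v, y)
            assert 0.0 <= mi <= h + 1e-12


class TestMIProfile:
    def _planted_shallow(self, rng, n=120):
        labels = np.repeat(["a", "b"], n // 2)
        U = rng.normal(size=(n, 9)) * 0.05
        U[:, 0] += np.where(labels == "a", 1.0, -1.0)
        d = make_decomposition(U, np.linspace(3, 1, 9))
        meta = pd.DataFrame(
            {"sample_id": labels, "cue": labels}, index=d.cell_ids
        )
        return d, meta

    def test_signal_in_leading_window_peaks_first(self, rng):
        d, meta = self._planted_shallow(rng)
        p = mi_profile(d, meta, "cue", windows=make_windows(9, max_pc=9))
        assert int(np.argmax(p.mi)) == 0
        assert p.cumulative_normalized[0] >= 0.5

    def test_cumulative_monotone_and_normalized_ends_at_one(self, rng):
        d, meta = self._planted_shallow(rng)
        p = mi_profile(d, meta, "cue", windows=make_windows(9, max_pc=9))
        assert np.all(np.diff(p.cumulative) >= -1e-15)
        assert p.cumulative_normalized[-1] == pytest.approx(1.0)

    def test_shuffled_labels_stay_within_null_envelope(self, rng):
        d, meta = self._planted_shallow(rng)
        meta = meta.copy()
        meta["cue"] = rng.permutation(meta["cue"].to_numpy())
        meta["sample_id"] = meta["cue"]  # blocks follow the shuffled label
        windows = make_windows(9, max_pc=9)
        pairs = sample_pairs(len(meta), 10_000, seed=0)
        p = mi_profile(d, meta, "cue", windows=windows, pairs=pairs)
        n = null_profile(d, meta, "cue", windows=windows, pairs=pairs,
                         mode="per_cell", n_perm=100, seed=1)
        assert np.mean(p.mi <= n.null_max) >= 0.95

    def test_single_level_variable_rejected(self, rng):
        d, meta = self._planted_shallow(rng)
        meta = meta.copy()
        meta["cue"] = "a"
        with pytest.raises(ValueError, match="levels"):
            mi_profile(d, meta, "cue")

    def test_tiny_pair_budget_rejected(self, rng):
        d, meta = self._planted_shallow(rng)
        with pytest.raises(ValueError, match="budget"):
            mi_profile(d, meta, "cue", pair_budget=10)

    def test_cell_order_permutation_leaves_mi_unchanged(self, rng):
        d, meta = self._planted_shallow(rng)
        windows = make_windows(9, max_pc=9)
        i, j = np.triu_indices(len(meta), k=1)
        pairs = PairSample(i, j, len(meta), 10**6, 0, True)
        p0 = mi_profile(d, meta, "cue", windows=windows, pairs=pairs)

        perm = rng.permutation(len(meta))
        inv = np.argsort(perm)
        d2 = make_decomposition(d.U[perm], d.s)
        meta2 = meta.iloc[perm].copy()
        meta2.index = d2.cell_ids
        ni, nj = inv[i], inv[j]
        lo, hi = np.minimum(ni, nj), np.maximum(ni, nj)
        pairs2 = PairSample(lo, hi, len(meta), 10**6, 0, True)
        p1 = mi_profile(d2, meta2, "cue", windows=windows, pairs=pairs2)
        assert np.array_equal(p0.mi, p1.mi)


class TestNullProfile:
    def test_identity_permutation_reproduces_true_mi(self, rng):
        labels = np.repeat(["a", "b"], 30)
        U = rng.normal(size=(60, 6))
        U[:, 0] += np.where(labels == "a", 1.0, -1.0)
        d = make_decomposition(U, np.ones(6))
        meta = pd.DataFrame({"sample_id": labels, "cue": labels},
                            index=d.cell_ids)
        windows = make_windows(6, max_pc=6)
        pairs = sample_pairs(60, 10_000)
        p = mi_profile(d, meta, "cue", windows=windows, pairs=pairs)
        n = null_profile(
            d, meta, "cue", windows=windows, pairs=pairs, mode="per_cell",
            permutations=np.arange(60)[None, :],
        )
        assert np.allclose(n.null_mi[0], p.mi, atol=1e-12)

    def test_per_condition_requires_constant_label_within_sample(self, rng):
        U = rng.normal(size=(20, 6))
        d = make_decomposition(U, np.ones(6))
        meta = pd.DataFrame({
            "sample_id": ["s0"] * 10 + ["s1"] * 10,
            "cue": ["a", "b"] * 10,
        }, index=d.cell_ids)
        with pytest.raises(ValueError, match="varies within sample"):
            null_profile(d, meta, "cue", windows=make_windows(6, max_pc=6),
                         pairs=sample_pairs(20, 1000), n_perm=2)

    def test_one_sample_per_level_warns_trivial_support(self, rng):
        U = rng.normal(size=(20, 6))
        d = make_decomposition(U, np.ones(6))
        meta = pd.DataFrame({
            "sample_id": ["s0"] * 10 + ["s1"] * 10,
            "cue": ["a"] * 10 + ["b"] * 10,
        }, index=d.cell_ids)
        with pytest.warns(UserWarning, match="trivial"):
            null_profile(d, meta, "cue", windows=make_windows(6, max_pc=6),
                         pairs=sample_pairs(20, 1000), n_perm=3)


class TestDepthAndHierarchy:
    def _profile(self, mi, name="v"):
        return MIProfile(name, make_windows(len(mi) + 2,
                                            max_pc=len(mi) + 2), np.array(mi))

    def test_all_mass_in_first_window(self):
        assert spectral_depth(self._profile([1.0, 0, 0, 0])) == 1

    def test_uniform_profile_half_rise_at_middle(self):
        p = self._profile([1.0] * 28)
        assert spectral_depth(p) == 14

    def test_two_scale_profile(self):
        mi = np.zeros(10)
        mi[4] = 0.7
        mi[9] = 0.3
        assert spectral_depth(self._profile(mi)) == 5

    def test_zero_profile_undefined(self):
        assert spectral_depth(self._profile([0.0] * 5)) is None

    def test_ranking_orders_by_depth(self):
        shallow = self._profile([1.0, 0, 0, 0], "a")
        deep = self._profile([0, 0, 0, 1.0], "b")
        r = rank_hierarchy([deep, shallow])
        assert r.ordering == ["a", "b"]
        assert r.depths == {"a": 1, "b": 4}

    def test_identical_profiles_tie_broken_by_name_and_reported(self):
        p1 = self._profile([0.5, 0.5, 0, 0], "zeta")
        p2 = self._profile([0.5, 0.5, 0, 0], "alpha")
        r = rank_hierarchy([p1, p2])
        assert r.ordering == ["alpha", "zeta"]
        assert ["alpha", "zeta"] in r.ties

    def test_undefined_depth_placed_last_and_flagged(self):
        good = self._profile([1.0, 0, 0, 0], "a")
        dead = self._profile([0.0] * 4, "b")
        r = rank_hierarchy([dead, good])
        assert r.ordering == ["a", "b"]
        assert r.undefined == ["b"]
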