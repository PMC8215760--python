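"""Diversity, Bray-Curtis and permutation tests, with enumeration oracles
and scikit-bio as an independent cross-check of the statistics."""

from itertools import permutations as iperm

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from plastisphere import ecology as eco
from tests.conftest import make_count_matrix


class TestFilterLowDepth:
    def test_strictly_below_threshold_removed(self):
        cm = make_count_matrix(np.array([[900, 1000, 5000]]))
        kept = eco.filter_low_depth(cm, 1000)
        assert list(kept.samples) == ["s1", "s2"]

    def test_zero_threshold_is_identity(self, toy_counts):
        kept = eco.filter_low_depth(toy_counts, 0)
        pd.testing.assert_frame_equal(kept.counts, toy_counts.counts)

    def test_error_when_everything_removed(self):
        cm = make_count_matrix(np.full((1, 3), 333))
        with pytest.raises(ValueError, match="1000"):
            eco.filter_low_depth(cm, 1000)


class TestDiversity:
    @pytest.mark.parametrize("column, simpson, richness", [
        ([1.0, 0.0, 0.0], 0.0, 1),
        ([0.5, 0.5, 0.0], 0.5, 2),
        ([0.5, 0.25, 0.25], 0.625, 3),  # 1 - (0.25 + 0.0625 + 0.0625)
    ])
    def test_simpson_and_richness(self, column, simpson, richness):
        rel = pd.DataFrame({"s": column})
        out = eco.diversity_metrics(rel)
        assert out.loc["s", "simpson"] == pytest.approx(simpson)
        assert out.loc["s", "richness"] == richness

    def test_unnormalised_column_rejected(self):
        with pytest.raises(ValueError, match="normalised"):
            eco.diversity_metrics(pd.DataFrame({"s": [0.5, 0.1]}))


class TestBrayCurtis:
    def test_identical_columns_have_zero_distance(self):
        rel = pd.DataFrame({"a": [0.3, 0.7], "b": [0.3, 0.7]})
        assert eco.bray_curtis(rel)["a", "b"] == 0.0

    def test_disjoint_supports_have_distance_one(self):
        rel = pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 1.0]})
        assert eco.bray_curtis(rel)["a", "b"] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        rel = pd.DataFrame({"a": [0.2, 0.8], "b": [0.6, 0.4]})
        # (|0.2-0.6| + |0.8-0.4|) / (0.2+0.6+0.8+0.4) = 0.8 / 2 = 0.4
        assert eco.bray_curtis(rel)["a", "b"] == pytest.approx(0.4)

    def test_two_all_zero_samples_rejected(self):
        rel = pd.DataFrame({"a": [0.0, 0.0], "b": [0.0, 0.0], "c": [0.5, 0.5]})
        with pytest.raises(ValueError, match="all-zero"):
            eco.bray_curtis(rel)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_bounded_and_invariant_to_taxon_order(self, seed):
        rng = np.random.default_rng(seed)
        rel = pd.DataFrame(rng.dirichlet(np.ones(6), size=4).T,
                           index=list("abcdef"),
                           columns=[f"s{i}" for i in range(4)])
        dm = eco.bray_curtis(rel)
        assert (np.asarray(dm.data) >= 0).all() and (np.asarray(dm.data) <= 1).all()
        shuffled = rel.sample(frac=1, random_state=0)
        dm2 = eco.bray_curtis(shuffled)
        np.testing.assert_allclose(dm.data, dm2.data, atol=1e-12)


def _separated_distance_matrix():
    """Two groups of 3 with every within distance < every between distance."""
    rng = np.random.default_rng(0)
    points = np.vstack([rng.normal(0, 0.05, (3, 2)),
                        rng.normal(10, 0.05, (3, 2))])
    d = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
    return d, np.array(["x", "x", "x", "y", "y", "y"])


def _brute_force_anosim(d, codes):
    """Independent enumeration: R for every distinct relabelling."""
    n = len(codes)
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])
    m = n * (n - 1) / 2

    def r_stat(labels):
        labels = np.asarray(labels)
        same = labels[iu[0]] == labels[iu[1]]
        return (ranks[~same].mean() - ranks[same].mean()) / (m / 2)

    observed = r_stat(codes)
    all_r = [r_stat(p) for p in sorted(set(iperm(codes.tolist())))]
    p_exact = sum(1 for r in all_r if r >= observed) / len(all_r)
    return observed, p_exact


class TestAnosim:
    def test_complete_separation_gives_r_one(self):
        d, codes = _separated_distance_matrix()
        result = eco.anosim(d, codes, n_permutations=99, seed=0)
        assert result.statistic == pytest.approx(1.0)

    def test_anti_separation_gives_negative_r(self):
        # construct distances with every between < every within
        rng = np.random.default_rng(7)
        codes = np.array(["x", "x", "x", "y", "y", "y"])
        d = np.zeros((6, 6))
        for i in range(6):
            for j in range(i + 1, 6):
                base = 1.0 if codes[i] != codes[j] else 10.0
                d[i, j] = d[j, i] = base + rng.uniform(0, 0.01)
        result = eco.anosim(d, codes, n_permutations=99, seed=0)
        assert result.statistic < 0

    def test_exhaustive_p_matches_enumeration_oracle(self):
        d, codes = _separated_distance_matrix()
        observed, p_exact = _brute_force_anosim(d, codes)
        result = eco.anosim(d, codes, exhaustive=True)
        assert result.statistic == pytest.approx(observed, abs=1e-12)
        assert result.p_value == pytest.approx(p_exact, abs=1e-12)
        assert p_exact == pytest.approx(2 / 20)  # both group-label swaps

    def test_rank_based_r_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        points = rng.normal(0, 1, (8, 2))
        d = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
        codes = np.array(["a"] * 4 + ["b"] * 4)
        r1 = eco.anosim(d, codes, n_permutations=9, seed=1).statistic
        r2 = eco.anosim(d**2, codes, n_permutations=9, seed=1).statistic
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_statistic_agrees_with_skbio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(4)
        points = rng.normal(0, 1, (9, 3))
        d = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
        codes = ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
        ours = eco.anosim(d, np.array(codes), n_permutations=9, seed=0)
        dm = skbio_distance.DistanceMatrix(d, ids=[str(i) for i in range(9)])
        theirs = skbio_distance.anosim(dm, list(codes), permutations=9)
        assert ours.statistic == pytest.approx(theirs["test statistic"],
                                               abs=1e-12)

    def test_single_sample_group_rejected(self):
        d, _ = _separated_distance_matrix()
        with pytest.raises(ValueError, match="single sample"):
            eco.anosim(d, np.array(["x"] * 5 + ["y"]), n_permutations=9)

    def test_p_value_floor_with_add_one_correction(self):
        d, codes = _separated_distance_matrix()
        result = eco.anosim(d, codes, n_permutations=99, seed=2)
        assert result.p_value >= 1 / 100


class TestPermanova:
    def test_hand_computed_pseudo_f(self):
        d, codes = _separated_distance_matrix()
        sq = d**2
        n, a = 6, 2
        ss_total = sq[np.triu_indices(6, 1)].sum() / n
        ss_within = (sq[:3, :3][np.triu_indices(3, 1)].sum() / 3
                     + sq[3:, 3:][np.triu_indices(3, 1)].sum() / 3)
        f_expected = ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))
        result = eco.permanova(d, codes, n_permutations=9, seed=0)
        assert result.statistic == pytest.approx(f_expected, rel=1e-12)

    def test_statistic_agrees_with_skbio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        d, codes = _separated_distance_matrix()
        ours = eco.permanova(d, codes, n_permutations=9, seed=0)
        dm = skbio_distance.DistanceMatrix(d, ids=list("pqrstu"))
        theirs = skbio_distance.permanova(dm, list(codes), permutations=9)
        assert ours.statistic == pytest.approx(theirs["test statistic"],
                                               rel=1e-9)

    def test_label_swap_leaves_f_unchanged(self):
        d, codes = _separated_distance_matrix()
        swapped = np.where(codes == "x", "y", "x")
        f1 = eco.permanova(d, codes, n_permutations=9, seed=0).statistic
        f2 = eco.permanova(d, swapped, n_permutations=9, seed=0).statistic
        assert f1 == pytest.approx(f2)

    def test_degenerate_zero_within_variance_rejected(self):
        d = np.zeros((4, 4))
        with pytest.raises(ValueError, match="degenerate"):
            eco.permanova(d, np.array(["a", "a", "b", "b"]), n_permutations=9)
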