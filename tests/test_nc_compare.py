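import itertools
import math

import numpy as np
import pandas as pd
import pytest

from microgliamorph import PHENOTYPES
from microgliamorph import nc_compare as nc
from microgliamorph.morphometry import NC_PARAM_NAMES

from conftest import rank_then_pearson


def toy_table(values_by_param, labels=None):
    frame = pd.DataFrame(values_by_param)
    if labels is not None:
        frame["label"] = labels
    return frame


class TestComputeCentroids:
    def test_single_cell_per_class(self):
        frame = toy_table({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0, 6.0, 7.0, 8.0]},
                          labels=list(PHENOTYPES))
        cents = nc.compute_centroids(frame, subset=("a", "b"))
        assert cents.centroids["amoeboid"].tolist() == [1.0, 5.0]
        assert cents.centroids["ramified"].tolist() == [4.0, 8.0]

    def test_odd_count_median(self):
        frame = toy_table({"a": [1.0, 2.0, 10.0] + [0.0] * 3},
                          labels=["amoeboid"] * 3 + ["activated", "rod_like", "ramified"])
        cents = nc.compute_centroids(frame, subset=("a",))
        assert cents.centroids["amoeboid"][0] == 2.0

    def test_even_count_midpoint(self):
        frame = toy_table({"a": [1.0, 2.0, 3.0, 4.0] + [0.0] * 3},
                          labels=["amoeboid"] * 4 + ["activated", "rod_like", "ramified"])
        cents = nc.compute_centroids(frame, subset=("a",))
        assert cents.centroids["amoeboid"][0] == 2.5

    def test_missing_class_raises(self):
        frame = toy_table({"a": [1.0, 2.0]}, labels=["amoeboid", "activated"])
        with pytest.raises(ValueError):
            nc.compute_centroids(frame, subset=("a",))

    def test_missing_column_raises(self):
        frame = toy_table({"a": [1.0] * 4}, labels=list(PHENOTYPES))
        with pytest.raises(KeyError):
            nc.compute_centroids(frame, subset=("a", "nope"))


def corner_centroids():
    frame = toy_table(
        {"x": [0.0, 10.0, 0.0, 10.0], "y": [0.0, 0.0, 10.0, 10.0]},
        labels=list(PHENOTYPES),
    )
    return nc.compute_centroids(frame, subset=("x", "y"))


class TestNcClassify:
    def test_cell_at_centroid(self):
        cents = corner_centroids()
        out = nc.nc_classify(toy_table({"x": [10.0], "y": [0.0]}), cents)
        assert out == ["activated"]

    def test_brute_force_distance_agreement(self):
        cents = corner_centroids()
        point = {"x": [1.0], "y": [1.0]}
        out = nc.nc_classify(toy_table(point), cents)
        dists = {
            cls: math.dist((1.0, 1.0), tuple(cents.centroids[cls])) for cls in PHENOTYPES
        }
        assert out[0] == min(dists, key=dists.get) == "amoeboid"

    def test_equidistant_tie_first_class_in_order(self):
        cents = corner_centroids()
        out = nc.nc_classify(toy_table({"x": [5.0], "y": [5.0]}), cents)
        assert out == ["amoeboid"]

    def test_zscore_mode_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(4)
        frame = toy_table({"x": rng.random(40), "y": rng.random(40)},
                          labels=[PHENOTYPES[i % 4] for i in range(40)])
        cents = nc.compute_centroids(frame, subset=("x", "y"), scaling="zscore")
        base = nc.nc_classify(frame, cents)
        scaled = frame.assign(x=frame["x"] * 1000 + 5)
        cents2 = nc.compute_centroids(scaled, subset=("x", "y"), scaling="zscore")
        assert nc.nc_classify(scaled, cents2) == base


class TestConformity:
    def test_identical_labels(self):
        labels = [PHENOTYPES[i % 4] for i in range(20)]
        res = nc.conformity(labels, labels)
        assert res.conformity == 1.0
        assert (res.matrix == np.diag([5, 5, 5, 5])).all()

    def test_constructed_matrix_40_of_50(self):
        cnn, ncl = [], []
        for i, cls in enumerate(PHENOTYPES):
            cnn += [cls] * 10
            ncl += [cls] * 10
        cnn += ["activated"] * 5 + ["rod_like"] * 5
        ncl += ["rod_like"] * 5 + ["activated"] * 5
        res = nc.conformity(cnn, ncl)
        assert res.conformity == pytest.approx(40 / 50)
        assert res.matrix.sum() == 50

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        cnn = [PHENOTYPES[i] for i in rng.integers(0, 4, 50)]
        ncl = [PHENOTYPES[i] for i in rng.integers(0, 4, 50)]
        res1 = nc.conformity(cnn, ncl)
        perm = rng.permutation(50)
        res2 = nc.conformity([cnn[i] for i in perm], [ncl[i] for i in perm])
        assert res1.conformity == res2.conformity
        assert (res1.matrix == res2.matrix).all()

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            nc.conformity([], [])


class TestExactSymmetryTest:
    def test_symmetric_matrix_p_one(self):
        m = np.array([[5, 2, 1, 0], [2, 5, 3, 1], [1, 3, 5, 2], [0, 1, 2, 5]])
        p, pairs = nc.exact_symmetry_test(m)
        assert p == 1.0

    def test_single_discordant_pair_closed_form(self):
        m = np.zeros((4, 4), dtype=int)
        m[0, 1] = 10
        p, pairs = nc.exact_symmetry_test(m)
        row = pairs[(pairs.i == 0) & (pairs.j == 1)].iloc[0]
        assert row.p_raw == pytest.approx(2 * 0.5**10)

    def test_balanced_pair_p_one(self):
        m = np.zeros((4, 4), dtype=int)
        m[0, 1] = m[1, 0] = 1
        p, pairs = nc.exact_symmetry_test(m)
        assert pairs.iloc[0].p_raw == 1.0

    def test_all_zero_off_diagonal(self):
        p, _ = nc.exact_symmetry_test(np.diag([3, 3, 3, 3]))
        assert p == 1.0

    def test_non_square_raises(self):
        with pytest.raises(ValueError):
            nc.exact_symmetry_test(np.zeros((3, 4)))


class TestEnumerateSubsets:
    def test_full_range_count_131054(self):
        assert sum(1 for _ in nc.enumerate_subsets(NC_PARAM_NAMES, 2, 17)) == 131054
        assert nc.count_subsets(17, 2, 17) == 131054

    def test_single_size_full_width(self):
        subsets = list(nc.enumerate_subsets(("a", "b", "c"), 3, 3))
        assert subsets == [("a", "b", "c")]

    def test_four_params_2_to_4_is_11_by_brute_force(self):
        params = ("a", "b", "c", "d")
        got = list(nc.enumerate_subsets(params, 2, 4))
        brute = [
            s
            for k in range(2, 5)
            for s in itertools.combinations(params, k)
        ]
        assert got == brute
        assert len(got) == 11

    def test_duplicate_free_lexicographic(self):
        got = list(nc.enumerate_subsets(("a", "b", "c", "d", "e"), 2, 3))
        assert len(got) == len(set(got))
        by_k = {}
        for s in got:
            by_k.setdefault(len(s), []).append(s)
        for k, subs in by_k.items():
            assert subs == sorted(subs)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            list(nc.enumerate_subsets(("a", "b"), 0, 2))


def synthetic_feature_table(n=200, seed=0, noise_param=None):
    """4 separable clusters over 4 informative features (+ optional noise)."""
    rng = np.random.default_rng(seed)
    labels = [PHENOTYPES[i % 4] for i in range(n)]
    centers = {ph: rng.uniform(0, 10, 4) * (i + 1) for i, ph in enumerate(PHENOTYPES)}
    cols = {f"f{j}": [] for j in range(4)}
    for lab in labels:
        for j in range(4):
            cols[f"f{j}"].append(centers[lab][j] + rng.normal(0, 0.8))
    frame = pd.DataFrame(cols)
    if noise_param:
        frame[noise_param] = rng.normal(0, 1, n)
    return frame, labels


class TestSweep:
    def test_three_param_sweep_has_four_subsets_in_bounds(self):
        frame, labels = synthetic_feature_table(40, seed=1)
        res = nc.sweep(frame, labels, k_min=2, k_max=3, parameters=("f0", "f1", "f2"))
        assert len(res.records) == 4
        assert ((res.records.conformity >= 0) & (res.records.conformity <= 1)).all()

    def test_full_subset_matches_direct_conformity_call(self):
        frame, labels = synthetic_feature_table(60, seed=2)
        params = ("f0", "f1", "f2", "f3")
        res = nc.sweep(frame, labels, k_min=4, k_max=4, parameters=params)
        training = frame.assign(label=labels)
        cents = nc.compute_centroids(training, subset=params)
        direct = nc.conformity(labels, nc.nc_classify(frame, cents))
        assert res.records.conformity.iloc[0] == pytest.approx(direct.conformity)

    def test_noise_parameter_does_not_help(self):
        frame, labels = synthetic_feature_table(160, seed=3, noise_param="junk")
        params = ("f0", "f1", "f2", "f3", "junk")
        res = nc.sweep(frame, labels, k_min=2, k_max=5, parameters=params,
                       symmetry=False).records
        with_junk = res[res.subset.str.contains("junk")]
        without = res[~res.subset.str.contains("junk")]
        # paired comparison: adding the noise column never raises median conformity
        assert without.conformity.median() >= with_junk.conformity.median()

    def test_top_parameters_ranks_informative_over_noise(self):
        frame, labels = synthetic_feature_table(160, seed=6, noise_param="junk")
        params = ("f0", "f1", "f2", "f3", "junk")
        res = nc.sweep(frame, labels, k_min=2, k_max=5, parameters=params, symmetry=False)
        top = nc.top_parameters(res, top_fraction=0.2)
        ranked = list(top["parameter"])
        assert ranked[-1] == "junk" or "junk" not in ranked

    def test_sweep_cardinality_closed_form(self):
        frame, labels = synthetic_feature_table(24, seed=4, noise_param="junk")
        params = ("f0", "f1", "f2", "f3", "junk")
        res = nc.sweep(frame, labels, k_min=2, k_max=5, parameters=params, symmetry=False)
        assert len(res.records) == nc.count_subsets(5, 2, 5)


class TestCorrelationAnalysis:
    def test_self_and_monotone_transform_rho_one(self):
        rng = np.random.default_rng(5)
        x = rng.random(30)
        frame = pd.DataFrame({"x": x, "xcubed": x**3, "z": rng.random(30)})
        labels = [PHENOTYPES[i % 4] for i in range(30)]
        out = nc.correlation_analysis(frame, labels, parameters=("x", "xcubed", "z"))
        rho = out["correlation_matrix"]
        assert rho.loc["x", "x"] == pytest.approx(1.0)
        assert rho.loc["x", "xcubed"] == pytest.approx(1.0)

    def test_rho_matches_rank_then_pearson_oracle(self):
        frame = pd.DataFrame({"a": [3.0, 1.0, 4.0, 1.5, 5.0], "b": [2.0, 0.5, 9.0, 2.5, 6.0],
                              "c": [1.0, 2.0, 3.0, 4.0, 5.0]})
        labels = ["amoeboid", "activated", "rod_like", "ramified", "amoeboid"]
        out = nc.correlation_analysis(frame, labels, parameters=("a", "b", "c"))
        oracle = rank_then_pearson(frame["a"], frame["b"])
        assert out["correlation_matrix"].loc["a", "b"] == pytest.approx(oracle)

    def test_constant_column_gives_nan(self):
        frame = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [7.0] * 4})
        labels = list(PHENOTYPES)
        out = nc.correlation_analysis(frame, labels, parameters=("a", "b"))
        assert math.isnan(out["correlation_matrix"].loc["a", "b"])

    def test_too_few_cells_raises(self):
        frame = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]})
        with pytest.raises(ValueError):
            nc.correlation_analysis(frame, ["amoeboid", "activated"], parameters=("a", "b"))


def test_directional_conformity_vs_correlation_property():
    """Strongly correlated pairs agree with the CNN labeling less well than
    weakly correlated pairs, on a table built to contain both kinds."""
    rng = np.random.default_rng(11)
    n = 240
    labels = [PHENOTYPES[i % 4] for i in range(n)]
    class_idx = np.array([PHENOTYPES.index(l) for l in labels], dtype=float)
    # two complementary discriminative axes: neither separates alone
    f0 = (class_idx % 2) * 4 + rng.normal(0, 0.5, n)
    f1 = (class_idx // 2) * 4 + rng.normal(0, 0.5, n)
    # f3 nearly duplicates f0 -> the high-|rho| pair (f0, f3) spans one axis only
    f3 = f0 * 2 + rng.normal(0, 0.2, n)
    frame = pd.DataFrame({"f0": f0, "f1": f1, "f3": f3})
    out = nc.correlation_analysis(frame, labels, parameters=("f0", "f1", "f3"))
    pairs = out["pairs"].dropna(subset=["abs_rho"])
    strong = pairs[pairs.abs_rho > 0.8].conformity
    weak = pairs[pairs.abs_rho < 0.2].conformity
    assert len(strong) and len(weak)
    assert strong.mean() < weak.mean()
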