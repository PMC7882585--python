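"""Bray-Curtis, PCoA, PERMANOVA, CAP and multivariate dispersion."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import braycurtis, pdist, squareform

from fragbeta.datamodel import CommunityMatrix, ValidationError
from fragbeta.distance import (
    DistanceMatrix,
    bray_curtis,
    cap_fit,
    multivariate_dispersion,
    pcoa,
    permanova,
)


def _cm(array, prefix="s"):
    array = np.asarray(array)
    return CommunityMatrix(
        pd.DataFrame(array, index=[f"{prefix}{i}" for i in range(array.shape[0])],
                     columns=[f"sp{j}" for j in range(array.shape[1])])
    )


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        dm = bray_curtis(_cm([[3, 4], [3, 4]]), "none")
        assert dm.array[0, 1] == pytest.approx(0.0)

    def test_disjoint_rows_one(self):
        dm = bray_curtis(_cm([[3, 0], [0, 7]]), "none")
        assert dm.array[0, 1] == pytest.approx(1.0)

    def test_sqrt_transform_hand_value(self):
        # rows (4,0),(1,1): sqrt -> (2,0),(1,1); (|2-1|+|0-1|)/((2+1)+(0+1)) = 0.5
        dm = bray_curtis(_cm([[4, 0], [1, 1]]), "sqrt")
        assert dm.array[0, 1] == pytest.approx(0.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_semimetric_bounds_and_species_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.poisson(3, (5, 8))
        X[X.sum(axis=1) == 0, 0] = 1
        dm = bray_curtis(_cm(X), "sqrt").array
        assert (dm >= -1e-12).all() and (dm <= 1 + 1e-12).all()
        assert np.allclose(dm, dm.T)
        perm = rng.permutation(8)
        dm2 = bray_curtis(_cm(X[:, perm]), "sqrt").array
        np.testing.assert_allclose(dm, dm2, atol=1e-12)


class TestPCoA:
    def test_equilateral_closed_form(self):
        # 3 unit-equidistant sites: total inertia 1, two equal axes of 0.5
        dm = DistanceMatrix(pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc")))
        res = pcoa(dm)
        np.testing.assert_allclose(res.eigenvalues, [0.5, 0.5, 0.0], atol=1e-12)

    def test_points_on_line_single_axis(self):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        D = np.abs(x[:, None] - x[None, :])
        dm = DistanceMatrix(pd.DataFrame(D, index=list("abcd"), columns=list("abcd")))
        res = pcoa(dm)
        assert (res.eigenvalues[1:] < 1e-9).all()
        recovered = res.coordinates.iloc[:, 0].to_numpy()
        np.testing.assert_allclose(
            np.abs(recovered - recovered[0]), x, atol=1e-9
        )

    def test_coordinates_reproduce_distances_when_euclidean(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((6, 3))
        D = squareform(pdist(pts))
        dm = DistanceMatrix(pd.DataFrame(D, index=range(6), columns=range(6)))
        res = pcoa(dm)
        D2 = squareform(pdist(res.coordinates.to_numpy()))
        np.testing.assert_allclose(D, D2, atol=1e-9)


def _brute_force_permanova_p(D, labels_levels):
    """Exact p over all site->group assignments with the fixed group sizes."""
    D2 = D**2
    n = D.shape[0]

    def F_of(labels):
        sst = D2[np.triu_indices(n, 1)].sum() / n
        ssw = 0.0
        for lab in set(labels):
            idx = np.where(np.asarray(labels) == lab)[0]
            sub = D2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        a = len(set(labels)) - 1
        return ((sst - ssw) / a) / (ssw / (n - a - 1))

    obs = F_of(labels_levels)
    sizes = {lab: labels_levels.count(lab) for lab in set(labels_levels)}
    labs = sorted(sizes)
    Fs = []
    for combo in itertools.combinations(range(n), sizes[labs[0]]):
        labels = np.array([labs[1]] * n, dtype=object)
        labels[list(combo)] = labs[0]
        Fs.append(F_of(list(labels)))
    return obs, np.mean(np.asarray(Fs) >= obs - 1e-12)


class TestPermanova:
    def test_exact_enumeration_matches_brute_force(self):
        rng = np.random.default_rng(5)
        X = rng.poisson(6, (6, 9)) + 1
        cm = _cm(X)
        dm = bray_curtis(cm, "sqrt")
        g = pd.Series(["A"] * 3 + ["B"] * 3, index=cm.site_ids, name="grp")
        res = permanova(dm, g, n_perm=999, seed=3)
        assert res.exact
        F_oracle, p_oracle = _brute_force_permanova_p(dm.array, list(g))
        assert res.table.loc["grp", "pseudo_F"] == pytest.approx(F_oracle)
        assert res.table.loc["grp", "p"] == pytest.approx(p_oracle)

    def test_pseudo_f_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(8)
        X = rng.poisson(5, (10, 12)) + 1
        cm = _cm(X)
        dm = bray_curtis(cm, "sqrt")
        g = pd.Series(["A"] * 5 + ["B"] * 5, index=cm.site_ids, name="grp")
        ours = permanova(dm, g, n_perm=99, seed=0)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.array, ids=[str(i) for i in range(10)]),
            list(g), permutations=9,
        )
        assert ours.table.loc["grp", "pseudo_F"] == pytest.approx(
            theirs["test statistic"], rel=1e-10
        )

    def test_degenerate_separation_r2_near_one(self):
        # two tight clusters, zero within-group distance
        X = np.array([[5, 0], [5, 0], [5, 0], [0, 7], [0, 7], [0, 7]])
        cm = _cm(X)
        dm = bray_curtis(cm, "none")
        g = pd.Series(["A"] * 3 + ["B"] * 3, index=cm.site_ids, name="grp")
        res = permanova(dm, g, n_perm=99, seed=0)
        assert res.table.loc["grp", "R2"] == pytest.approx(1.0)

    def test_constant_grouping_rejected(self):
        X = np.eye(4, dtype=int) + 1
        cm = _cm(X)
        dm = bray_curtis(cm, "none")
        g = pd.Series(["A"] * 4, index=cm.site_ids, name="grp")
        with pytest.raises(ValidationError):
            permanova(dm, g, n_perm=9, seed=0)

    def test_type_one_error_nominal_under_exchangeability(self):
        # two arbitrary group labels on iid communities: p ~ uniform
        rng = np.random.default_rng(21)
        rejections = 0
        n_sim = 200
        for s in range(n_sim):
            X = rng.poisson(4, (12, 10)) + 1
            cm = _cm(X)
            dm = bray_curtis(cm, "sqrt")
            g = pd.Series(["A"] * 6 + ["B"] * 6, index=cm.site_ids, name="grp")
            res = permanova(dm, g, n_perm=99, seed=int(rng.integers(2**31)))
            rejections += res.table.loc["grp", "p"] <= 0.05
        # binomial(200, 0.05) central 99.9% region
        assert 1 <= rejections <= 22


class TestCAP:
    def test_first_axis_predictor_recovers_eigenvalue_share(self):
        rng = np.random.default_rng(12)
        X = rng.poisson(8, (12, 10)) + 1
        cm = _cm(X)
        dm = bray_curtis(cm, "sqrt")
        axes = pcoa(dm)
        pred = pd.DataFrame({"axis1": axes.coordinates.iloc[:, 0]})
        model = cap_fit(dm, pred, n_perm=49, seed=0)
        share = axes.positive_eigenvalues[0] / axes.positive_eigenvalues.sum()
        assert model.terms.loc["axis1", "explained_fraction"] == pytest.approx(share, rel=1e-9)

    def test_total_constrained_monotone_in_predictors(self):
        rng = np.random.default_rng(13)
        X = rng.poisson(8, (14, 12)) + 1
        cm = _cm(X)
        dm = bray_curtis(cm, "sqrt")
        preds = pd.DataFrame(rng.standard_normal((14, 3)),
                             index=cm.site_ids, columns=["a", "b", "c"])
        totals = [
            cap_fit(dm, preds.iloc[:, :k], n_perm=9, seed=0).total_constrained
            for k in (1, 2, 3)
        ]
        assert totals[0] <= totals[1] + 1e-12 <= totals[2] + 2e-12

    def test_zero_variance_predictor_rejected(self):
        X = np.eye(6, dtype=int) + 2
        cm = _cm(X)
        dm = bray_curtis(cm, "none")
        preds = pd.DataFrame({"flat": np.ones(6)}, index=cm.site_ids)
        with pytest.raises(ValidationError, match="zero-variance"):
            cap_fit(dm, preds, n_perm=9, seed=0)

    def test_collinear_predictors_named(self):
        rng = np.random.default_rng(14)
        X = rng.poisson(5, (10, 8)) + 1
        cm = _cm(X)
        dm = bray_curtis(cm, "none")
        v = rng.standard_normal(10)
        preds = pd.DataFrame({"v1": v, "v2": 2 * v}, index=cm.site_ids)
        with pytest.raises(ValidationError, match="collinear"):
            cap_fit(dm, preds, n_perm=9, seed=0)

    def test_noise_predictor_p_uniformish(self):
        rng = np.random.default_rng(15)
        hits = 0
        n_sim = 100
        for s in range(n_sim):
            X = rng.poisson(5, (12, 10)) + 1
            cm = _cm(X)
            dm = bray_curtis(cm, "sqrt")
            preds = pd.DataFrame({"noise": rng.standard_normal(12)}, index=cm.site_ids)
            m = cap_fit(dm, preds, n_perm=99, seed=int(rng.integers(2**31)))
            hits += m.terms.loc["noise", "p"] <= 0.05
        assert hits <= 14    # binomial(100, .05) 99.9% upper bound


class TestDispersion:
    def test_identical_subplots_zero(self):
        assert multivariate_dispersion([[1, 1, 0], [1, 1, 0], [1, 1, 0]]) == pytest.approx(0.0)

    def test_two_subplots_half_distance(self):
        a = np.array([[1, 1, 0, 0], [1, 0, 1, 1]])
        expected = braycurtis(a[0], a[1]) / 2
        assert multivariate_dispersion(a) == pytest.approx(expected)

    def test_duplicating_whole_plot_set_preserves_dispersion(self):
        # replicating every subplot changes neither the distance structure
        # nor the centroid, so dispersion is invariant
        rng = np.random.default_rng(31)
        for _ in range(10):
            X = rng.integers(0, 2, (4, 6))
            X[X.sum(axis=1) == 0, 0] = 1
            base = multivariate_dispersion(X)
            dup = multivariate_dispersion(np.vstack([X, X]))
            assert dup == pytest.approx(base, abs=1e-9)

    def test_dispersion_bounded_by_max_pairwise_distance(self):
        rng = np.random.default_rng(32)
        for _ in range(10):
            X = rng.integers(0, 2, (5, 7))
            X[X.sum(axis=1) == 0, 0] = 1
            D = squareform(pdist((X > 0).astype(float), metric="braycurtis"))
            assert multivariate_dispersion(X) <= D.max() + 1e-9
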