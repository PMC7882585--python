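"""Field-data derivations and varimax PCA condensation."""

import numpy as np
import pandas as pd
import pytest

from fragbeta.datamodel import (
    LandscapeTable,
    PCQRecords,
    PlantData,
    ValidationError,
)
from fragbeta.environment import (
    ellenberg_means,
    functional_dispersion,
    gower_distance,
    landscape_metrics,
    pca_varimax,
    pcq_metrics,
    varimax,
)


def _pcq_df(distances_by_point, dbh=20.0, conifer=False, dead=False, site="a"):
    rows = []
    for p, dists in enumerate(distances_by_point, start=1):
        for q, d in enumerate(dists, start=1):
            rows.append(
                {"site_id": site, "point_index": p, "quarter_index": q,
                 "distance_m": d, "tree_species_id": "t", "dbh_cm": dbh,
                 "is_conifer": conifer, "is_dead": dead}
            )
    return pd.DataFrame(rows)


class TestPCQ:
    def test_identical_dbh_zero_sd_and_cover_identity(self):
        rec = PCQRecords(_pcq_df([[2.0, 3.0, 2.5, 4.0]] * 3, dbh=30.0))
        fs = pcq_metrics(rec)
        assert fs.loc["a", "sd_basal_area_cm2"] == pytest.approx(0.0)
        assert fs.loc["a", "mean_basal_area_cm2"] == pytest.approx(np.pi * 15**2)
        # deciduous + conifer cover == density x mean basal area (m^2/ha)
        total_cover = fs.loc["a", "deciduous_cover_m2_ha"] + fs.loc["a", "conifer_cover_m2_ha"]
        assert total_cover == pytest.approx(
            fs.loc["a", "density_trees_ha"] * fs.loc["a", "mean_basal_area_cm2"] * 1e-4
        )

    def test_doubling_distances_quarters_density(self):
        d1 = pcq_metrics(PCQRecords(_pcq_df([[1.0, 2.0, 1.5, 2.5]] * 4)))
        d2 = pcq_metrics(PCQRecords(_pcq_df([[2.0, 4.0, 3.0, 5.0]] * 4)))
        assert d2.loc["a", "density_trees_ha"] == pytest.approx(
            d1.loc["a", "density_trees_ha"] / 4
        )

    def test_pollard_formula_hand_value(self):
        # n=2 points, sum d^2 = 8: 1e4 * 4*(8-1) / (pi*8)
        rec = PCQRecords(_pcq_df([[1.0, 1.0, 1.0, 1.0]] * 2))
        fs = pcq_metrics(rec)
        assert fs.loc["a", "density_trees_ha"] == pytest.approx(1e4 * 28 / (np.pi * 8))

    def test_incomplete_points_excluded(self):
        df = _pcq_df([[1.0, 1.0, 1.0, 1.0]] * 2)
        df = df.iloc[:-1]   # drop one quarter of point 2
        fs = pcq_metrics(PCQRecords(df))
        # only point 1 remains: n=1, sum d^2 = 4
        assert fs.loc["a", "density_trees_ha"] == pytest.approx(1e4 * 12 / (np.pi * 4))

    def test_dead_share(self):
        df = pd.concat([_pcq_df([[1.0] * 4], dead=True), _pcq_df([[1.0] * 4] * 3, dead=False)])
        df["point_index"] = np.repeat([1, 2, 3, 4], 4)
        fs = pcq_metrics(PCQRecords(df))
        assert fs.loc["a", "pct_dead_trees"] == pytest.approx(25.0)


@pytest.fixture
def small_plants():
    inc = pd.DataFrame(
        [[1, 1, 0], [1, 0, 1], [0, 0, 1]],
        index=["siteA", "siteB", "siteC"],
        columns=["p1", "p2", "p3"],
    )
    traits = pd.DataFrame(
        {"height": [10.0, 30.0, 20.0], "form": ["herb", "shrub", "herb"]},
        index=["p1", "p2", "p3"],
    )
    ellen = pd.DataFrame(
        {"humidity": [4.0, 6.0, np.nan], "nutrients": [3.0, np.nan, 5.0],
         "temperature": [6.0, 7.0, 8.0]},
        index=["p1", "p2", "p3"],
    )
    return PlantData(inc, traits, ellen)


class TestEllenberg:
    def test_means_respect_missing_values(self, small_plants):
        em = ellenberg_means(small_plants)
        assert em.loc["siteA", "humidity"] == pytest.approx(5.0)    # (4+6)/2
        assert em.loc["siteA", "nutrients"] == pytest.approx(3.0)   # p2 missing
        assert em.loc["siteB", "humidity"] == pytest.approx(4.0)    # p3 missing
        assert em.loc["siteC", "temperature"] == pytest.approx(8.0)

    def test_no_scorable_species_gives_nan(self, small_plants):
        em = ellenberg_means(small_plants)
        assert np.isnan(em.loc["siteC", "humidity"])   # only p3, humidity missing


class TestFDis:
    def test_single_species_site_zero(self, small_plants):
        fdis = functional_dispersion(small_plants)
        assert fdis["siteC"] == pytest.approx(0.0)

    def test_two_species_half_gower_distance(self, small_plants):
        D = gower_distance(small_plants.traits)
        fdis = functional_dispersion(small_plants)
        assert fdis["siteA"] == pytest.approx(D.loc["p1", "p2"] / 2)

    def test_gower_mixed_traits_hand_value(self, small_plants):
        D = gower_distance(small_plants.traits)
        # p1 vs p2: height |10-30|/20 = 1, form mismatch = 1 -> mean 1.0
        assert D.loc["p1", "p2"] == pytest.approx(1.0)
        # p1 vs p3: height |10-20|/20 = 0.5, form match = 0 -> 0.25
        assert D.loc["p1", "p3"] == pytest.approx(0.25)

    def test_adding_centroid_species_does_not_increase_fdis(self):
        # numeric traits only; a species at the trait centroid pulls FDis down
        rng = np.random.default_rng(5)
        for _ in range(10):
            traits = pd.DataFrame(
                rng.uniform(0, 1, (4, 2)), index=[f"p{i}" for i in range(4)],
                columns=["t1", "t2"],
            )
            centroid = traits.mean(axis=0)
            traits5 = pd.concat([traits, centroid.to_frame("pc").T])
            inc4 = pd.DataFrame([[1, 1, 1, 1]], index=["s"], columns=traits.index)
            inc5 = pd.DataFrame([[1, 1, 1, 1, 1]], index=["s"], columns=traits5.index)
            ell4 = pd.DataFrame(np.full((4, 3), 5.0), index=traits.index,
                                columns=["humidity", "nutrients", "temperature"])
            ell5 = pd.DataFrame(np.full((5, 3), 5.0), index=traits5.index,
                                columns=["humidity", "nutrients", "temperature"])
            f4 = functional_dispersion(PlantData(inc4, traits, ell4))["s"]
            f5 = functional_dispersion(PlantData(inc5, traits5, ell5))["s"]
            assert f5 <= f4 + 1e-9


def _landscape_row(site, r, forest, reed, grass, edge=100.0):
    return {
        "site_id": site, "radius_m": r, "forest": forest, "reed": reed,
        "grassland": grass, "water": 0.0, "agriculture": 0.05,
        "urban_industrial": 0.05, "edge_length_m": edge,
        "to_edge_m": 10.0, "to_canal_m": 20.0, "to_industry_m": 30.0,
    }


class TestLandscape:
    def test_equal_thirds_shannon_ln3(self):
        rows = [_landscape_row("a", r, 0.2, 0.2, 0.2) for r in (200, 500)]
        lm = landscape_metrics(LandscapeTable(pd.DataFrame(rows)))
        assert lm.loc[("a", 200), "habitat_diversity"] == pytest.approx(np.log(3))

    def test_single_class_zero_diversity(self):
        rows = [_landscape_row("a", r, 0.6, 0.0, 0.0) for r in (200, 500)]
        lm = landscape_metrics(LandscapeTable(pd.DataFrame(rows)))
        assert lm.loc[("a", 500), "habitat_diversity"] == pytest.approx(0.0)

    def test_edge_density_arithmetic(self):
        # 500 m buffer = 78.54 ha; 4712 m of edge -> 60.0 m/ha
        rows = [_landscape_row("a", r, 0.5, 0.1, 0.1, edge=4712.0) for r in (200, 500)]
        lm = landscape_metrics(LandscapeTable(pd.DataFrame(rows)))
        assert lm.loc[("a", 500), "edge_density_m_ha"] == pytest.approx(60.0, abs=0.01)

    def test_modified_fraction_sums_classes(self):
        rows = [_landscape_row("a", r, 0.5, 0.1, 0.1) for r in (200, 500)]
        lm = landscape_metrics(LandscapeTable(pd.DataFrame(rows)))
        assert lm.loc[("a", 200), "modified_fraction"] == pytest.approx(0.1)


class TestVarimaxPCA:
    def _blocked_data(self, seed=42, n=200):
        rng = np.random.default_rng(seed)
        F = rng.standard_normal((n, 2))
        load = np.zeros((6, 2))
        load[:3, 0] = [0.9, 0.8, 0.85]
        load[3:, 1] = [0.9, 0.85, 0.8]
        X = F @ load.T + 0.3 * rng.standard_normal((n, 6))
        return pd.DataFrame(X, columns=[f"v{i}" for i in range(6)]), load

    def test_planted_two_factor_recovery(self):
        data, load = self._blocked_data()
        res = pca_varimax(data)
        assert res.n_axes == 2
        L = res.loadings.to_numpy()
        planted = load / np.linalg.norm(load, axis=0)
        for j in range(2):
            congruence = max(
                abs(planted[:, j] @ L[:, i]) / np.linalg.norm(L[:, i]) for i in range(2)
            )
            assert congruence > 0.95
        # each variable loads highest on its own block's factor
        for v in range(6):
            assert np.argmax(np.abs(L[v])) == (0 if v < 3 else 1) or \
                np.argmax(np.abs(L[v])) == (1 if v < 3 else 0)

    def test_rotation_preserves_communalities_and_total_variance(self):
        data, _ = self._blocked_data(seed=7)
        res = pca_varimax(data)
        Z = (data - data.mean()) / data.std(ddof=1)
        eigval, eigvec = np.linalg.eigh(np.corrcoef(Z.to_numpy(), rowvar=False))
        order = np.argsort(eigval)[::-1]
        L0 = eigvec[:, order][:, : res.n_axes] * np.sqrt(eigval[order][: res.n_axes])
        np.testing.assert_allclose(
            (L0**2).sum(axis=1), (res.loadings.to_numpy() ** 2).sum(axis=1), atol=1e-8
        )
        assert res.explained_fraction.sum() == pytest.approx(
            res.explained_prerotation.sum(), abs=1e-10
        )

    def test_sign_convention_deterministic(self):
        data, _ = self._blocked_data(seed=11)
        res = pca_varimax(data)
        for name in res.axis_names:
            col = res.loadings[name]
            assert col.iloc[np.argmax(np.abs(col.to_numpy()))] > 0

    def test_constant_variable_named_in_error(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ValidationError, match="flat"):
            pca_varimax(df)

    def test_varimax_orthogonality_of_rotation(self):
        rng = np.random.default_rng(3)
        L = rng.standard_normal((8, 3))
        _, R = varimax(L)
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-10)
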