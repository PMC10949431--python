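import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import microtempo as mt
from microtempo.multivariate import _random_permutation, gower_center


def _euclidean_df(X, ids=None):
    ids = ids or [f"s{i}" for i in range(X.shape[0])]
    return pd.DataFrame(squareform(pdist(X)), index=ids, columns=ids)


def _oneway_permanova_F(d2, labels):
    """Independent pseudo-F from within-group squared-distance sums."""
    labels = np.asarray(labels)
    n = len(labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            block = d2[np.ix_(idx, idx)]
            ss_within += block[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    a = len(groups)
    return (ss_between / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def test_ss_decomposition_exact(self, small_dataset):
        table, metadata, *_ = small_dataset
        d = mt.bray_curtis(table)
        res = mt.permanova(
            d, metadata, ["season", "year", "season:year", "species"],
            n_perm=19, seed=0,
        )
        t = res.table
        terms = t.drop(index=["Residual", "Total"])
        assert terms["SS"].sum() + t.loc["Residual", "SS"] == pytest.approx(
            t.loc["Total", "SS"], abs=1e-8
        )
        assert terms["R2"].sum() <= 1.0

    def test_oneway_matches_scikit_bio(self):
        """Independent route: scikit-bio's one-way PERMANOVA on the same data."""
        from skbio.stats.distance import DistanceMatrix as SkbDM
        from skbio.stats.distance import permanova as skb_permanova

        rng = np.random.default_rng(21)
        X = rng.random((12, 5))
        ids = [f"s{i}" for i in range(12)]
        d = pd.DataFrame(squareform(pdist(X)), index=ids, columns=ids)
        meta = pd.DataFrame({"g": ["a"] * 6 + ["b"] * 6}, index=ids)
        mine = mt.permanova(d, meta, ["g"], n_perm=99, seed=0)
        ref = skb_permanova(SkbDM(d.to_numpy(), ids), grouping=meta["g"], permutations=99)
        assert float(mine.table.loc["g", "F"]) == pytest.approx(
            float(ref["test statistic"]), rel=1e-10
        )

    def test_oneway_F_matches_independent_formula(self):
        rng = np.random.default_rng(1)
        X = rng.random((9, 4))
        d = _euclidean_df(X)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        meta = pd.DataFrame({"g": labels}, index=d.index)
        res = mt.permanova(d, meta, ["g"], n_perm=19, seed=0)
        expect = _oneway_permanova_F(d.to_numpy() ** 2, labels)
        assert float(res.table.loc["g", "F"]) == pytest.approx(expect, rel=1e-10)

    def test_exact_enumeration_matches_brute_force(self):
        rng = np.random.default_rng(2)
        X = rng.random((6, 3))
        X[:3] += 0.6  # separate the groups so p is informative
        d = _euclidean_df(X)
        labels = np.array(["a"] * 3 + ["b"] * 3)
        meta = pd.DataFrame({"g": labels}, index=d.index)
        res = mt.permanova(d, meta, ["g"], permutations="exact")
        d2 = d.to_numpy() ** 2
        f_obs = _oneway_permanova_F(d2, labels)
        count = total = 0
        for keep in itertools.combinations(range(6), 3):
            lab = np.array(["b"] * 6)
            lab[list(keep)] = "a"
            total += 1
            count += _oneway_permanova_F(d2, lab) >= f_obs - 1e-12
        assert res.table.loc["g", "p"] == pytest.approx(count / total, abs=1e-12)
        assert res.n_perm == 720

    def test_no_effect_duplicated_composition(self):
        X = np.vstack([np.random.default_rng(0).random((4, 3))] * 2)
        d = _euclidean_df(X)
        meta = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 4}, index=d.index)
        res = mt.permanova(d, meta, ["g"], n_perm=99, seed=0)
        assert res.r2("g") == pytest.approx(0.0, abs=1e-10)

    def test_single_level_term_rejected(self, small_dataset):
        table, metadata, *_ = small_dataset
        d = mt.bray_curtis(table)
        with pytest.raises(ValueError):
            mt.permanova(d, metadata, ["habitat"], n_perm=9)

    def test_strata_permutations_stay_within_levels(self):
        rng = np.random.default_rng(0)
        strata_idx = [np.array([0, 1, 2]), np.array([3, 4]), np.array([5, 6, 7, 8])]
        for _ in range(200):
            perm = _random_permutation(rng, 9, strata_idx)
            for idx in strata_idx:
                assert set(perm[idx]) == set(idx)

    def test_strata_run_end_to_end(self, small_dataset):
        table, metadata, *_ = small_dataset
        d = mt.bray_curtis(table)
        res = mt.permanova(
            d, metadata, ["season"], n_perm=49, strata="genotype", seed=0
        )
        assert 0 < res.p("season") <= 1


class TestPermdisp:
    def test_hand_anova_example(self):
        pts = np.array([0.0, 2, 4, 1, 2, 3])[:, None]
        d = _euclidean_df(pts, ids=list("abcdef"))
        res = mt.permdisp(d, pd.Series(list("AAABBB"), index=d.index))
        assert res.distances.tolist() == pytest.approx([2, 0, 2, 1, 0, 1])
        assert res.F == pytest.approx(0.8)

    def test_identical_clouds_no_difference(self):
        pts = np.array([[0.0], [1.0], [3.0], [0.0], [1.0], [3.0]])
        d = _euclidean_df(pts)
        res = mt.permdisp(d, pd.Series(list("AAABBB"), index=d.index))
        assert res.F == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)

    def test_scaling_group_scales_distances(self):
        a = np.array([[0.0], [2.0], [4.0]])
        d1 = _euclidean_df(np.vstack([a, a]))
        d10 = _euclidean_df(np.vstack([a, a * 10]))
        g = pd.Series(list("AAABBB"), index=d1.index)
        r1, r10 = mt.permdisp(d1, g), mt.permdisp(d10, g)
        assert r10.group_means["B"] == pytest.approx(10 * r1.group_means["B"])

    def test_singleton_group_rejected(self):
        pts = np.arange(4, dtype=float)[:, None]
        d = _euclidean_df(pts)
        with pytest.raises(ValueError):
            mt.permdisp(d, pd.Series(["A", "A", "A", "B"], index=d.index))

    def test_bray_curtis_negative_eigenvalue_bookkeeping(self, small_dataset):
        table, metadata, *_ = small_dataset
        d = mt.bray_curtis(table)
        res = mt.permdisp(d, metadata["season"])
        assert (res.distances >= 0).all()
        assert np.isfinite(res.F)


class TestDbrda:
    def test_reduces_to_rda_on_euclidean_input(self):
        rng = np.random.default_rng(4)
        Y = rng.random((20, 5))
        constraints = pd.DataFrame(
            {"x1": rng.random(20), "x2": rng.random(20)},
            index=[f"s{i}" for i in range(20)],
        )
        d = _euclidean_df(Y, ids=list(constraints.index))
        res = mt.dbrda(d, constraints, n_perm=9, seed=0)
        Yc = Y - Y.mean(axis=0)
        Xc = constraints.to_numpy() - constraints.to_numpy().mean(axis=0)
        H = Xc @ np.linalg.pinv(Xc)
        frac = np.sum((H @ Yc) ** 2) / np.sum(Yc ** 2)
        assert res.constrained_inertia / res.total_inertia == pytest.approx(frac, rel=1e-10)

    def test_inertia_partition(self, small_dataset):
        table, metadata, *_ = small_dataset
        d = mt.bray_curtis(table)
        constraints = metadata[["season", "species"]].astype(str)
        with pytest.warns(UserWarning, match="negative eigenvalue"):
            res = mt.dbrda(d, constraints, n_perm=9, seed=0)
        assert res.constrained_inertia + res.unconstrained_inertia == pytest.approx(
            res.total_inertia, abs=1e-8
        )

    def test_constant_constraint_rejected(self):
        d = _euclidean_df(np.arange(6, dtype=float)[:, None])
        constraints = pd.DataFrame({"x": [1.0] * 6}, index=d.index)
        with pytest.raises(ValueError, match="constant"):
            mt.dbrda(d, constraints, n_perm=9)

    def test_aliased_column_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(5)
        Y = rng.random((10, 3))
        x = rng.random(10)
        constraints = pd.DataFrame(
            {"x1": x, "x2": 2 * x}, index=[f"s{i}" for i in range(10)]
        )
        d = _euclidean_df(Y, ids=list(constraints.index))
        import logging

        with caplog.at_level(logging.WARNING):
            res = mt.dbrda(d, constraints, n_perm=9, seed=0)
        assert "rank deficient" in caplog.text


class TestClimatePca:
    def _climate(self, n=40, seed=0):
        dates = pd.date_range("2018-01-01", periods=n)
        rng = np.random.default_rng(seed)
        x = rng.random(n)
        return pd.DataFrame(
            {"date": dates, "tmin": x, "tmax": x + 1, "day_length": 2 * x + 5,
             "srad": 100.0, "precip": 3.0, "vapor_pressure": 900.0}
        )

    def test_correlated_variables_load_on_pc1(self):
        climate = self._climate()
        res = mt.climate_pca(climate, [pd.Timestamp("2018-02-01")], window_days=7)
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_minmax_scaling_record(self):
        climate = self._climate()
        res = mt.climate_pca(climate, [pd.Timestamp("2018-02-01")], window_days=7)
        assert (res.scaling["min"] <= res.scaling["max"]).all()
        # scaled window rows span [0, 1] per non-constant variable
        from microtempo.multivariate import climate_windows, minmax_scale_columns
        from microtempo.io import CLIMATE_VARIABLES

        win = climate_windows(climate, [pd.Timestamp("2018-02-01")], 7)
        scaled, _ = minmax_scale_columns(win, CLIMATE_VARIABLES)
        assert scaled["tmin"].min() == 0.0 and scaled["tmin"].max() == 1.0

    def test_window_before_coverage_rejected(self):
        climate = self._climate()
        with pytest.raises(ValueError, match="cover"):
            mt.climate_pca(climate, [pd.Timestamp("2018-01-03")], window_days=7)

    def test_date_scores_one_row_per_sample_date(self):
        climate = self._climate()
        dates = [pd.Timestamp("2018-02-01"), pd.Timestamp("2018-02-05")]
        res = mt.climate_pca(climate, dates, window_days=7)
        assert list(res.date_scores.index) == dates


def test_gower_centering_properties():
    rng = np.random.default_rng(6)
    d = squareform(pdist(rng.random((8, 3))))
    G = gower_center(d)
    assert np.allclose(G.sum(axis=0), 0.0, atol=1e-10)
    assert np.allclose(G, G.T)
    # trace(G) equals the classical total sum of squares of the coordinates
    X = rng.random((8, 3))
    G2 = gower_center(squareform(pdist(X)))
    ss = ((X - X.mean(axis=0)) ** 2).sum()
    assert np.trace(G2) == pytest.approx(ss, rel=1e-10)
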