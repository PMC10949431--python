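import itertools

import numpy as np
import pandas as pd
import pytest

import microtempo as mt


@pytest.fixture()
def taxonomy():
    return pd.DataFrame(
        {
            "kingdom": "Fungi",
            "phylum": "Mucoromycota",
            "class": "Mortierellomycetes",
            "order": "Mortierellales",
            "family": ["Mortierellaceae", "Mortierellaceae", "Inocybaceae"],
            "genus": ["Mortierella", None, "UnknownGenus"],
        },
        index=["F1", "F2", "F3"],
    )


@pytest.fixture()
def guild_table():
    return pd.DataFrame(
        {"guild": ["saprotroph", "ectomycorrhizal"], "rank": ["genus", "family"]},
        index=pd.Index(["Mortierella", "Mortierellaceae"], name="taxon"),
    )


class TestAssignGuilds:
    def test_genus_exact_match(self, taxonomy, guild_table):
        out = mt.assign_guilds(taxonomy, guild_table)
        assert out.loc["F1", "guild"] == "saprotroph"
        assert out.loc["F1", "matched_rank"] == "genus"

    def test_family_fallback_when_genus_missing(self, taxonomy, guild_table):
        out = mt.assign_guilds(taxonomy, guild_table)
        assert out.loc["F2", "guild"] == "ectomycorrhizal"
        assert out.loc["F2", "matched_rank"] == "family"

    def test_no_match_unclassified(self, taxonomy, guild_table):
        out = mt.assign_guilds(taxonomy, guild_table)
        assert out.loc["F3", "guild"] == "unclassified"

    def test_duplicate_taxon_key_rejected(self, taxonomy, guild_table):
        dup = pd.concat([guild_table, guild_table.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            mt.assign_guilds(taxonomy, dup)


class TestGuildAbundance:
    def test_single_guild_proportion_one(self, taxonomy, guild_table):
        counts = pd.DataFrame({"s1": [3, 2, 5]}, index=taxonomy.index)
        assignment = mt.assign_guilds(taxonomy, guild_table)
        assignment["guild"] = "saprotroph"
        out = mt.guild_abundance(counts, assignment)
        assert out.loc["saprotroph", "s1"] == pytest.approx(1.0)

    def test_three_to_one_split(self):
        counts = pd.DataFrame({"s1": [3, 1]}, index=["F1", "F2"])
        assignment = pd.DataFrame(
            {"guild": ["saprotroph", "endophyte"]}, index=["F1", "F2"]
        )
        out = mt.guild_abundance(counts, assignment)
        assert out.loc["saprotroph", "s1"] == pytest.approx(0.75)
        assert out.loc["endophyte", "s1"] == pytest.approx(0.25)

    def test_columns_sum_to_one(self, small_dataset):
        table, _, taxonomy, _ = small_dataset
        guilds = mt.generate_guild_table(taxonomy, seed=0)
        assignment = mt.assign_guilds(taxonomy, guilds)
        out = mt.guild_abundance(table, assignment)
        assert np.allclose(out.sum(axis=0), 1.0)


class TestAnova:
    def test_one_way_hand_example(self):
        response = pd.Series([1.0, 2, 3, 4, 5, 6], index=[f"s{i}" for i in range(6)])
        meta = pd.DataFrame({"species": ["x"] * 3 + ["y"] * 3}, index=response.index)
        out = mt.anova_three_way(response, meta, factors=("species",))
        assert out.loc["species", "F"] == pytest.approx(13.5)
        assert out.loc["species", "df"] == 1
        assert out.loc["Residual", "df"] == 4

    def test_matches_projection_oracle(self):
        rng = np.random.default_rng(0)
        n = 24
        meta = pd.DataFrame(
            {"season": rng.choice(["w", "s"], n), "year": rng.choice(["1", "2"], n)},
            index=[f"s{i}" for i in range(n)],
        )
        y = pd.Series(rng.normal(size=n), index=meta.index)
        out = mt.anova_three_way(y, meta, factors=("season", "year"))
        # sequential SS via explicit nested projections
        def hat(cols):
            X = np.column_stack(cols)
            return X @ np.linalg.pinv(X)

        ones = np.ones((n, 1))
        a = (meta["season"] == "w").to_numpy(float)[:, None]
        b = (meta["year"] == "1").to_numpy(float)[:, None]
        yv = y.to_numpy()
        h0, h1 = hat([ones]), hat([ones, a])
        h2 = hat([ones, a, b])
        h3 = hat([ones, a, b, a * b])
        ss_season = yv @ (h1 - h0) @ yv
        ss_year = yv @ (h2 - h1) @ yv
        ss_inter = yv @ (h3 - h2) @ yv
        assert out.loc["season", "sum_sq"] == pytest.approx(ss_season, rel=1e-8)
        assert out.loc["year", "sum_sq"] == pytest.approx(ss_year, rel=1e-8)
        assert out.loc["season:year", "sum_sq"] == pytest.approx(ss_inter, rel=1e-8)

    def test_constant_response_guarded(self):
        response = pd.Series([2.0] * 8, index=[f"s{i}" for i in range(8)])
        meta = pd.DataFrame({"season": ["w", "s"] * 4}, index=response.index)
        out = mt.anova_three_way(response, meta, factors=("season",))
        assert out.loc["season", "F"] == 0.0
        assert out.loc["season", "p"] == 1.0

    def test_additive_balanced_design_zero_interaction(self):
        rows = []
        for s in ("w", "x"):
            for yr in ("1", "2"):
                for rep in range(3):
                    rows.append({"season": s, "year": yr,
                                 "resp": (s == "w") * 2.0 + (yr == "1") * 5.0})
        df = pd.DataFrame(rows, index=[f"s{i}" for i in range(12)])
        out = mt.anova_three_way(df["resp"], df, factors=("season", "year"))
        assert out.loc["season:year", "sum_sq"] == pytest.approx(0.0, abs=1e-12)

    def test_balanced_design_order_invariant(self):
        rng = np.random.default_rng(3)
        rows = []
        for s in ("w", "x"):
            for yr in ("1", "2"):
                for rep in range(4):
                    rows.append({"season": s, "year": yr})
        meta = pd.DataFrame(rows, index=[f"s{i}" for i in range(16)])
        y = pd.Series(rng.normal(size=16), index=meta.index)
        a = mt.anova_three_way(y, meta, factors=("season", "year"))
        b = mt.anova_three_way(y, meta, factors=("year", "season"))
        assert a.loc["season", "sum_sq"] == pytest.approx(b.loc["season", "sum_sq"])
        assert a.loc["year", "sum_sq"] == pytest.approx(b.loc["year", "sum_sq"])

    def test_single_level_factor_dropped(self, caplog):
        import logging

        response = pd.Series([1.0, 2, 3, 4], index=[f"s{i}" for i in range(4)])
        meta = pd.DataFrame(
            {"season": ["w", "w", "s", "s"], "year": ["1"] * 4}, index=response.index
        )
        with caplog.at_level(logging.WARNING):
            out = mt.anova_three_way(response, meta, factors=("season", "year"))
        assert "year" not in out.index


class TestTukey:
    def test_equal_means_share_letter(self):
        # each cell holds the same ten values: identical means, nonzero spread
        y = pd.Series(
            np.tile(np.arange(10, dtype=float), 3), index=[f"s{i}" for i in range(30)]
        )
        cells = pd.Series(np.repeat(["a", "b", "c"], 10), index=y.index)
        pairs, letters = mt.tukey_hsd(y, cells)
        assert (pairs["p_adj"] > 0.9).all()
        assert len(set(letters)) == 1

    def test_separated_cells_distinct_letters(self):
        y = pd.Series(
            [0.0, 0.01, 0.02, 5.0, 5.01, 5.02], index=[f"s{i}" for i in range(6)]
        )
        cells = pd.Series(["lo"] * 3 + ["hi"] * 3, index=y.index)
        pairs, letters = mt.tukey_hsd(y, cells)
        assert set(letters["lo"]) != set(letters["hi"])

    def test_letters_are_valid_nonsignificance_cover(self):
        rng = np.random.default_rng(2)
        y = pd.Series(
            np.concatenate([rng.normal(m, 1.0, 8) for m in (0, 0.5, 1.2, 3.0)]),
            index=[f"s{i}" for i in range(32)],
        )
        cells = pd.Series(
            np.repeat(["c1", "c2", "c3", "c4"], 8), index=y.index
        )
        pairs, letters = mt.tukey_hsd(y, cells)
        for _, row in pairs.iterrows():
            g1, g2 = str(row["group1"]), str(row["group2"])
            shared = set(letters[g1]) & set(letters[g2])
            if row["p_adj"] <= 0.05:
                assert not shared  # significant pairs never share a letter
            else:
                assert shared  # non-significant pairs share one

    def test_adjusted_p_close_to_permutation_oracle(self):
        rng = np.random.default_rng(7)
        means = {"g1": 0.0, "g2": 0.8, "g3": 1.6}
        y = pd.Series(
            np.concatenate([rng.normal(means[g], 1.0, 10) for g in means]),
            index=[f"s{i}" for i in range(30)],
        )
        cells = pd.Series(np.repeat(list(means), 10), index=y.index)
        pairs, _ = mt.tukey_hsd(y, cells)

        # permutation oracle: null distribution of the maximum studentized
        # range statistic over pairs, labels permuted
        def q_stats(values, labels):
            groups = {g: values[labels == g] for g in np.unique(labels)}
            resid = np.concatenate([v - v.mean() for v in groups.values()])
            ms = (resid ** 2).sum() / (len(values) - len(groups))
            out = {}
            for g1, g2 in itertools.combinations(sorted(groups), 2):
                v1, v2 = groups[g1], groups[g2]
                se = np.sqrt(ms / 2 * (1 / len(v1) + 1 / len(v2)))
                out[(g1, g2)] = abs(v1.mean() - v2.mean()) / se
            return out

        values, labels = y.to_numpy(), cells.to_numpy()
        obs = q_stats(values, labels)
        max_null = []
        perm_rng = np.random.default_rng(0)
        for _ in range(3000):
            max_null.append(max(q_stats(values, perm_rng.permutation(labels)).values()))
        max_null = np.asarray(max_null)
        for _, row in pairs.iterrows():
            key = tuple(sorted([str(row["group1"]), str(row["group2"])]))
            p_perm = float((max_null >= obs[key]).mean())
            assert row["p_adj"] == pytest.approx(p_perm, abs=0.02)

    def test_all_singleton_cells_rejected(self):
        y = pd.Series([1.0, 2.0], index=["s1", "s2"])
        cells = pd.Series(["a", "b"], index=y.index)
        with pytest.raises(ValueError):
            mt.tukey_hsd(y, cells)
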