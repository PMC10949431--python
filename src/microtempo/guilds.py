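"""Fungal guild assignment and the factorial ANOVA / Tukey HSD machinery.

Guilds (saprotroph, ectomycorrhizal, plant pathogen, ...) are assigned from
a user- or generator-supplied lookup table mapping taxon names at any rank
to guilds; the most specific matching rank wins.  Per-sample guild relative
abundances, alpha diversity and core-group abundances are all compared with
a three-way ANOVA (season, year, host species and their interactions,
sequential Type-I sums of squares) followed by Tukey's honestly significant
difference test with a compact letter display over season-by-year cells.
"""

from __future__ import annotations

import logging
import string
import warnings
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import TAXONOMY_RANKS, CountTable
from .normalize import relative_abundance

logger = logging.getLogger(__name__)

# genus is the most specific rank consulted first, then coarser ranks
_MATCH_ORDER = tuple(reversed(TAXONOMY_RANKS))


def assign_guilds(taxonomy: pd.DataFrame, guild_table: pd.DataFrame) -> pd.DataFrame:
    """Assign one guild per ASV by most-specific-rank lookup.

    ``guild_table`` is indexed by taxon name with a ``guild`` column (and
    optional ``confidence`` passed through).  For each ASV the ranks are
    consulted genus first, then family, order, ...; the first match wins
    and no match yields "unclassified".
    """
    if guild_table.index.duplicated().any():
        dup = guild_table.index[guild_table.index.duplicated()][0]
        raise ValueError(f"duplicate taxon key {dup!r} in guild table")
    lookup = guild_table["guild"].to_dict()
    confidence = (
        guild_table["confidence"].to_dict()
        if "confidence" in guild_table.columns
        else {}
    )
    rows = []
    for asv, tax in taxonomy.iterrows():
        guild, rank, conf = "unclassified", None, None
        for r in _MATCH_ORDER:
            name = tax.get(r)
            if pd.isna(name) or name in ("", "unclassified"):
                continue
            if name in lookup:
                guild, rank, conf = lookup[name], r, confidence.get(name)
                break
        rows.append(
            {"asv_id": asv, "guild": guild, "matched_rank": rank, "confidence": conf}
        )
    return pd.DataFrame(rows).set_index("asv_id")


def guild_abundance(
    table: CountTable | pd.DataFrame,
    guilds: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-sample guild relative abundances (guilds x samples, columns sum to 1)."""
    counts = table.counts if isinstance(table, CountTable) else table
    props = relative_abundance(counts)
    labels = guilds.loc[counts.index, "guild"]
    out = props.groupby(labels.to_numpy()).sum()
    out.index.name = "guild"
    return out


def anova_three_way(
    response: pd.Series,
    metadata: pd.DataFrame,
    factors: tuple[str, ...] = ("season", "year", "species"),
) -> pd.DataFrame:
    """Factorial ANOVA with sequential (Type-I) SS in the stated factor order.

    Fits ``response ~ season * year * species`` (all interactions); factors
    with a single observed level are dropped with a warning, as are
    interactions.  Returns the ANOVA table with term, df, sum_sq, mean_sq,
    F and p rows plus the residual.
    """
    meta = metadata.loc[response.index]
    usable = []
    for f in factors:
        if meta[f].astype(str).nunique() >= 2:
            usable.append(f)
        else:
            logger.warning("anova_three_way: factor %r has one level; dropped", f)
    if not usable:
        raise ValueError("no factor with two or more levels")
    data = meta[usable].astype(str).copy()
    data["response"] = response.to_numpy(dtype=float)
    formula = "response ~ " + " * ".join(f"C({f})" for f in usable)
    fit = smf.ols(formula, data=data).fit()
    if fit.df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant response yields 0/0 F ratios
        table = anova_lm(fit, typ=1)
    table = table.rename(
        columns={"df": "df", "sum_sq": "sum_sq", "F": "F", "PR(>F)": "p"}
    )
    table["mean_sq"] = table["sum_sq"] / table["df"]
    table.index = [
        idx.replace("C(", "").replace(")", "") for idx in table.index
    ]
    # a constant response has no testable variation anywhere
    if np.allclose(response.to_numpy(dtype=float), response.iloc[0]):
        table.loc[table.index != "Residual", "F"] = 0.0
        table.loc[table.index != "Residual", "p"] = 1.0
    return table[["df", "sum_sq", "mean_sq", "F", "p"]]


def tukey_hsd(
    response: pd.Series, cells: pd.Series, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.Series]:
    """Tukey HSD over cells with a compact letter display.

    Uses the studentized-range distribution with the Tukey-Kramer
    correction for unequal cell sizes.  Letters are assigned from the
    maximal cliques of the non-significance graph, so cells sharing a
    letter are never significantly different at ``alpha``.
    """
    cells = cells.loc[response.index].astype(str)
    sizes = cells.value_counts()
    if len(sizes) < 2:
        raise ValueError("need at least two cells")
    if (sizes < 2).all():
        raise ValueError("all cells have n = 1: residual mean square undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hsd = pairwise_tukeyhsd(
            response.to_numpy(dtype=float), cells.to_numpy(), alpha=alpha
        )
    pairs = pd.DataFrame(
        hsd.summary().data[1:], columns=hsd.summary().data[0]
    )
    pairs = pairs.rename(columns={"p-adj": "p_adj"})
    pairs["p_adj"] = pd.to_numeric(pairs["p_adj"])

    # compact letter display: cover the non-significance graph by cliques
    levels = sorted(cells.unique())
    nonsig = nx.Graph()
    nonsig.add_nodes_from(levels)
    for _, row in pairs.iterrows():
        if row["p_adj"] > alpha:
            nonsig.add_edge(str(row["group1"]), str(row["group2"]))
    letters = {lvl: "" for lvl in levels}
    cliques = sorted(nx.find_cliques(nonsig), key=lambda c: sorted(c))
    alphabet = list(string.ascii_lowercase) + [
        a + b for a in string.ascii_lowercase for b in string.ascii_lowercase
    ]
    for letter, clique in zip(alphabet, cliques):
        for lvl in clique:
            letters[lvl] += letter
    letter_series = pd.Series(letters, name="letters").loc[levels]
    return pairs, letter_series
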