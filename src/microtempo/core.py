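"""Core-taxon delineation, the contribution statistic C, and temporal grouping.

Core ASVs are delineated from abundance-occupancy structure: an ASV is core
when it occurs in at least a threshold fraction (default 70%) of a habitat's
samples at one or more time points.  Their share of community turnover is
quantified by the contribution statistic

    C = BC_core / BC_all

per sample pair, where BC_core restricts the Bray-Curtis numerator to core
ASVs while keeping the full-community denominator, so C is in [0, 1] and the
contributions of disjoint ASV sets are additive.  Core ASVs are then grouped
by their standardized temporal profiles (Z-scores of mean relative abundance
over time points) with complete-linkage clustering on 1 - Pearson r.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import CountTable
from .normalize import relative_abundance

logger = logging.getLogger(__name__)


def abundance_occupancy(
    table: CountTable | pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Occupancy and mean relative abundance per ASV per time point.

    Occupancy is the fraction of a time point's samples in which the ASV has
    a nonzero count; abundance is the mean of its per-sample proportions.
    """
    counts = table.counts if isinstance(table, CountTable) else table
    meta = metadata.loc[counts.columns]
    props = relative_abundance(counts)
    rows = []
    for date, sub in meta.groupby("date"):
        samples = list(sub.index)
        if not samples:
            continue
        present = (counts[samples] > 0).mean(axis=1)
        mean_ra = props[samples].mean(axis=1)
        for asv in counts.index:
            rows.append(
                {
                    "asv_id": asv,
                    "time_point": pd.Timestamp(date),
                    "occupancy": float(present[asv]),
                    "mean_rel_abund": float(mean_ra[asv]),
                }
            )
    return pd.DataFrame(rows)


def select_core(occ: pd.DataFrame, threshold: float = 0.70) -> list[str]:
    """ASVs whose occupancy reaches ``threshold`` at >= 1 time point (inclusive)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    max_occ = occ.groupby("asv_id")["occupancy"].max()
    return sorted(max_occ.index[(max_occ >= threshold).to_numpy()])


def core_contribution(
    table: CountTable | pd.DataFrame,
    core: list[str],
    metadata: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, float]:
    """Contribution C = BC_core / BC_all of the core set, per sample pair.

    BC_core keeps the full-community denominator with a core-restricted
    numerator.  When metadata is given, each pair is classed as within- or
    among-season.  Pairs with BC_all = 0 (identical samples) are excluded
    with a warning.  Returns the per-pair table and the overall mean C.
    """
    counts = table.counts if isinstance(table, CountTable) else table
    missing = [a for a in core if a not in counts.index]
    if missing:
        raise ValueError(f"core ASV(s) not in table: {missing[:5]}")
    X = counts.to_numpy(dtype=float)
    core_mask = counts.index.isin(core)
    samples = list(counts.columns)
    season = (
        metadata.loc[samples, "season"].astype(str) if metadata is not None else None
    )
    rows = []
    skipped = 0
    for i, j in itertools.combinations(range(len(samples)), 2):
        x, y = X[:, i], X[:, j]
        denom = float((x + y).sum())
        num_all = float(np.abs(x - y).sum())
        if denom == 0 or num_all == 0:
            skipped += 1
            continue
        bc_all = num_all / denom
        bc_core = float(np.abs(x[core_mask] - y[core_mask]).sum()) / denom
        row = {
            "sample_1": samples[i],
            "sample_2": samples[j],
            "bc_all": bc_all,
            "bc_core": bc_core,
            "C": bc_core / bc_all,
        }
        if season is not None:
            row["pair_class"] = (
                "within_season"
                if season.iloc[i] == season.iloc[j]
                else "among_season"
            )
        rows.append(row)
    if skipped:
        logger.warning(
            "core_contribution: %d pair(s) with zero dissimilarity excluded", skipped
        )
    if not rows:
        raise ValueError("no sample pair has a defined contribution")
    pairs = pd.DataFrame(rows)
    return pairs, float(pairs["C"].mean())


@dataclass
class CoreGroupResult:
    """Core-group clustering output.

    ``z_profiles`` rows are per-ASV Z-scores (population SD) of mean
    relative abundance over time points; ``labels`` maps each clustered
    core ASV to its group; ``variance_explained`` holds the between-group
    fraction of profile sum of squares at each candidate k.
    """

    core_asv_ids: list[str]
    labels: pd.Series
    z_profiles: pd.DataFrame
    mean_profiles: pd.DataFrame
    group_profiles: pd.DataFrame
    k: int
    variance_explained: pd.Series
    linkage_matrix: np.ndarray
    excluded_constant: list[str] = field(default_factory=list)
    C: float | None = None


def temporal_profiles(
    table: CountTable | pd.DataFrame, metadata: pd.DataFrame, asvs: list[str]
) -> pd.DataFrame:
    """Mean relative abundance per ASV per time point (mean over samples)."""
    counts = table.counts if isinstance(table, CountTable) else table
    props = relative_abundance(counts)
    meta = metadata.loc[counts.columns]
    by_date = {
        pd.Timestamp(date): props.loc[asvs, list(sub.index)].mean(axis=1)
        for date, sub in meta.groupby("date")
    }
    profiles = pd.DataFrame(by_date)
    return profiles[sorted(profiles.columns)]


def zscore_profiles(profiles: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-ASV Z-scores over time points (mean 0, population SD 1).

    Constant profiles (zero temporal variance) cannot be standardized and
    are returned separately.
    """
    values = profiles.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=0)
    constant = sd == 0
    excluded = list(profiles.index[constant])
    if excluded:
        logger.warning(
            "zscore_profiles: %d constant profile(s) excluded: %s",
            len(excluded), excluded[:5],
        )
    kept = profiles.loc[~constant]
    z = (kept.to_numpy(dtype=float) - kept.to_numpy(dtype=float).mean(axis=1, keepdims=True))
    z = z / kept.to_numpy(dtype=float).std(axis=1, ddof=0, keepdims=True)
    return pd.DataFrame(z, index=kept.index, columns=profiles.columns), excluded


def _variance_explained(z: np.ndarray, labels: np.ndarray) -> float:
    grand = z.mean(axis=0, keepdims=True)
    total = float(((z - grand) ** 2).sum())
    if total <= 1e-12 * z.size:  # identical profiles up to float noise
        return 1.0
    within = 0.0
    for g in np.unique(labels):
        block = z[labels == g]
        within += float(((block - block.mean(axis=0, keepdims=True)) ** 2).sum())
    return 1.0 - within / total


def cluster_core_groups(
    table: CountTable | pd.DataFrame,
    metadata: pd.DataFrame,
    core: list[str],
    k_max: int = 8,
    gain_threshold: float = 0.05,
) -> CoreGroupResult:
    """Group core ASVs by temporal profile with complete-linkage clustering.

    Pipeline: mean relative abundance per time point -> per-ASV Z-score ->
    pairwise 1 - Pearson r -> complete linkage -> k selected as the
    smallest k whose gain in variance explained (between-group fraction of
    profile sum of squares) from k to k+1 falls below ``gain_threshold``.
    """
    if len(core) < 2:
        raise ValueError("need at least 2 core ASVs to cluster")
    profiles = temporal_profiles(table, metadata, core)
    z, excluded = zscore_profiles(profiles)
    if z.shape[0] < 2:
        raise ValueError("fewer than 2 core ASVs with non-constant profiles")
    zv = z.to_numpy(dtype=float)

    # 1 - Pearson r between Z-profiles; Z-scoring makes this a scaled
    # squared Euclidean distance, so values lie in [0, 2]
    corr = np.corrcoef(zv)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z_link = linkage(squareform(dist, checks=False), method="complete")

    k_cap = min(k_max, zv.shape[0])
    ve = {}
    labels_at = {}
    for k in range(1, k_cap + 1):
        labels = fcluster(Z_link, t=k, criterion="maxclust")
        labels_at[k] = labels
        ve[k] = _variance_explained(zv, labels)
    k_sel = k_cap
    for k in range(1, k_cap):
        if ve[k + 1] - ve[k] < gain_threshold:
            k_sel = k
            break
    labels = pd.Series(labels_at[k_sel], index=z.index, name="group")

    group_profiles = pd.DataFrame(
        {g: z.loc[labels.index[(labels == g).to_numpy()]].mean(axis=0)
         for g in sorted(labels.unique())}
    ).T
    group_profiles.index.name = "group"

    return CoreGroupResult(
        core_asv_ids=list(core),
        labels=labels,
        z_profiles=z,
        mean_profiles=profiles,
        group_profiles=group_profiles,
        k=k_sel,
        variance_explained=pd.Series(ve, name="variance_explained"),
        linkage_matrix=Z_link,
        excluded_constant=excluded,
    )
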