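"""Depth normalization: SRS subsampling, relative abundance, CLR transform."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountTable

logger = logging.getLogger(__name__)


@dataclass
class SubsampleConfig:
    """Target depth and tie-breaking seed for SRS subsampling."""

    c_min: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c_min < 1:
            raise ValueError("c_min must be >= 1")


def srs_subsample(table: CountTable, config: SubsampleConfig) -> CountTable:
    """Subsample every sample to exactly ``c_min`` reads by ranked scaling.

    Scaling with ranked subsampling (SRS): each sample's counts are scaled
    by ``c_min / total``; integer parts are kept, and the remaining units
    (``c_min`` minus the sum of integer parts) are assigned one each to the
    ASVs with the largest fractional parts, ties broken uniformly at random
    with the configured seed.  Unlike rarefaction this is deterministic up
    to tie-breaking and preserves rank order within a sample.

    Samples with fewer than ``c_min`` reads are dropped with a warning.
    """
    c_min = config.c_min
    totals = table.counts.sum(axis=0)
    keep = totals[totals >= c_min].index
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if dropped:
        logger.warning(
            "srs_subsample: dropping %d sample(s) below c_min=%d: %s",
            len(dropped), c_min, dropped,
        )
    if len(keep) == 0:
        raise ValueError(f"all samples fall below c_min={c_min}")

    rng = np.random.default_rng(config.seed)
    out = {}
    for s in keep:
        col = table.counts[s].to_numpy(dtype=float)
        scaled = col * c_min / col.sum()
        floor = np.floor(scaled)
        frac = scaled - floor
        remaining = int(round(c_min - floor.sum()))
        if remaining > 0:
            tiebreak = rng.random(len(col))
            order = np.lexsort((tiebreak, -frac))
            floor[order[:remaining]] += 1
        out[s] = floor.astype(np.int64)
    counts = pd.DataFrame(out, index=table.counts.index)
    counts = counts[list(keep)]
    return CountTable(counts, habitat=table.habitat, domain=table.domain)


def relative_abundance(table: CountTable | pd.DataFrame) -> pd.DataFrame:
    """Per-sample proportions; each column sums to 1."""
    counts = table.counts if isinstance(table, CountTable) else table
    colsums = counts.sum(axis=0)
    if (colsums <= 0).any():
        bad = colsums.index[(colsums <= 0).to_numpy()][0]
        raise ValueError(f"sample {bad!r} has zero total count")
    return counts / colsums


def clr_transform(
    table: CountTable | pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Centered log-ratio transform per sample: y_i = ln(x_i + pc) - mean_j ln(x_j + pc)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    counts = table.counts if isinstance(table, CountTable) else table
    logged = np.log(counts.to_numpy(dtype=float) + pseudocount)
    centered = logged - logged.mean(axis=0, keepdims=True)
    return pd.DataFrame(centered, index=counts.index, columns=counts.columns)
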