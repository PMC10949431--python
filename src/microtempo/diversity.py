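"""Hill-number alpha diversity and Bray-Curtis dissimilarity."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import CountTable, validate_distance_matrix


def hill_diversity(table: CountTable | pd.DataFrame, q: float) -> pd.Series:
    """Effective number of ASVs ^qD per sample.

    ^qD = (sum_i p_i^q)^(1/(1-q)) for q != 1; the q -> 1 limit is the
    exponential of Shannon entropy (computed directly for stability).
    q = 0 is richness, q = 1 weights ASVs by relative abundance, q = 2
    down-weights rare ASVs; ^qD is non-increasing in q.
    """
    if q < 0:
        raise ValueError("q must be nonnegative")
    counts = table.counts if isinstance(table, CountTable) else table
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[(totals <= 0).to_numpy()][0]
        raise ValueError(f"sample {bad!r} is empty")
    p = (counts / totals).to_numpy(dtype=float)
    if q == 0:
        values = (p > 0).sum(axis=0).astype(float)
    elif q == 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        values = np.exp(-plogp.sum(axis=0))
    else:
        values = np.power(np.power(p, q).sum(axis=0), 1.0 / (1.0 - q))
    return pd.Series(values, index=counts.columns, name=f"hill_q{q:g}")


def hill_diversity_table(
    table: CountTable | pd.DataFrame, orders=(0, 1, 2)
) -> pd.DataFrame:
    """Long-format diversity table: sample_id, q, value."""
    rows = []
    for q in orders:
        s = hill_diversity(table, q)
        for sid, v in s.items():
            rows.append({"sample_id": sid, "q": q, "value": v})
    return pd.DataFrame(rows)


def bray_curtis(table: CountTable | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples (columns).

    BC_xy = sum_i |x_i - y_i| / sum_i (x_i + y_i), bounded by [0, 1] for
    nonnegative abundances.  A pair of all-zero samples has an undefined
    denominator and is rejected.
    """
    counts = table.counts if isinstance(table, CountTable) else table
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    X = counts.to_numpy(dtype=float).T
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative abundances")
    zero = X.sum(axis=1) == 0
    if zero.sum() >= 2:
        bad = list(counts.columns[zero])
        raise ValueError(f"all-zero sample pair(s) undefined under Bray-Curtis: {bad}")
    d = squareform(pdist(X, metric="braycurtis"))
    out = pd.DataFrame(d, index=counts.columns, columns=counts.columns)
    validate_distance_matrix(out)
    return out
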