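"""Permutation-based multivariate inference on community distance matrices.

Implements multi-factor PERMANOVA with sequential (Type-I) sums of squares,
strata-constrained and exact-enumeration permutations; PERMDISP (homogeneity
of multivariate dispersions) with negative-eigenvalue bookkeeping; distance-
based redundancy analysis (dbRDA, the McArdle-Anderson direct approach); and
PCA of min-max-scaled climate windows for use as dbRDA constraints.

The partitioning works on the Gower-centered inner-product matrix
``G = -1/2 * C * D^2 * C`` where ``C = I - 11'/n``: sums of squares are
traces of projector-weighted G, so terms + residual = total exactly.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-9


# ---------------------------------------------------------------------------
# design-matrix machinery


def _factor_dummies(series: pd.Series) -> np.ndarray:
    """Full-rank treatment coding (first level dropped) of one factor."""
    levels = pd.unique(series)
    if len(levels) < 2:
        raise ValueError(f"factor {series.name!r} has fewer than 2 levels")
    dummies = pd.get_dummies(series.astype("category"), drop_first=True)
    return dummies.to_numpy(dtype=float)


def _term_columns(metadata: pd.DataFrame, term: str) -> np.ndarray:
    """Design columns for one term; 'a:b' builds the interaction product."""
    parts = term.split(":")
    blocks = []
    for part in parts:
        part = part.strip()
        if part not in metadata.columns:
            raise ValueError(f"term component {part!r} not in metadata")
        col = metadata[part]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 8:
            # continuous covariate: single centered column
            x = col.to_numpy(dtype=float)
            blocks.append((x - x.mean())[:, None])
        else:
            blocks.append(_factor_dummies(col.astype(str).rename(part)))
    X = blocks[0]
    for b in blocks[1:]:
        X = np.einsum("ij,ik->ijk", X, b).reshape(X.shape[0], -1)
    return X


def _orth_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal column basis of X (SVD with rank tolerance)."""
    if X.size == 0:
        return np.zeros((X.shape[0], 0))
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > _RANK_TOL * max(X.shape) * (s[0] if s.size else 1.0)).sum())
    return u[:, :rank]


def gower_center(d: np.ndarray) -> np.ndarray:
    """G = -1/2 * C * D^2 * C with C the centering operator."""
    d = np.asarray(d, dtype=float)
    a = -0.5 * d**2
    n = a.shape[0]
    row = a.mean(axis=0, keepdims=True)
    col = a.mean(axis=1, keepdims=True)
    return a - row - col + a.mean()


def _check_distance(d: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    if not d.index.equals(d.columns):
        raise ValueError("distance matrix row/column ids differ")
    missing = [s for s in d.index if s not in metadata.index]
    if missing:
        raise ValueError(f"samples {missing} missing from metadata")
    return metadata.loc[d.index]


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    """Sequential PERMANOVA table plus the permutation scheme used."""

    table: pd.DataFrame      # rows: terms, Residual, Total; cols df/SS/R2/F/p
    n_perm: int
    exact: bool

    def r2(self, term: str) -> float:
        return float(self.table.loc[term, "R2"])

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


def _strata_permutations_iter(strata_idx: list[np.ndarray]):
    """All permutations that shuffle only within strata (exact mode)."""
    per_stratum = [itertools.permutations(idx) for idx in strata_idx]
    n = sum(len(s) for s in strata_idx)
    for combo in itertools.product(*per_stratum):
        perm = np.empty(n, dtype=int)
        for idx, permuted in zip(strata_idx, combo):
            perm[idx] = permuted
        yield perm


def _random_permutation(rng, n, strata_idx):
    if strata_idx is None:
        return rng.permutation(n)
    perm = np.arange(n)
    for idx in strata_idx:
        perm[idx] = idx[rng.permutation(len(idx))]
    return perm


def permanova(
    d: pd.DataFrame,
    metadata: pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    strata: str | None = None,
    seed: int | None = None,
    permutations: str = "monte_carlo",
) -> PermanovaResult:
    """Sequential (Type-I) PERMANOVA of a distance matrix on ordered terms.

    ``terms`` are metadata factor names, interactions written ``"a:b"``;
    sums of squares are sequential in the given order, pseudo-F uses the
    residual mean square, and p-values follow the ``(1 + #{F* >= F}) /
    (1 + n_perm)`` convention.  With ``strata``, permutations shuffle
    samples only within levels of that factor (repeated-measures design).
    ``permutations="exact"`` enumerates every admissible permutation and
    reports ``#{F* >= F} / N`` (the identity is included).
    """
    metadata = _check_distance(d, metadata)
    n = d.shape[0]
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    strata_idx = None
    if strata is not None:
        groups = metadata[strata].astype(str)
        strata_idx = [
            np.flatnonzero((groups == g).to_numpy()) for g in pd.unique(groups)
        ]
        if all(len(idx) == 1 for idx in strata_idx):
            raise ValueError("strata are finer than samples: nothing to permute")

    G = gower_center(d.to_numpy(dtype=float))
    ss_total = float(np.trace(G))

    # cumulative orthonormal bases -> per-term projector differences
    ones = np.ones((n, 1)) / math.sqrt(n)
    basis = ones
    projectors, dfs = [], []
    for term in terms:
        X = _term_columns(metadata, term)
        X = X - basis @ (basis.T @ X)          # residualize on previous terms
        Q = _orth_basis(X)
        if Q.shape[1] == 0:
            raise ValueError(f"term {term!r} adds no estimable contrast")
        projectors.append(Q @ Q.T)
        dfs.append(Q.shape[1])
        basis = np.hstack([basis, Q])
    H_model = basis @ basis.T - ones @ ones.T
    df_res = n - 1 - sum(dfs)
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def term_stats(Gp):
        ss = np.array([float(np.sum(P * Gp)) for P in projectors])
        ss_res = float(np.trace(Gp)) - float(np.sum(H_model * Gp))
        f = (ss / np.array(dfs)) / (ss_res / df_res)
        return ss, ss_res, f

    ss_obs, ss_res_obs, f_obs = term_stats(G)

    exact = permutations == "exact"
    if exact:
        if strata_idx is None:
            total = math.factorial(n)
            perm_iter = itertools.permutations(range(n))
        else:
            total = math.prod(math.factorial(len(idx)) for idx in strata_idx)
            perm_iter = _strata_permutations_iter(strata_idx)
        if total > 2_000_000:
            raise ValueError(f"exact enumeration infeasible: {total} permutations")
        count = np.zeros(len(terms))
        n_done = 0
        for perm in perm_iter:
            perm = np.asarray(perm, dtype=int)
            Gp = G[np.ix_(perm, perm)]
            _, _, f = term_stats(Gp)
            count += f >= f_obs - 1e-12
            n_done += 1
        pvals = count / n_done
        n_used = n_done
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(terms))
        for _ in range(n_perm):
            perm = _random_permutation(rng, n, strata_idx)
            Gp = G[np.ix_(perm, perm)]
            _, _, f = term_stats(Gp)
            count += f >= f_obs - 1e-12
        pvals = (1.0 + count) / (1.0 + n_perm)
        n_used = n_perm

    rows = []
    for term, df, ss, f, p in zip(terms, dfs, ss_obs, f_obs, pvals):
        rows.append(
            {"term": term, "df": df, "SS": ss, "R2": ss / ss_total, "F": f, "p": p}
        )
    rows.append(
        {
            "term": "Residual",
            "df": df_res,
            "SS": ss_res_obs,
            "R2": ss_res_obs / ss_total,
            "F": np.nan,
            "p": np.nan,
        }
    )
    rows.append(
        {"term": "Total", "df": n - 1, "SS": ss_total, "R2": 1.0, "F": np.nan, "p": np.nan}
    )
    table = pd.DataFrame(rows).set_index("term")
    return PermanovaResult(table=table, n_perm=n_used, exact=exact)


# ---------------------------------------------------------------------------
# PERMDISP


@dataclass
class DispersionResult:
    """Distances to group centroids and the ANOVA test of their homogeneity."""

    distances: pd.Series       # per-sample distance to its group centroid
    group_means: pd.Series
    F: float
    p: float


def _pcoa_coords(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate embedding split into real and imaginary parts.

    Negative eigenvalues of the Gower-centered matrix (non-Euclidean
    distances such as Bray-Curtis) yield imaginary axes; both parts are
    returned so squared distances can be corrected as real^2 - imag^2.
    """
    G = gower_center(d)
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-10 * max(1.0, float(np.abs(eigval).max()))
    pos = eigval > tol
    neg = eigval < -tol
    real = eigvec[:, pos] * np.sqrt(eigval[pos])
    imag = eigvec[:, neg] * np.sqrt(-eigval[neg])
    return real, imag


def permdisp(d: pd.DataFrame, group: pd.Series) -> DispersionResult:
    """PERMDISP: distances to group centroids in PCoA space, one-way ANOVA.

    Squared distances combine the real and imaginary embeddings as
    ``z^2 = max(d_real^2 - d_imag^2, 0)``; the parametric ANOVA F/p on the
    per-sample distances tests homogeneity of multivariate dispersion.
    """
    group = group.loc[d.index].astype(str)
    counts = group.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        bad = counts.index[(counts < 2).to_numpy()][0]
        raise ValueError(f"group {bad!r} has fewer than 2 samples")

    real, imag = _pcoa_coords(d.to_numpy(dtype=float))
    z = np.zeros(len(group))
    for g in counts.index:
        mask = (group == g).to_numpy()
        c_real = real[mask].mean(axis=0)
        c_imag = imag[mask].mean(axis=0) if imag.shape[1] else np.zeros(0)
        d2_real = ((real[mask] - c_real) ** 2).sum(axis=1)
        d2_imag = (
            ((imag[mask] - c_imag) ** 2).sum(axis=1) if imag.shape[1] else 0.0
        )
        z[mask] = np.sqrt(np.clip(d2_real - d2_imag, 0.0, None))

    samples = [z[(group == g).to_numpy()] for g in counts.index]
    F, p = stats.f_oneway(*samples)
    if np.isnan(F):  # all distances identical
        F, p = 0.0, 1.0
    means = pd.Series({g: float(s.mean()) for g, s in zip(counts.index, samples)})
    return DispersionResult(
        distances=pd.Series(z, index=d.index, name="dist_to_centroid"),
        group_means=means,
        F=float(F),
        p=float(p),
    )


# ---------------------------------------------------------------------------
# dbRDA


@dataclass
class DbrdaResult:
    """Constrained ordination of a distance matrix (McArdle-Anderson dbRDA)."""

    site_scores: pd.DataFrame      # samples x constrained axes
    eigenvalues: np.ndarray        # per constrained axis
    term_table: pd.DataFrame       # per-term df, SS, variance fraction, F, p
    constrained_inertia: float
    unconstrained_inertia: float
    total_inertia: float
    negative_inertia: float


def dbrda(
    d: pd.DataFrame,
    constraints: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> DbrdaResult:
    """Distance-based redundancy analysis with marginal permutation tests.

    Works directly on the Gower-centered matrix: constrained inertia is
    ``trace(H G H)`` for the hat matrix ``H`` of the (centered) constraint
    design; ordination axes are eigenvectors of ``H G H``.  Each term's
    marginal test removes it from the full design.  For Euclidean input
    this reduces exactly to classical redundancy analysis.
    """
    constraints = _check_distance(d, constraints)
    n = d.shape[0]
    G = gower_center(d.to_numpy(dtype=float))
    total = float(np.trace(G))

    term_blocks: dict[str, np.ndarray] = {}
    for col in constraints.columns:
        series = constraints[col]
        if pd.api.types.is_numeric_dtype(series):
            x = series.to_numpy(dtype=float)
            if np.ptp(x) == 0:
                raise ValueError(f"constraint {col!r} is constant")
            term_blocks[col] = (x - x.mean())[:, None]
        else:
            term_blocks[col] = _factor_dummies(series.astype(str).rename(col))
    terms = list(term_blocks)

    def hat(blocks: list[np.ndarray]) -> tuple[np.ndarray, int]:
        if not blocks:
            return np.zeros((n, n)), 0
        X = np.hstack(blocks)
        X = X - X.mean(axis=0, keepdims=True)
        Q = _orth_basis(X)
        if Q.shape[1] < sum(b.shape[1] for b in blocks):
            logger.warning("dbrda: design is rank deficient; aliased columns dropped")
        return Q @ Q.T, Q.shape[1]

    H_full, df_full = hat(list(term_blocks.values()))
    constrained = float(np.sum(H_full * G))
    residual = total - constrained
    df_res = n - 1 - df_full
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    eigval_G = np.linalg.eigvalsh(G)
    negative = float(eigval_G[eigval_G < 0].sum())
    if abs(negative) > 0.05 * abs(total):
        warnings.warn(
            f"dbrda: negative eigenvalue mass {negative:.4g} exceeds 5% of "
            f"total inertia {total:.4g}",
            stacklevel=2,
        )

    # ordination axes from H G H
    HGH = H_full @ G @ H_full
    HGH = (HGH + HGH.T) / 2
    eigval, eigvec = np.linalg.eigh(HGH)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > 1e-10 * max(1.0, float(np.abs(eigval).max()))
    axes = eigvec[:, keep] * np.sqrt(eigval[keep])
    site_scores = pd.DataFrame(
        axes,
        index=d.index,
        columns=[f"dbRDA{i + 1}" for i in range(int(keep.sum()))],
    )

    # marginal permutation tests per term
    rng = np.random.default_rng(seed)
    rows = []
    marginal = {}
    for term in terms:
        H_rest, _ = hat([term_blocks[t] for t in terms if t != term])
        P = H_full - H_rest
        df_t = df_full - int(round(np.trace(H_rest)))
        ss_t = float(np.sum(P * G))
        f_obs = (ss_t / max(df_t, 1)) / (residual / df_res)
        marginal[term] = (P, df_t, f_obs)
        rows.append(
            {
                "term": term,
                "df": df_t,
                "SS": ss_t,
                "fraction": ss_t / total,
                "F": f_obs,
                "p": np.nan,
            }
        )
    counts = {t: 0 for t in terms}
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        res_p = float(np.trace(Gp)) - float(np.sum(H_full * Gp))
        for term in terms:
            P, df_t, f_obs = marginal[term]
            f_p = (float(np.sum(P * Gp)) / max(df_t, 1)) / (res_p / df_res)
            if f_p >= f_obs - 1e-12:
                counts[term] += 1
    for row in rows:
        row["p"] = (1.0 + counts[row["term"]]) / (1.0 + n_perm)
    term_table = pd.DataFrame(rows).set_index("term")

    return DbrdaResult(
        site_scores=site_scores,
        eigenvalues=eigval[keep],
        term_table=term_table,
        constrained_inertia=constrained,
        unconstrained_inertia=residual,
        total_inertia=total,
        negative_inertia=negative,
    )


# ---------------------------------------------------------------------------
# climate PCA


@dataclass
class PcaResult:
    """PCA of min-max-scaled climate windows preceding each sample date."""

    loadings: pd.DataFrame         # variables x components
    scores: pd.DataFrame           # daily rows x components (+ window date column)
    variance_explained: np.ndarray
    scaling: pd.DataFrame          # per-variable min/max used
    date_scores: pd.DataFrame      # per-sample-date mean scores (PC1, PC2, ...)


def climate_windows(
    climate: pd.DataFrame, sample_dates, window_days: int = 7
) -> pd.DataFrame:
    """Daily climate rows in the ``window_days`` days before each sample date.

    The window for date t covers t-window_days .. t-1; a window reaching
    before climate coverage is an error.
    """
    from .io import CLIMATE_VARIABLES

    climate = climate.sort_values("date")
    available = set(climate["date"])
    out = []
    for sd in sample_dates:
        sd = pd.Timestamp(sd)
        days = [sd - pd.Timedelta(days=k) for k in range(window_days, 0, -1)]
        missing = [day for day in days if day not in available]
        if missing:
            raise ValueError(
                f"climate does not cover window before {sd.date()} "
                f"(missing {missing[0].date()})"
            )
        block = climate[climate["date"].isin(days)].copy()
        block["sample_date"] = sd
        out.append(block)
    cols = ["sample_date", "date", *CLIMATE_VARIABLES]
    return pd.concat(out, ignore_index=True)[cols]


def minmax_scale_columns(df: pd.DataFrame, columns) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scale each named column to [0, 1]; constant columns map to 0."""
    scaled = df.copy()
    record = []
    for col in columns:
        lo, hi = float(df[col].min()), float(df[col].max())
        scaled[col] = 0.0 if hi == lo else (df[col] - lo) / (hi - lo)
        record.append({"variable": col, "min": lo, "max": hi})
    return scaled, pd.DataFrame(record).set_index("variable")


def climate_pca(
    climate: pd.DataFrame, sample_dates, window_days: int = 7
) -> PcaResult:
    """PCA of the daily climate records in each pre-sample-date window.

    Variables are min-max scaled to [0, 1] across all retained rows, then
    decomposed on the covariance matrix (the scaling already homogenizes
    ranges).  Per-sample-date mean scores (PC1, PC2) are exposed for use
    as constraining variables in dbRDA.
    """
    from .io import CLIMATE_VARIABLES

    windows = climate_windows(climate, sample_dates, window_days)
    scaled, record = minmax_scale_columns(windows, CLIMATE_VARIABLES)
    X = scaled[list(CLIMATE_VARIABLES)].to_numpy(dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    var_frac = var / var.sum() if var.sum() > 0 else var
    pcs = [f"PC{i + 1}" for i in range(len(s))]
    scores = pd.DataFrame(u * s, columns=pcs)
    scores.insert(0, "sample_date", windows["sample_date"].to_numpy())
    scores.insert(1, "date", windows["date"].to_numpy())
    loadings = pd.DataFrame(vt.T, index=list(CLIMATE_VARIABLES), columns=pcs)
    date_scores = scores.groupby("sample_date")[pcs].mean()
    return PcaResult(
        loadings=loadings,
        scores=scores,
        variance_explained=var_frac,
        scaling=record,
        date_scores=date_scores,
    )
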