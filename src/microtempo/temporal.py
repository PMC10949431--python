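"""Dissimilarity-time decay regression and environmental-dissimilarity diagnostics.

Directional change in community composition shows up as a positive slope of
Bray-Curtis dissimilarity against elapsed time between sample dates, whereas
purely seasonal communities oscillate with no net trend.  Points are genotype
means between date pairs, so pseudo-replication from repeated sampling of
clonal individuals is absorbed before the regression; a random-intercept
(per-genotype) variant is fitted alongside as a robustness check.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .multivariate import climate_windows, minmax_scale_columns

logger = logging.getLogger(__name__)


def build_decay_table(d: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Mean cross-date dissimilarity per genotype and unordered date pair.

    For every genotype and every pair of distinct sample dates, averages the
    distance over all cross-date sample pairs of that genotype.  Within-date
    pairs and cross-genotype pairs never contribute.  Genotypes observed at a
    single date are excluded with a warning.
    """
    meta = metadata.loc[d.index]
    rows = []
    for genotype, sub in meta.groupby("genotype"):
        dates = sorted(pd.unique(sub["date"]))
        if len(dates) < 2:
            logger.warning(
                "build_decay_table: genotype %r has a single date; excluded", genotype
            )
            continue
        for t1, t2 in itertools.combinations(dates, 2):
            s1 = sub.index[(sub["date"] == t1).to_numpy()]
            s2 = sub.index[(sub["date"] == t2).to_numpy()]
            block = d.loc[s1, s2].to_numpy(dtype=float)
            rows.append(
                {
                    "genotype": genotype,
                    "t1": pd.Timestamp(t1),
                    "t2": pd.Timestamp(t2),
                    "delta_t": abs((pd.Timestamp(t2) - pd.Timestamp(t1)).days),
                    "mean_bc": float(block.mean()),
                }
            )
    if not rows:
        raise ValueError("no genotype has two or more dates")
    return pd.DataFrame(rows)


@dataclass
class TimeDecayResult:
    """Slope of dissimilarity on elapsed time, per 365 days.

    ``slope`` is the OLS estimate; the primary ``ci_low/ci_high/p`` use a
    genotype-clustered covariance, because rows of the decay table reuse
    the same samples across date pairs within a genotype and the classical
    iid interval is too narrow for that structure.  The classical t-based
    interval is kept in ``ols_*``; ``lme_*`` fields hold the
    random-intercept (per genotype) maximum-likelihood fit of the same
    fixed effect, and ``slope_per_day`` is ``slope / 365``.
    """

    slope: float
    ci_low: float
    ci_high: float
    intercept: float
    r2_adj: float
    p: float
    slope_per_day: float
    ols_ci_low: float
    ols_ci_high: float
    ols_p: float
    lme_slope: float | None = None
    lme_ci_low: float | None = None
    lme_ci_high: float | None = None
    lme_p: float | None = None

    def ci_covers(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def fit_time_decay(table: pd.DataFrame, random_intercept: bool = True) -> TimeDecayResult:
    """OLS of mean dissimilarity on elapsed time (slope per 365 days).

    The reported CI and p are genotype-cluster robust when the table has
    two or more genotypes (falling back to the classical interval
    otherwise).  Optionally also fits a linear mixed-effects model with a
    random intercept per genotype (ML), reporting the same fixed effect.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows to fit a decay regression")
    dt_years = table["delta_t"].to_numpy(dtype=float) / 365.0
    if np.ptp(dt_years) == 0:
        raise ValueError("delta_t is constant; slope is unidentifiable")
    y = table["mean_bc"].to_numpy(dtype=float)
    X = sm.add_constant(dt_years)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    n_geno = table["genotype"].nunique() if "genotype" in table.columns else 1
    if n_geno >= 2:
        robust = sm.OLS(y, X).fit(
            cov_type="cluster", cov_kwds={"groups": table["genotype"]}
        )
        rci = robust.conf_int(alpha=0.05)
        primary = (float(rci[1, 0]), float(rci[1, 1]), float(robust.pvalues[1]))
    else:
        primary = (float(ci[1, 0]), float(ci[1, 1]), float(fit.pvalues[1]))
    result = TimeDecayResult(
        slope=float(fit.params[1]),
        ci_low=primary[0],
        ci_high=primary[1],
        intercept=float(fit.params[0]),
        r2_adj=float(fit.rsquared_adj),
        p=primary[2],
        slope_per_day=float(fit.params[1]) / 365.0,
        ols_ci_low=float(ci[1, 0]),
        ols_ci_high=float(ci[1, 1]),
        ols_p=float(fit.pvalues[1]),
    )
    if random_intercept and table["genotype"].nunique() >= 2:
        data = table.assign(dt_years=dt_years)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lme = smf.mixedlm(
                "mean_bc ~ dt_years", data, groups=data["genotype"]
            ).fit(reml=False)
        lme_ci = lme.conf_int().loc["dt_years"]
        result.lme_slope = float(lme.params["dt_years"])
        result.lme_ci_low = float(lme_ci[0])
        result.lme_ci_high = float(lme_ci[1])
        result.lme_p = float(lme.pvalues["dt_years"])
    return result


def env_dissimilarity_vs_time(
    climate: pd.DataFrame, sample_dates, window_days: int = 7
) -> tuple[pd.DataFrame, float]:
    """Euclidean distance of scaled window-mean climate for every date pair.

    Window means (the ``window_days`` days before each sample date) are
    min-max scaled per variable, then the Euclidean distance between every
    pair of sample dates is tabulated against elapsed time.  The returned
    diagnostic is the Pearson correlation between distance and
    ``|sin(pi * delta_t / 365.25)|`` — near 1 when environmental
    dissimilarity oscillates annually instead of accumulating.
    """
    from .io import CLIMATE_VARIABLES

    windows = climate_windows(climate, sample_dates, window_days)
    means = windows.groupby("sample_date")[list(CLIMATE_VARIABLES)].mean()
    scaled, _ = minmax_scale_columns(means, CLIMATE_VARIABLES)
    X = scaled.to_numpy(dtype=float)
    dates = list(scaled.index)
    rows = []
    for i, j in itertools.combinations(range(len(dates)), 2):
        delta = abs((dates[j] - dates[i]).days)
        dist = float(np.linalg.norm(X[i] - X[j]))
        rows.append(
            {"t1": dates[i], "t2": dates[j], "delta_t": delta, "distance": dist}
        )
    table = pd.DataFrame(rows)
    osc = np.abs(np.sin(np.pi * table["delta_t"].to_numpy() / 365.25))
    if np.ptp(table["distance"].to_numpy()) == 0 or np.ptp(osc) == 0:
        diagnostic = 0.0
    else:
        diagnostic = float(stats.pearsonr(table["distance"], osc)[0])
    return table, diagnostic
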