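"""Planted-truth recovery and calibration experiments.

Each function runs a self-contained simulation experiment at desk scale:
generate data with known structure, run the corresponding analysis stage,
and measure how well the planted truth is recovered.  They back both the
acceptance checks and the reproducibility script, and are convenient for
exploring how the methods behave as conditions change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import cluster_core_groups
from .diversity import bray_curtis
from .io import CountTable
from .multivariate import dbrda, permanova
from .network import NetworkConfig, estimate_network, identify_hubs, network_from_edges
from .normalize import SubsampleConfig, srs_subsample
from .synthetic import SynthConfig, expected_decay_slope, generate_dataset
from .temporal import build_decay_table, fit_time_decay


def _subsampled_bc(table, metadata, seed=0):
    c_min = int(table.counts.sum(axis=0).min())
    sub = srs_subsample(table, SubsampleConfig(c_min=c_min, seed=seed))
    return bray_curtis(sub), metadata.loc[sub.sample_ids]


def drift_slope_recovery(
    n_seeds: int = 20, seed0: int = 100, drift_frac: float = 0.3, n_mc: int = 400
) -> pd.DataFrame:
    """Planted-drift recovery: does the decay CI cover the model-implied slope?

    Seasonality is off so the only temporal signal is directional drift;
    the planted truth per seed comes from the Monte-Carlo enumeration in
    :func:`microtempo.synthetic.expected_decay_slope`.
    """
    rows = []
    for k in range(n_seeds):
        cfg = SynthConfig(
            n_asvs=150, seed=seed0 + k, seasonal_frac=0.0, season_amplitude=0.0,
            drift_frac=drift_frac, interaction_sd=0.0,
        )
        table, metadata, _, _ = generate_dataset(cfg)
        truth_slope = expected_decay_slope(cfg, n_mc=n_mc) if drift_frac > 0 else 0.0
        d, meta = _subsampled_bc(table, metadata)
        fit = fit_time_decay(build_decay_table(d, meta))
        rows.append(
            {
                "seed": cfg.seed,
                "truth": truth_slope,
                "slope": fit.slope,
                "ci_low": fit.ci_low,
                "ci_high": fit.ci_high,
                "covered": fit.ci_covers(truth_slope),
                "p": fit.p,
            }
        )
    return pd.DataFrame(rows)


def core_group_recovery(n_seeds: int = 10, seed0: int = 0) -> pd.DataFrame:
    """Two planted temporal profile families (cos vs -cos): ARI vs truth."""
    from sklearn.metrics import adjusted_rand_score

    rows = []
    for k in range(n_seeds):
        cfg = SynthConfig(
            n_asvs=20, seed=seed0 + k, seasonal_frac=1.0, season_amplitude=2.0,
            drift_frac=0.0, interaction_sd=0.0, genotype_sd=0.0, noise_sd=0.1,
            seasonal_phase_choices=(0.0, 182.625), base_sd=0.3,
        )
        table, metadata, _, truth = generate_dataset(cfg)
        res = cluster_core_groups(table, metadata, list(table.counts.index))
        planted = (truth.asv.loc[res.labels.index, "phase"] == 0.0).astype(int)
        rows.append(
            {
                "seed": cfg.seed,
                "k": res.k,
                "ari": adjusted_rand_score(planted, res.labels.to_numpy()),
            }
        )
    return pd.DataFrame(rows)


def network_chain_recovery(n_seeds: int = 10, seed0: int = 0) -> pd.DataFrame:
    """Planted 30-node chain precision structure: edge-recovery F1 by MB+StARS."""
    rows = []
    edges = tuple((i, i + 1) for i in range(29))
    for k in range(n_seeds):
        cfg = SynthConfig(
            n_asvs=30, seed=seed0 + k, network_edges=edges,
            seasonal_frac=0.0, season_amplitude=0.0, drift_frac=0.0,
            interaction_sd=0.0, genotype_sd=0.0, noise_sd=1.0, base_sd=1.0,
            reps_min=3, reps_max=3,
        )
        table, _, _, truth = generate_dataset(cfg)
        bact = CountTable(table.counts.iloc[:15], "rhizosphere", "bacteria_archaea")
        fung = CountTable(table.counts.iloc[15:], "rhizosphere", "fungi")
        net = estimate_network(bact, fung, NetworkConfig(seed=seed0 + k))
        est = {frozenset(e) for e in net.graph.edges}
        tru = {frozenset(e) for e in truth.edges}
        tp = len(est & tru)
        precision = tp / len(est) if est else 0.0
        recall = tp / len(tru)
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        rows.append(
            {"seed": cfg.seed, "n_edges": len(est), "precision": precision,
             "recall": recall, "f1": f1}
        )
    return pd.DataFrame(rows)


def permanova_null_calibration(
    n_rep: int = 500, n_perm: int = 199, n: int = 20, seed: int = 42
) -> float:
    """Rejection rate at alpha=0.05 when group labels carry no information."""
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    rejections = 0
    for _ in range(n_rep):
        X = rng.random((n, 6))
        d = pd.DataFrame(squareform(pdist(X)), index=ids, columns=ids)
        meta = pd.DataFrame(
            {"g": rng.permutation(["a"] * (n // 2) + ["b"] * (n - n // 2))}, index=ids
        )
        res = permanova(d, meta, ["g"], n_perm=n_perm, seed=int(rng.integers(2**31)))
        rejections += res.p("g") <= 0.05
    return rejections / n_rep


def dbrda_null_calibration(
    n_rep: int = 500, n_perm: int = 199, n: int = 20, seed: int = 43
) -> float:
    """Rejection rate at alpha=0.05 for a constraint orthogonal to the data."""
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    rejections = 0
    for _ in range(n_rep):
        X = rng.random((n, 6))
        d = pd.DataFrame(squareform(pdist(X)), index=ids, columns=ids)
        constraints = pd.DataFrame({"x": rng.random(n)}, index=ids)
        res = dbrda(d, constraints, n_perm=n_perm, seed=int(rng.integers(2**31)))
        rejections += res.term_table.loc["x", "p"] <= 0.05
    return rejections / n_rep


def star_hub_recovery() -> bool:
    """A star-graph center that is core and abundant must pass every hub filter."""
    edges = [("hub", f"leaf{i}") for i in range(5)]
    net = network_from_edges(edges)
    counts = pd.DataFrame(
        {"s1": [1000] + [200] * 5, "s2": [900] + [210] * 5},
        index=["hub"] + [f"leaf{i}" for i in range(5)],
    )
    hubs = identify_hubs(
        net, CountTable(counts), core=["hub"] + [f"leaf{i}" for i in range(5)]
    )
    return list(hubs.index) == ["hub"]
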