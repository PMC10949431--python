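"""Cross-domain co-occurrence network estimation and hub-ASV classification.

Networks are estimated from non-subsampled count tables: a prevalence
filter removes rare ASVs, the two domain tables (bacteria/archaea and
fungi) are CLR-transformed per domain and concatenated over shared
samples, and a sparse conditional-dependence graph is fitted by
Meinshausen-Buhlmann neighborhood selection — one lasso regression of
each node's CLR profile on all others over a geometric penalty grid.
The penalty is chosen by StARS (Stability Approach to Regularization
Selection): edge-selection frequencies over repeated subsamples give a
total instability D(lambda), and the largest penalty whose monotonized
instability stays below a bound beta is kept.

Hub ASVs are nodes at or above the 90th percentile of both degree and
betweenness centrality that also belong to the core community and account
for at least 0.1% of sequences in their habitat.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path

from .io import CountTable
from .normalize import clr_transform, relative_abundance

logger = logging.getLogger(__name__)


@dataclass
class NetworkConfig:
    """Estimation settings: penalty grid, StARS bound, symmetrization rule."""

    prevalence_min: float = 0.20
    n_lambda: int = 20
    lambda_min_ratio: float = 0.01
    stars_beta: float = 0.05
    n_subsamples: int = 20
    symmetrization: str = "OR"
    clr_pseudocount: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence_min <= 1.0:
            raise ValueError("prevalence_min must lie in [0, 1]")
        if not 0.0 < self.stars_beta < 1.0:
            raise ValueError("stars_beta must lie in (0, 1)")
        if self.n_lambda < 1:
            raise ValueError("empty lambda grid")
        if self.symmetrization not in ("OR", "AND"):
            raise ValueError("symmetrization must be 'OR' or 'AND'")


@dataclass
class NetworkResult:
    """Selected graph with centralities and per-edge stability."""

    nodes: pd.DataFrame           # id-indexed: domain, degree, betweenness
    edges: pd.DataFrame           # node_1, node_2, sign, stability
    graph: nx.Graph
    lambda_selected: float | None
    lambda_path: np.ndarray | None
    instability: np.ndarray | None


def prevalence_filter(table: CountTable, min_prev: float = 0.20) -> CountTable:
    """Drop ASVs present in fewer than ``min_prev`` of samples (strict <)."""
    if not 0.0 <= min_prev <= 1.0:
        raise ValueError("min_prev must lie in [0, 1]")
    prevalence = (table.counts > 0).mean(axis=1)
    keep = prevalence[(prevalence >= min_prev).to_numpy()].index
    if len(keep) == 0:
        raise ValueError(f"prevalence filter at {min_prev} removed every ASV")
    return CountTable(table.counts.loc[keep], table.habitat, table.domain)


def _neighborhoods(X: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """MB selection: boolean (n_lambda, p, p) with [l, j, k] = k selected for j.

    Columns of X must be standardized; the lasso objective is
    ``1/(2n)||y - Xb||^2 + lambda ||b||_1`` so the grid is shared across
    nodes and comparable to correlations.
    """
    n, p = X.shape
    selected = np.zeros((len(lambdas), p, p), dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for j in range(p):
            others = np.delete(np.arange(p), j)
            # lasso_path expects alphas in decreasing order
            _, coefs, _ = lasso_path(
                X[:, others], X[:, j], alphas=lambdas, max_iter=2000, tol=1e-5
            )
            nz = coefs != 0  # (p-1, n_lambda)
            for li in range(len(lambdas)):
                selected[li, j, others] = nz[:, li]
    return selected


def _neighborhood_coefs(X: np.ndarray, lam: float) -> np.ndarray:
    """Lasso coefficients at one penalty: [j, k] = weight of k in j's regression."""
    n, p = X.shape
    coefs = np.zeros((p, p))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for j in range(p):
            others = np.delete(np.arange(p), j)
            _, c, _ = lasso_path(
                X[:, others], X[:, j], alphas=[lam], max_iter=2000, tol=1e-5
            )
            coefs[j, others] = c[:, 0]
    return coefs


def _symmetrize(selected_j: np.ndarray, rule: str) -> np.ndarray:
    return (
        selected_j | selected_j.T if rule == "OR" else selected_j & selected_j.T
    )


def estimate_network(
    bacteria: CountTable,
    fungi: CountTable,
    config: NetworkConfig | None = None,
) -> NetworkResult:
    """Estimate a cross-domain co-occurrence network (MB + StARS).

    Both tables are prevalence-filtered, CLR-transformed per domain and
    joined over their shared samples.  StARS draws ``n_subsamples``
    subsamples of size ``floor(10*sqrt(n))`` (capped at n-1) without
    replacement, computes per-edge selection frequencies theta over the
    penalty grid, and selects the largest penalty whose running-supremum
    instability ``D = mean(2*theta*(1-theta))`` is at most ``beta``.
    """
    config = config or NetworkConfig()
    shared = [s for s in bacteria.sample_ids if s in set(fungi.sample_ids)]
    if len(shared) < 10:
        raise ValueError(
            f"only {len(shared)} shared samples; StARS subsampling undefined below 10"
        )
    parts = []
    domains = {}
    for tbl in (bacteria, fungi):
        filtered = prevalence_filter(tbl.subset_samples(shared), config.prevalence_min)
        clr = clr_transform(filtered, config.clr_pseudocount)
        parts.append(clr)
        for asv in clr.index:
            domains[asv] = tbl.domain
    data = pd.concat(parts)
    if data.index.duplicated().any():
        raise ValueError("ASV identifiers collide between the two domain tables")
    node_ids = list(data.index)
    p = len(node_ids)
    if p < 2:
        raise ValueError("fewer than 2 nodes after filtering")

    X = data.to_numpy(dtype=float).T  # samples x nodes
    X = X - X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    X = X / sd
    n = X.shape[0]

    corr = (X.T @ X) / n
    lam_max = float(np.max(np.abs(corr - np.diag(np.diag(corr)))))
    if lam_max <= 0:
        raise ValueError("data carry no pairwise association; lambda grid empty")
    lambdas = lam_max * np.power(
        config.lambda_min_ratio, np.linspace(0.0, 1.0, config.n_lambda)
    )  # decreasing

    rng = np.random.default_rng(config.seed)
    m = min(int(math.floor(10.0 * math.sqrt(n))), n - 1)
    freq = np.zeros((len(lambdas), p, p))
    for _ in range(config.n_subsamples):
        idx = rng.choice(n, size=m, replace=False)
        sel = _neighborhoods(X[idx], lambdas)
        for li in range(len(lambdas)):
            freq[li] += _symmetrize(sel[li], config.symmetrization)
    theta = freq / config.n_subsamples

    iu = np.triu_indices(p, k=1)
    instability = np.array(
        [float(np.mean(2.0 * t[iu] * (1.0 - t[iu]))) for t in theta]
    )
    sup_instability = np.maximum.accumulate(instability)  # largest lambda first
    admissible = np.flatnonzero(sup_instability <= config.stars_beta)
    li_sel = int(admissible[-1]) if admissible.size else 0
    lam_sel = float(lambdas[li_sel])

    coef_full = _neighborhood_coefs(X, lam_sel)
    sel_full = coef_full != 0
    adjacency = _symmetrize(sel_full, config.symmetrization)
    np.fill_diagonal(adjacency, False)

    # edge sign from the lasso coefficients (falling back to the CLR
    # correlation when the two directed coefficients cancel exactly)
    coef_sym = coef_full + coef_full.T
    sign = np.where(coef_sym != 0, np.sign(coef_sym), np.sign(corr))

    graph = nx.Graph()
    graph.add_nodes_from(node_ids)
    edge_rows = []
    for a, b in zip(*np.nonzero(np.triu(adjacency, k=1))):
        graph.add_edge(node_ids[a], node_ids[b])
        edge_rows.append(
            {
                "node_1": node_ids[a],
                "node_2": node_ids[b],
                "sign": int(sign[a, b]),
                "stability": float(theta[li_sel, a, b]),
            }
        )
    edges = pd.DataFrame(edge_rows, columns=["node_1", "node_2", "sign", "stability"])
    nodes = _centrality_table(graph, domains)
    return NetworkResult(
        nodes=nodes,
        edges=edges,
        graph=graph,
        lambda_selected=lam_sel,
        lambda_path=lambdas,
        instability=instability,
    )


def _centrality_table(graph: nx.Graph, domains: dict[str, str] | None = None) -> pd.DataFrame:
    if graph.number_of_nodes() == 0:
        return pd.DataFrame(
            columns=["domain", "degree", "betweenness"],
            index=pd.Index([], name="asv_id"),
        )
    betweenness = nx.betweenness_centrality(graph, normalized=False)
    rows = []
    for node in graph.nodes:
        rows.append(
            {
                "asv_id": node,
                "domain": (domains or {}).get(node),
                "degree": graph.degree[node],
                "betweenness": betweenness[node],
            }
        )
    return pd.DataFrame(rows).set_index("asv_id")


def network_from_edges(edges, nodes=None, domains=None) -> NetworkResult:
    """Build a NetworkResult from an explicit edge list (e.g. planted truth)."""
    graph = nx.Graph()
    if nodes is not None:
        graph.add_nodes_from(nodes)
    graph.add_edges_from(edges)
    edge_df = pd.DataFrame(
        [{"node_1": a, "node_2": b, "sign": 0, "stability": np.nan} for a, b in graph.edges],
        columns=["node_1", "node_2", "sign", "stability"],
    )
    return NetworkResult(
        nodes=_centrality_table(graph, domains),
        edges=edge_df,
        graph=graph,
        lambda_selected=None,
        lambda_path=None,
        instability=None,
    )


def _nearest_rank_threshold(values: np.ndarray, percentile: float) -> float:
    """Inclusive nearest-rank percentile (value at rank ceil(p*n))."""
    ordered = np.sort(values)
    rank = max(1, math.ceil(percentile * len(ordered)))
    return float(ordered[rank - 1])


def identify_hubs(
    net: NetworkResult,
    tables: CountTable | list[CountTable],
    core: list[str],
    percentile: float = 0.90,
    min_abund: float = 0.001,
) -> pd.DataFrame:
    """Hub ASVs: top-decile degree AND betweenness, core member, abundant.

    Mean relative abundance is computed per node on the non-subsampled
    table of its own domain; ties at the percentile cutoffs are inclusive
    (the >= reading of the rule).  Returns the hub table with the per-hub
    degree, betweenness, abundance and core flag.
    """
    if net.nodes.empty:
        raise ValueError("empty network: no nodes to classify")
    if isinstance(tables, CountTable):
        tables = [tables]
    mean_abund: dict[str, float] = {}
    for tbl in tables:
        props = relative_abundance(tbl)
        for asv, value in props.mean(axis=1).items():
            mean_abund[asv] = float(value)

    deg = net.nodes["degree"].to_numpy(dtype=float)
    btw = net.nodes["betweenness"].to_numpy(dtype=float)
    deg_thr = _nearest_rank_threshold(deg, percentile)
    btw_thr = _nearest_rank_threshold(btw, percentile)
    core_set = set(core)

    out = net.nodes.copy()
    out["mean_rel_abund"] = [mean_abund.get(a, 0.0) for a in out.index]
    out["is_core"] = [a in core_set for a in out.index]
    out["is_hub"] = (
        (out["degree"] >= deg_thr)
        & (out["betweenness"] >= btw_thr)
        & out["is_core"]
        & (out["mean_rel_abund"] >= min_abund)
    )
    hubs = out[out["is_hub"]].drop(columns="is_hub")
    return hubs
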