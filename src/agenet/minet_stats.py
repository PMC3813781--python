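"""Mutual-information networks, DPI pruning, topology and hub comparison.

Pairwise mutual information between mean temporal profiles is estimated
with the Gaussian-copula closed form on the Spearman correlation,
MI = -1/2 * ln(1 - rho_s^2), which is nonnegative, rank-based (invariant
under strictly monotone transforms of either profile) and exactly
testable; |rho_s| = 1 is capped at MI_max. Dense MI matrices are pruned
with the data-processing inequality (the ARACNE rule): in every triangle
the weakest edge is removed when it is smaller than both others minus a
tolerance, decisions taken against the original matrix and applied once.

Nine topology parameters summarize each network: edge count, mean
degree, transitivity, mean coreness, mean nearest-neighbor degree, mean
graph strength, mean second-order neighborhood size, vertex connectivity
(cohesion), and "diameter" defined as the mean shortest-path length over
connected pairs (high-MI edges are short: distance = 1/weight).
Percentage changes between conditions use the reciprocal of the diameter
so that positive changes always mean a tighter network. Hubs are nodes
whose graph strength exceeds mean + n_sd * sd of the strengths.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mi_matrix",
    "dpi_prune",
    "network_stats",
    "NetStats",
    "percent_change",
    "find_hubs",
    "hub_turnover",
    "HubReport",
    "MI_MAX_DEFAULT",
]

MI_MAX_DEFAULT = 5.0  # nats, stands in for the infinite MI of |rho| = 1


def mi_matrix(
    mean_profiles: pd.DataFrame, mi_max: float = MI_MAX_DEFAULT
) -> pd.DataFrame:
    """Gaussian-copula MI from Spearman correlation of mean profiles.

    ``mean_profiles`` is genes x ages (replicates already averaged).
    Genes with constant profiles have undefined rank correlation and are
    dropped with a warning. The diagonal is set to 0.
    """
    X = mean_profiles.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 ages")
    sd = X.std(axis=1)
    if (sd == 0).any():
        dropped = list(mean_profiles.index[sd == 0])
        warnings.warn(
            f"dropping {len(dropped)} constant-profile genes: {dropped[:5]}...",
            stacklevel=2,
        )
        mean_profiles = mean_profiles.loc[sd > 0]
        X = mean_profiles.to_numpy(dtype=float)
    ranks = stats.rankdata(X, axis=1)
    rho = np.corrcoef(ranks)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        mi = -0.5 * np.log(1.0 - rho ** 2)
    mi = np.where(np.isclose(np.abs(rho), 1.0) | (mi > mi_max), mi_max, mi)
    np.fill_diagonal(mi, 0.0)
    idx = mean_profiles.index
    return pd.DataFrame(mi, index=idx, columns=idx)


def dpi_prune(mi: pd.DataFrame, eps: float = 0.0) -> nx.Graph:
    """ARACNE-style data-processing-inequality pruning of a dense MI matrix.

    Edge (i, k) is removed when some third gene j satisfies
    MI_ik < min(MI_ij, MI_jk) - eps (strict, so exact ties survive).
    All removal decisions are made against the input matrix and applied
    simultaneously; the result is idempotent under re-pruning.
    """
    M = mi.to_numpy(dtype=float).copy()
    n = M.shape[0]
    remove = np.zeros_like(M, dtype=bool)
    for j in range(n):
        col = M[:, j]
        bound = np.minimum(col[:, None], col[None, :])  # min(MI_ij, MI_jk)
        mask = M < bound - eps
        mask[j, :] = False
        mask[:, j] = False
        remove |= mask
    net = nx.Graph()
    net.add_nodes_from(mi.index)
    genes = list(mi.index)
    iu, ju = np.triu_indices(n, k=1)
    keep = (M[iu, ju] > 0) & ~remove[iu, ju]
    for i, j in zip(iu[keep], ju[keep]):
        net.add_edge(genes[i], genes[j], weight=float(M[i, j]))
    return net


@dataclass
class NetStats:
    """The nine topology parameters compared between conditions."""

    n_edges: int
    mean_degree: float
    transitivity: float
    mean_coreness: float
    mean_neighbor_degree: float
    mean_strength: float
    mean_second_order_neighborhood: float
    vertex_connectivity: int
    diameter: float  # mean shortest-path length over connected pairs
    reciprocal_diameter: float
    max_eccentricity: float  # conventional diameter, reported for reference

    def as_dict(self) -> dict:
        return {
            "n_edges": self.n_edges,
            "mean_degree": self.mean_degree,
            "transitivity": self.transitivity,
            "mean_coreness": self.mean_coreness,
            "mean_neighbor_degree": self.mean_neighbor_degree,
            "mean_strength": self.mean_strength,
            "mean_second_order_neighborhood": self.mean_second_order_neighborhood,
            "vertex_connectivity": self.vertex_connectivity,
            "diameter": self.diameter,
            "reciprocal_diameter": self.reciprocal_diameter,
        }


def _strengths(net: nx.Graph) -> pd.Series:
    return pd.Series(dict(net.degree(weight="weight")), dtype=float)


def network_stats(net: nx.Graph) -> NetStats:
    """Compute the nine topology parameters of a weighted undirected graph.

    Shortest paths use distance = 1/weight (strong dependencies are
    close). On disconnected graphs vertex connectivity is 0 and path
    statistics average over connected pairs only (with a warning).
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    n = net.number_of_nodes()
    degrees = np.array([d for _, d in net.degree()], dtype=float)
    mean_degree = degrees.mean()
    transitivity = nx.transitivity(net)
    simple = nx.Graph(net)  # core_number forbids self-loops; copy drops attrs only
    mean_coreness = float(np.mean(list(nx.core_number(simple).values())))
    nbr_deg = nx.average_neighbor_degree(net)
    mean_neighbor_degree = float(np.mean([nbr_deg[v] for v in net.nodes]))
    mean_strength = float(_strengths(net).mean()) if net.number_of_edges() else 0.0

    second_order = []
    for v in net.nodes:
        reach = nx.single_source_shortest_path_length(net, v, cutoff=2)
        second_order.append(len(reach) - 1)
    mean_second = float(np.mean(second_order))

    connected = nx.is_connected(net) if n > 1 else True
    if not connected:
        warnings.warn(
            "network is disconnected: vertex connectivity 0, path averages "
            "over connected pairs",
            stacklevel=2,
        )
        vconn = 0
    else:
        vconn = nx.node_connectivity(net) if n > 1 else 0

    for u, v, d in net.edges(data=True):
        d["distance"] = 1.0 / d["weight"] if d.get("weight", 1.0) > 0 else np.inf
    total, pairs = 0.0, 0
    ecc = 0.0
    for source, dists in nx.all_pairs_dijkstra_path_length(net, weight="distance"):
        for target, dist in dists.items():
            if target == source:
                continue
            total += dist
            pairs += 1
            ecc = max(ecc, dist)
    diameter = total / pairs if pairs else np.nan
    recip = 1.0 / diameter if pairs and diameter > 0 else np.nan
    return NetStats(
        n_edges=net.number_of_edges(),
        mean_degree=float(mean_degree),
        transitivity=float(transitivity),
        mean_coreness=mean_coreness,
        mean_neighbor_degree=mean_neighbor_degree,
        mean_strength=mean_strength,
        mean_second_order_neighborhood=mean_second,
        vertex_connectivity=int(vconn),
        diameter=float(diameter),
        reciprocal_diameter=float(recip),
        max_eccentricity=float(ecc),
    )


def percent_change(stats_control: NetStats, stats_treated: NetStats) -> pd.Series:
    """Per-parameter percentage change treated vs control.

    Delta% = 100 * (x_T - x_C) / x_C for all parameters except the
    diameter, which enters through its reciprocal so that positive bars
    always mean better connectivity. Parameters with a zero control value
    are reported as NaN.
    """
    a = stats_control.as_dict()
    b = stats_treated.as_dict()
    out = {}
    for key in a:
        if key == "diameter":
            continue
        x_c, x_t = a[key], b[key]
        out[key] = 100.0 * (x_t - x_c) / x_c if x_c else np.nan
    return pd.Series(out, name="percent_change")


@dataclass
class HubReport:
    strengths: pd.Series
    mean_strength: float
    sd_strength: float
    hubs: set


def find_hubs(net: nx.Graph, n_sd: float = 1.0) -> HubReport:
    """Hubs: nodes with graph strength above mean + n_sd * sample sd.

    Graph strength is the sum of the weights of a node's incident edges.
    A regular network (sd = 0) has no hubs by definition.
    """
    if net.number_of_nodes() < 3:
        raise ValueError("hub detection needs at least 3 nodes")
    s = _strengths(net)
    mean, sd = float(s.mean()), float(s.std(ddof=1))
    hubs = set(s.index[s > mean + n_sd * sd]) if sd > 0 else set()
    return HubReport(s, mean, sd, hubs)


def hub_turnover(report_control: HubReport, report_treated: HubReport) -> tuple[set, set]:
    """(gained, lost) hub sets when moving from control to treated."""
    gained = report_treated.hubs - report_control.hubs
    lost = report_control.hubs - report_treated.hubs
    return gained, lost
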