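"""Significance-thresholded co-expression networks and difference networks.

Per-condition networks connect gene pairs whose temporal profiles are
significantly correlated. Replicates enter through resampling: each draw
picks one replicate per age per gene (54 distinct profiles per gene under
the 3/3/3/2 design, 54^2 = 2,916 joint choices per pair), Pearson r and
its two-sided t-test p-value (df = n_ages - 2) are computed per draw and
averaged. An edge is kept when the mean p-value is <= alpha (default
0.05); with only four ages this demands |r| close to 1, so the networks
are sparse.

The difference network compares co-expression *strength* between
conditions: w_ij = |r_treated| - |r_control|, pruned at |w| >= tau.
Positive weights mean tighter co-expression under treatment. Gene sets
(GMT) whose difference-subnetwork contains disproportionately many
connected genes are found with a one-sided Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .temporal import ProfileSet, TemporalProfile

__all__ = [
    "CorrelationRecord",
    "resampled_correlation",
    "resampled_correlation_matrix",
    "replicate_combinations",
    "pair_combinations",
    "build_corr_network",
    "fit_power_law",
    "PowerLawFit",
    "difference_network",
    "connectivity_enrichment",
    "read_gmt",
    "write_gmt",
    "write_edgelist",
]

EDGE_ALPHA_DEFAULT = 0.05
# difference-network pruning threshold: with four ages a chance mean
# correlation has |r| ~ 0.45 +- 0.25, so chance |w| reaches 0.5 often;
# 0.8 keeps ~0.1% of null pairs (the global pruned network stays sparse
# at the gene level, which the connectivity enrichment needs) while pairs
# whose coupling genuinely flips retain at ~25%
TAU_DEFAULT = 0.8


@dataclass
class CorrelationRecord:
    gene_i: str
    gene_j: str
    r_bar: float
    p_bar: float
    n_draws: int


def replicate_combinations(tp: TemporalProfile | ProfileSet) -> int:
    """Distinct one-replicate-per-age profile selections (54 for 3/3/3/2)."""
    if isinstance(tp, ProfileSet):
        return tp.n_replicate_combinations()
    return int(np.prod([len(v) for v in tp.values]))


def pair_combinations(tp_i, tp_j) -> int:
    """Joint selections for a gene pair (2,916 for two 3/3/3/2 profiles)."""
    return replicate_combinations(tp_i) * replicate_combinations(tp_j)


def _r_to_p(r: np.ndarray, n_ages: int) -> np.ndarray:
    """Two-sided t-test p-value of a Pearson r with df = n_ages - 2."""
    df = n_ages - 2
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt(df / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(t, df)
    return np.where(np.isclose(np.abs(r), 1.0), 0.0, p)


def resampled_correlation(
    tp_i: TemporalProfile,
    tp_j: TemporalProfile,
    n_draws: int = 100,
    seed: int | None = 0,
) -> CorrelationRecord:
    """Mean Pearson r and mean p over random joint replicate selections.

    Draws with a constant profile on either side are skipped; if every
    draw is degenerate the correlation is undefined and an error is
    raised. With a single replicate everywhere the result equals the
    plain Pearson correlation of the two profiles.
    """
    if tp_i.ages != tp_j.ages:
        raise ValueError("profiles must share the same age grid")
    if tp_i.n_ages < 3:
        raise ValueError("need at least 3 ages")
    rng = np.random.default_rng(seed)
    n_ages = tp_i.n_ages
    xi = np.column_stack(
        [tp_i.values[a][rng.integers(len(tp_i.values[a]), size=n_draws)]
         for a in range(n_ages)]
    )
    xj = np.column_stack(
        [tp_j.values[a][rng.integers(len(tp_j.values[a]), size=n_draws)]
         for a in range(n_ages)]
    )
    ci = xi - xi.mean(axis=1, keepdims=True)
    cj = xj - xj.mean(axis=1, keepdims=True)
    denom = np.sqrt((ci ** 2).sum(axis=1) * (cj ** 2).sum(axis=1))
    valid = denom > 0
    if not valid.any():
        raise ValueError("all draws degenerate: constant profiles")
    r = (ci * cj).sum(axis=1)[valid] / denom[valid]
    p = _r_to_p(r, n_ages)
    return CorrelationRecord(
        tp_i.gene_id, tp_j.gene_id, float(r.mean()), float(p.mean()), int(valid.sum())
    )


def resampled_correlation_matrix(
    pset: ProfileSet, n_draws: int = 100, seed: int | None = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs mean r and mean p over replicate-resampled profiles.

    Each draw independently picks one replicate per age for every gene and
    computes the full gene-gene Pearson matrix plus the per-pair t-test
    p-value; both are averaged over draws. Pairs involving a constant
    drawn profile are skipped in that draw (NaN if never defined).
    """
    rng = np.random.default_rng(seed)
    n_genes = len(pset.gene_ids)
    n_ages = len(pset.ages)
    r_sum = np.zeros((n_genes, n_genes))
    p_sum = np.zeros((n_genes, n_genes))
    n_valid = np.zeros((n_genes, n_genes))
    for _ in range(n_draws):
        X = np.column_stack(
            [
                b[np.arange(n_genes), rng.integers(b.shape[1], size=n_genes)]
                for b in pset.blocks
            ]
        )
        c = X - X.mean(axis=1, keepdims=True)
        ss = np.sqrt((c ** 2).sum(axis=1))
        ok = ss > 0
        ssn = np.where(ok, ss, 1.0)
        z = c / ssn[:, None]
        r = z @ z.T
        r = np.clip(r, -1.0, 1.0)
        valid = np.outer(ok, ok)
        p = _r_to_p(r, n_ages)
        r_sum += np.where(valid, r, 0.0)
        p_sum += np.where(valid, p, 0.0)
        n_valid += valid
    with np.errstate(invalid="ignore"):
        r_bar = r_sum / n_valid
        p_bar = p_sum / n_valid
    idx = pset.gene_ids
    return (
        pd.DataFrame(r_bar, index=idx, columns=idx),
        pd.DataFrame(p_bar, index=idx, columns=idx),
    )


def build_corr_network(
    pset: ProfileSet,
    alpha: float = EDGE_ALPHA_DEFAULT,
    n_draws: int = 100,
    seed: int | None = 0,
    matrices: tuple[pd.DataFrame, pd.DataFrame] | None = None,
) -> nx.Graph:
    """Per-condition co-expression network thresholded on the mean p-value.

    Edge (i, j) with weight r_bar is kept iff p_bar <= alpha; genes
    without any significant partner do not appear as nodes (node counts
    then mean "connected genes"). Precomputed (r_bar, p_bar) matrices can
    be passed to avoid recomputation.
    """
    if matrices is None:
        r_bar, p_bar = resampled_correlation_matrix(pset, n_draws, seed)
    else:
        r_bar, p_bar = matrices
    genes = list(r_bar.index)
    net = nx.Graph(condition=pset.condition)
    rv = r_bar.to_numpy()
    pv = p_bar.to_numpy()
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = pv[iu, ju] <= alpha
    for i, j in zip(iu[keep], ju[keep]):
        net.add_edge(genes[i], genes[j], weight=float(rv[i, j]))
    return net


@dataclass
class PowerLawFit:
    gamma: float  # slope of log10 f(k) on log10 k
    log_c: float  # intercept
    r_squared: float
    n_points: int


def fit_power_law(network: nx.Graph) -> PowerLawFit:
    """OLS fit of the degree-frequency distribution f(k) ~ c * k^gamma.

    Regression of log10 frequency on log10 degree over the observed
    (nonzero-frequency, k >= 1) degrees; needs at least 3 support points.
    """
    degrees = np.array([d for _, d in network.degree()])
    degrees = degrees[degrees >= 1]
    ks, freqs = np.unique(degrees, return_counts=True)
    if len(ks) < 3:
        raise ValueError("power-law fit needs >= 3 distinct degrees")
    x = np.log10(ks.astype(float))
    y = np.log10(freqs.astype(float))
    res = stats.linregress(x, y)
    return PowerLawFit(
        float(res.slope), float(res.intercept), float(res.rvalue ** 2), len(ks)
    )


def difference_network(
    r_control: pd.DataFrame, r_treated: pd.DataFrame, tau: float = TAU_DEFAULT
) -> nx.Graph:
    """Absolute-correlation difference network, pruned at |w| >= tau.

    w_ij = |r_treated,ij| - |r_control,ij|: positive weights mean the pair
    is more tightly co-expressed under treatment regardless of sign. All
    genes appear as nodes (isolated nodes = unchanged co-expression), so
    the graph doubles as the enrichment universe.
    """
    if not r_control.index.equals(r_treated.index):
        raise ValueError("correlation matrices cover different gene sets")
    w = np.abs(r_treated.to_numpy()) - np.abs(r_control.to_numpy())
    genes = list(r_control.index)
    net = nx.Graph(tau=tau)
    net.add_nodes_from(genes)
    iu, ju = np.triu_indices(len(genes), k=1)
    vals = w[iu, ju]
    keep = np.abs(vals) >= tau
    keep &= np.isfinite(vals)
    for i, j, v in zip(iu[keep], ju[keep], vals[keep]):
        net.add_edge(genes[i], genes[j], weight=float(v))
    return net


def connectivity_enrichment(
    pruned_dn: nx.Graph,
    gene_sets: dict[str, set],
    min_set_size: int = 4,
) -> tuple[pd.DataFrame, list[str]]:
    """Gene sets over-represented among connected genes of the difference net.

    A set member is "connected" when it has at least one retained edge
    within the set-induced subgraph. The background is the fraction of
    connected genes (any retained edge) among genes *outside* the set, so
    the 2x2 margins are independent. One-sided (greater) Fisher exact
    p-values, BH-adjusted across sets. Sets smaller than ``min_set_size``
    (after intersecting the universe) are skipped and reported.
    """
    from .diffexpr import bh_adjust

    universe = set(pruned_dn.nodes)
    globally_connected = {n for n in universe if pruned_dn.degree(n) > 0}
    rows, skipped = [], []
    for set_id, members in gene_sets.items():
        inset = set(members) & universe
        if len(inset) < min_set_size:
            skipped.append(set_id)
            continue
        sub = pruned_dn.subgraph(inset)
        conn_in = sum(1 for n in inset if sub.degree(n) > 0)
        outside = universe - inset
        conn_out = len(globally_connected & outside)
        table = [
            [conn_in, len(inset) - conn_in],
            [conn_out, len(outside) - conn_out],
        ]
        odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "set_id": set_id,
                "set_size": len(inset),
                "connected_in_set": conn_in,
                "background_connected_fraction": (
                    conn_out / len(outside) if outside else np.nan
                ),
                "odds_ratio": odds,
                "fisher_p": p,
            }
        )
    result = pd.DataFrame(rows)
    if len(result):
        result["q"] = bh_adjust(result["fisher_p"].to_numpy())
        result = result.sort_values("fisher_p").reset_index(drop=True)
    return result, skipped


def read_gmt(path) -> dict[str, set]:
    """Read a GMT gene-set file: tab-separated set id, description, members."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(gene_sets: dict[str, set], path, descriptions=None) -> None:
    with open(path, "w") as fh:
        for set_id, members in gene_sets.items():
            desc = (descriptions or {}).get(set_id, "na")
            fh.write("\t".join([set_id, desc, *sorted(members)]) + "\n")


def write_edgelist(net: nx.Graph, path) -> None:
    """3-column TSV edge list (gene_i, gene_j, weight), sorted for stability."""
    with open(path, "w") as fh:
        fh.write("gene_i\tgene_j\tweight\n")
        for u, v, d in sorted(net.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d.get('weight', 1.0):.6g}\n")
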