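"""Consensus negative-binomial differential expression per age level.

Differential expression between the two conditions is tested separately
at each age with a conditional NB exact test: conditioning on the pooled
count total of a gene, the probability of group totals at least as
unlikely as the observed split is summed (two-sided by probability
ordering; ties are counted in the tail, which is conservative). Group
sums of n i.i.d. NB(mu, phi) variables are NB(n*mu, phi/n), and phi -> 0
recovers the Poisson/binomial exact test.

A gene is called differentially expressed only when the BH-adjusted
p-value is <= alpha under *both* dispersion-estimation modes (pooled
moments vs per-condition moments averaged). Requiring agreement of two
differently-specified tests mirrors the common practice of accepting
only calls confirmed by two independent NB testing tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expr import CountMatrix

__all__ = [
    "size_factors",
    "estimate_dispersion",
    "nb_exact_test",
    "bh_adjust",
    "call_deg",
    "deg_summary_row",
    "constant_deg",
    "DEGResult",
]

ALPHA_DEFAULT = 0.01


class NormalizationError(ValueError):
    pass


class EstimationError(ValueError):
    pass


@dataclass
class DEGResult:
    """Per-gene table and one summary row for a single age level."""

    table: pd.DataFrame  # per-gene p/q/log2fc/direction/is_deg
    summary: dict  # age, n_total, n_up, n_down, fraction_down


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Uses only genes with nonzero counts in every sample (the geometric
    mean of a gene with a zero is zero, making the ratio undefined).
    """
    counts = cm.counts.to_numpy(dtype=float)
    allpos = (counts > 0).all(axis=1)
    if not allpos.any():
        raise NormalizationError("no gene has nonzero counts in all samples")
    logc = np.log(counts[allpos])
    log_geomean = logc.mean(axis=1)
    ratios = logc - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.counts.columns, name="size_factor")


def estimate_dispersion(
    cm: CountMatrix,
    sf: pd.Series,
    mode: str = "pooled",
    floor_quantile: float | None = 0.5,
) -> pd.Series:
    """Method-of-moments NB dispersion phi per gene on normalized counts.

    phi = max(0, (s^2 - m) / m^2). ``pooled`` combines the *within*-
    condition variances into one pooled variance (weighted by degrees of
    freedom) around the grand mean, so a real condition effect does not
    masquerade as dispersion; ``per_condition`` solves for phi separately
    inside each condition (own mean and variance) and averages the two.
    phi is clamped at zero (counts can be under-dispersed by chance).
    When the design has a single condition both modes coincide with the
    plain within-group moment estimate.

    With two or three replicates the per-gene moment estimate is very
    noisy and piles up at zero, which makes a downstream exact test
    anti-conservative; ``floor_quantile`` therefore raises every phi to
    at least the given across-gene quantile of the raw estimates
    (default: the median), the conservative information-sharing rule of
    early NB testing tools. Pass None for the raw per-gene estimates.
    """
    if mode not in ("pooled", "per_condition"):
        raise ValueError(f"unknown dispersion mode {mode!r}")
    norm = cm.counts.div(sf, axis=1)
    groups = []
    for cond in cm.design["condition"].unique():
        cols = cm.samples(condition=cond)
        if len(cols) < 2:
            raise EstimationError("need >= 2 replicates per condition")
        groups.append(norm[cols])

    def _phi_from(m: pd.Series, s2: pd.Series) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = (s2 - m) / (m ** 2)
        return phi.clip(lower=0.0).fillna(0.0)

    if mode == "pooled":
        dof = sum(g.shape[1] - 1 for g in groups)
        s2 = sum((g.shape[1] - 1) * g.var(axis=1, ddof=1) for g in groups) / dof
        m = norm.mean(axis=1)
        phi = _phi_from(m, s2)
    else:
        phis = [_phi_from(g.mean(axis=1), g.var(axis=1, ddof=1)) for g in groups]
        phi = pd.concat(phis, axis=1).mean(axis=1)
    if floor_quantile is not None:
        phi = phi.clip(lower=float(phi.quantile(floor_quantile)))
    return phi.rename("phi")


def _group_logpmf(total_grid: np.ndarray, mu: float, phi_group: float) -> np.ndarray:
    if mu <= 0:
        out = np.full_like(total_grid, -np.inf, dtype=float)
        out[total_grid == 0] = 0.0
        return out
    if phi_group <= 0:
        return stats.poisson.logpmf(total_grid, mu)
    r = 1.0 / phi_group
    p = r / (r + mu)
    return stats.nbinom.logpmf(total_grid, r, p)


def nb_exact_test(
    cm: CountMatrix, sf: pd.Series, disp: pd.Series, age: int
) -> pd.Series:
    """Two-sided conditional NB exact test p-values at one age level.

    For each gene, the group sums K_A (control) and K_B (treated) are
    modelled as NB with means proportional to the groups' summed size
    factors and dispersions phi/n_group; conditioning on K_A + K_B, the
    p-value sums P(K_A = a) * P(K_B = k - a) over all splits no more
    probable than the observed one.
    """
    cols_a = cm.samples(condition="control", age=age)
    cols_b = cm.samples(condition="treated", age=age)
    if not cols_a or not cols_b:
        raise ValueError(f"age {age} lacks samples in one of the conditions")
    ka = cm.counts[cols_a].sum(axis=1).to_numpy()
    kb = cm.counts[cols_b].sum(axis=1).to_numpy()
    sa = float(sf[cols_a].sum())
    sb = float(sf[cols_b].sum())
    na, nb = len(cols_a), len(cols_b)
    phi = disp.loc[cm.gene_ids].to_numpy(dtype=float)

    pvals = np.ones(cm.n_genes)
    for i in range(cm.n_genes):
        ks = int(ka[i] + kb[i])
        if ks == 0:
            continue
        q = ks / (sa + sb)
        grid = np.arange(ks + 1)
        lp = _group_logpmf(grid, q * sa, phi[i] / na) + _group_logpmf(
            grid[::-1], q * sb, phi[i] / nb
        )
        lp_obs = lp[int(ka[i])]
        finite = np.isfinite(lp)
        if not finite.any() or not np.isfinite(lp_obs):
            continue
        m = lp[finite].max()
        w = np.exp(lp[finite] - m)
        tail = w[lp[finite] <= lp_obs + 1e-9].sum()
        pvals[i] = min(1.0, tail / w.sum())
    return pd.Series(pvals, index=cm.gene_ids, name=f"p_age{age}")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), clamped to <= 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_deg(cm: CountMatrix, age: int, alpha: float = ALPHA_DEFAULT) -> DEGResult:
    """Consensus DEG calls at one age: both dispersion modes must agree.

    ``cm`` should already be filtered with the low-count rule. Direction
    is the sign of the normalized-mean ratio treated/control; the summary
    reports up/down tallies and the percentage of down-regulated calls.
    """
    sub = cm.subset_samples(cm.samples(age=age))
    sf = size_factors(sub)
    p_pooled = nb_exact_test(sub, sf, estimate_dispersion(sub, sf, "pooled"), age)
    p_percond = nb_exact_test(
        sub, sf, estimate_dispersion(sub, sf, "per_condition"), age
    )
    q_pooled = bh_adjust(p_pooled.to_numpy())
    q_percond = bh_adjust(p_percond.to_numpy())

    norm = sub.counts.div(sf, axis=1)
    mean_c = norm[sub.samples(condition="control")].mean(axis=1)
    mean_t = norm[sub.samples(condition="treated")].mean(axis=1)
    log2fc = np.log2((mean_t + 0.5) / (mean_c + 0.5))
    is_deg = (q_pooled <= alpha) & (q_percond <= alpha)
    direction = np.where(log2fc > 0, "up", "down")

    table = pd.DataFrame(
        {
            "age_days": age,
            "mean_control": mean_c,
            "mean_treated": mean_t,
            "log2fc": log2fc,
            "p_pooled": p_pooled.to_numpy(),
            "p_percond": p_percond.to_numpy(),
            "q_pooled": q_pooled,
            "q_percond": q_percond,
            "direction": direction,
            "is_deg": is_deg,
        },
        index=cm.gene_ids,
    )
    n_up = int(((direction == "up") & is_deg).sum())
    n_down = int(((direction == "down") & is_deg).sum())
    return DEGResult(table, deg_summary_row(age, n_up, n_down))


def deg_summary_row(age: int, n_up: int, n_down: int) -> dict:
    """Tally a DEG count row: totals and the percentage of down-regulated genes.

    ``fraction_down`` is the exact percentage 100 * n_down / n_total;
    ``fraction_down_printed`` truncates it to one decimal place, the
    convention used when quoting such tables.
    """
    n_total = n_up + n_down
    if n_total > 0:
        frac = 100.0 * n_down / n_total
        printed = float(np.floor(frac * 10) / 10)
    else:
        frac = printed = 0.0
    return {
        "age_days": age,
        "n_total": n_total,
        "n_up": n_up,
        "n_down": n_down,
        "fraction_down": frac,
        "fraction_down_printed": printed,
    }


def constant_deg(tables: dict[int, pd.DataFrame]) -> tuple[set, set]:
    """Genes called DE with the same direction at all four age levels.

    Returns (always-up, always-down) gene-id sets.
    """
    if len(tables) < 4:
        raise ValueError("constant-DEG intersection needs all four age levels")
    up_sets, down_sets = [], []
    for tab in tables.values():
        deg = tab[tab["is_deg"]]
        up_sets.append(set(deg.index[deg["direction"] == "up"]))
        down_sets.append(set(deg.index[deg["direction"] == "down"]))
    always_up = set.intersection(*up_sets)
    always_down = set.intersection(*down_sets)
    return always_up, always_down
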