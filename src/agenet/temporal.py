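"""Temporal-profile statistics: monotony, reversals, negative-correlation
permutation test, and fuzzy c-means clustering.

A gene's temporal profile is its replicate expression values over the
four age levels (1, 5, 10, 20 days) in one condition. Monotony is the
mean Spearman correlation of resampled profiles with an increasing ramp,
classified at +-0.75; genes that are monotone in opposite directions in
the two conditions "reverse" their ageing trend under treatment. The
Monte-Carlo test detects genes whose control and treated profiles are
significantly negatively correlated over age, using a null built by
permuting the chronological order of the treated profile. Significant
genes are grouped by fuzzy c-means over their standardized mean profiles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expr import ExpressionMatrix

__all__ = [
    "TemporalProfile",
    "ProfileSet",
    "profiles_from_expression",
    "monotony_score",
    "monotony_scores",
    "classify_monotony",
    "find_reversals",
    "negcorr_perm_test",
    "NegCorrResult",
    "standardized_profiles",
    "fuzzy_cmeans_cluster",
    "ClusterResult",
    "MONOTONY_THRESHOLD",
]

MONOTONY_THRESHOLD = 0.75


class UndefinedCorrelationError(ValueError):
    pass


@dataclass
class TemporalProfile:
    """Replicate expression values of one gene over the ordered ages."""

    gene_id: str
    condition: str
    ages: tuple[int, ...]
    values: tuple[np.ndarray, ...]  # one array of replicates per age

    def __post_init__(self) -> None:
        if any(self.ages[i] >= self.ages[i + 1] for i in range(len(self.ages) - 1)):
            raise ValueError("ages must be strictly increasing")
        if any(len(v) == 0 for v in self.values):
            raise ValueError("every age needs at least one replicate")

    @property
    def n_ages(self) -> int:
        return len(self.ages)

    def means(self) -> np.ndarray:
        return np.array([v.mean() for v in self.values])

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        """One random replicate per age."""
        return np.array([v[rng.integers(len(v))] for v in self.values])


@dataclass
class ProfileSet:
    """Temporal profiles of many genes in one condition, column-aligned.

    ``blocks[a]`` is a genes x replicates array for age ``ages[a]``.
    """

    gene_ids: pd.Index
    condition: str
    ages: tuple[int, ...]
    blocks: list[np.ndarray]

    def get(self, gene_id: str) -> TemporalProfile:
        i = self.gene_ids.get_loc(gene_id)
        return TemporalProfile(
            gene_id,
            self.condition,
            self.ages,
            tuple(b[i] for b in self.blocks),
        )

    def mean_profiles(self) -> pd.DataFrame:
        """Genes x ages matrix of per-age replicate means."""
        return pd.DataFrame(
            np.column_stack([b.mean(axis=1) for b in self.blocks]),
            index=self.gene_ids,
            columns=list(self.ages),
        )

    def n_replicate_combinations(self) -> int:
        """Number of distinct one-replicate-per-age profile draws (54 for 3/3/3/2)."""
        return int(np.prod([b.shape[1] for b in self.blocks]))


def profiles_from_expression(
    expr: ExpressionMatrix, condition: str, genes=None
) -> ProfileSet:
    """Collect per-age replicate blocks for one condition."""
    ages = tuple(sorted(expr.design["age_days"].unique()))
    values = expr.values if genes is None else expr.values.loc[pd.Index(genes)]
    blocks = []
    for age in ages:
        cols = expr.samples(condition, age)
        if not cols:
            raise ValueError(f"no samples for ({condition}, {age} d)")
        blocks.append(values[cols].to_numpy(dtype=float))
    return ProfileSet(values.index, condition, ages, blocks)


def _spearman_vs_ramp(draws: np.ndarray) -> np.ndarray:
    """Row-wise Spearman correlation of draws (n x ages) with an increasing ramp.

    Rows with zero rank variance (constant profiles) score 0.
    """
    ranks = stats.rankdata(draws, axis=1)
    ramp = np.arange(1, draws.shape[1] + 1, dtype=float)
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    gc = ramp - ramp.mean()
    denom = np.sqrt((rc ** 2).sum(axis=1) * (gc ** 2).sum())
    num = rc @ gc
    out = np.zeros(draws.shape[0])
    np.divide(num, denom, out=out, where=denom > 0)
    return out


def _resample_indices(
    rng: np.random.Generator, n_rep: list[int], B
) -> np.ndarray:
    """B x n_ages matrix of replicate choices; B='all' enumerates the product."""
    if B == "all":
        return np.array(list(itertools.product(*[range(r) for r in n_rep])))
    return np.column_stack([rng.integers(r, size=B) for r in n_rep])


def monotony_score(tp: TemporalProfile, B=100, seed: int | None = 0) -> float:
    """Mean Spearman correlation with an increasing ramp over B replicate draws.

    Each draw picks one random replicate per age; B='all' enumerates every
    combination (54 under the 3/3/3/2 design). The score only uses ranks,
    so any strictly increasing transform of the age axis leaves it fixed.
    """
    if tp.n_ages < 3:
        raise ValueError("monotony needs at least 3 age levels")
    rng = np.random.default_rng(seed)
    n_rep = [len(v) for v in tp.values]
    idx = _resample_indices(rng, n_rep, B)
    draws = np.column_stack([tp.values[a][idx[:, a]] for a in range(tp.n_ages)])
    return float(_spearman_vs_ramp(draws).mean())


def monotony_scores(pset: ProfileSet, B=100, seed: int = 0) -> pd.Series:
    """Vectorized monotony scores for all genes of a ProfileSet."""
    rng = np.random.default_rng(seed)
    n_rep = [b.shape[1] for b in pset.blocks]
    idx = _resample_indices(rng, n_rep, B)
    n_draws = idx.shape[0]
    total = np.zeros(len(pset.gene_ids))
    for d in range(n_draws):
        draws = np.column_stack(
            [pset.blocks[a][:, idx[d, a]] for a in range(len(pset.ages))]
        )
        total += _spearman_vs_ramp(draws)
    return pd.Series(total / n_draws, index=pset.gene_ids, name="rho_bar")


def classify_monotony(rho_bar: float, t: float = MONOTONY_THRESHOLD) -> str:
    """Three-way monotony class: 'up' (> t), 'down' (< -t), else 'nonuniform'."""
    if not -1 - 1e-9 <= rho_bar <= 1 + 1e-9:
        raise ValueError("rho_bar must lie in [-1, 1]")
    if rho_bar > t:
        return "up"
    if rho_bar < -t:
        return "down"
    return "nonuniform"


def find_reversals(
    classes_control: pd.Series, classes_treated: pd.Series
) -> tuple[set, set]:
    """Genes whose monotony class flips between conditions.

    Returns (up-in-control-down-in-treated, down-in-control-up-in-treated);
    nonuniform genes never participate.
    """
    common = classes_control.index.intersection(classes_treated.index)
    if len(common) == 0:
        raise ValueError("no genes classified in both conditions")
    cc = classes_control.loc[common]
    ct = classes_treated.loc[common]
    up_down = set(common[(cc == "up") & (ct == "down")])
    down_up = set(common[(cc == "down") & (ct == "up")])
    return up_down, down_up


@dataclass
class NegCorrResult:
    gene_id: str
    r_obs: float
    p_value: float
    n_iter: int
    significant: bool


def negcorr_perm_test(
    tp_control: TemporalProfile,
    tp_treated: TemporalProfile,
    n_iter: int = 1000,
    seed: int | None = 0,
) -> NegCorrResult:
    """Monte-Carlo test for negative correlation between the two conditions.

    The observed statistic is the Pearson correlation of the per-age mean
    profiles. The null permutes the chronological order of the treated
    profile; each iteration additionally picks one random replicate per
    age in both conditions. One-sided p = (#{r_null <= r_obs} + 1) /
    (n_iter + 1); a gene is significant when r_obs < 0 and p <= 0.05.
    """
    if tp_control.ages != tp_treated.ages:
        raise ValueError("profiles must share the same age grid")
    mc, mt = tp_control.means(), tp_treated.means()
    if mc.std() == 0 or mt.std() == 0:
        raise UndefinedCorrelationError(
            f"constant mean profile for gene {tp_control.gene_id}"
        )
    r_obs = float(np.corrcoef(mc, mt)[0, 1])

    rng = np.random.default_rng(seed)
    n_ages = tp_control.n_ages
    draws_c = np.column_stack(
        [
            tp_control.values[a][rng.integers(len(tp_control.values[a]), size=n_iter)]
            for a in range(n_ages)
        ]
    )
    draws_t = np.column_stack(
        [
            tp_treated.values[a][rng.integers(len(tp_treated.values[a]), size=n_iter)]
            for a in range(n_ages)
        ]
    )
    perms = rng.permuted(
        np.tile(np.arange(n_ages), (n_iter, 1)), axis=1
    )
    draws_t = np.take_along_axis(draws_t, perms, axis=1)

    c = draws_c - draws_c.mean(axis=1, keepdims=True)
    t = draws_t - draws_t.mean(axis=1, keepdims=True)
    denom = np.sqrt((c ** 2).sum(axis=1) * (t ** 2).sum(axis=1))
    r_null = np.zeros(n_iter)
    np.divide((c * t).sum(axis=1), denom, out=r_null, where=denom > 0)

    p = (np.sum(r_null <= r_obs) + 1) / (n_iter + 1)
    return NegCorrResult(
        tp_control.gene_id,
        r_obs,
        float(p),
        n_iter,
        bool(r_obs < 0 and p <= 0.05),
    )


def standardized_profiles(expr: ExpressionMatrix, genes=None) -> pd.DataFrame:
    """Concatenated control+treated mean profiles, z-scored per gene.

    The feature vector of a gene is its per-age mean in the control
    condition followed by its per-age mean under treatment, standardized
    across the 8 values so clustering sees shapes rather than magnitudes.
    """
    mean_c = expr.condition_age_means("control")
    mean_t = expr.condition_age_means("treated")
    X = pd.concat(
        [mean_c.add_prefix("c"), mean_t.add_prefix("t")], axis=1
    )
    if genes is not None:
        X = X.loc[pd.Index(genes)]
    mu = X.mean(axis=1)
    sd = X.std(axis=1, ddof=0)
    if (sd == 0).any():
        X = X[sd > 0]
        mu, sd = mu[sd > 0], sd[sd > 0]
    return X.sub(mu, axis=0).div(sd, axis=0)


@dataclass
class ClusterResult:
    membership: pd.DataFrame  # genes x clusters, rows sum to 1
    centers: np.ndarray  # clusters x features
    chosen_c: int
    fuzzifier: float
    validity: pd.DataFrame  # per candidate c: PC, Xie-Beni, silhouette, avg rank
    objectives: dict = field(default_factory=dict)


def _fcm_once(
    X: np.ndarray,
    c: int,
    m: float,
    rng: np.random.Generator,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """One fuzzy c-means run (Bezdek updates) from a random partition."""
    n = X.shape[0]
    U = rng.dirichlet(np.ones(c), size=n)
    history = []
    obj_prev = np.inf
    for _ in range(max_iter):
        W = U ** m
        centers = (W.T @ X) / W.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        obj = float((W * d2).sum())
        history.append(obj)
        inv = d2 ** (-1.0 / (m - 1.0))
        U = inv / inv.sum(axis=1, keepdims=True)
        if abs(obj_prev - obj) < tol:
            break
        obj_prev = obj
    return U, centers, history[-1], history


def fuzzy_cmeans_cluster(
    profiles: pd.DataFrame,
    c_candidates=range(2, 13),
    m: float = 2.0,
    restarts: int = 30,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> ClusterResult:
    """Fuzzy c-means over standardized profiles with validity-based c choice.

    For every candidate cluster count the best of ``restarts`` random
    starts (by objective) is kept; the cluster count is chosen by the
    best average rank over three validity indexes: partition coefficient
    (higher better), Xie-Beni (lower better) and mean silhouette of the
    hard assignment (higher better). Ties go to the smaller c.
    """
    X = profiles.to_numpy(dtype=float)
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("profiles are degenerate (all identical)")
    c_candidates = [c for c in c_candidates]
    if X.shape[0] <= max(c_candidates):
        c_candidates = [c for c in c_candidates if c < X.shape[0]]
        if not c_candidates:
            raise ValueError("too few genes for the requested cluster counts")
    rng = np.random.default_rng(seed)
    from sklearn.metrics import silhouette_score

    best = {}
    rows = []
    for c in c_candidates:
        best_run = None
        for _ in range(restarts):
            U, centers, obj, hist = _fcm_once(X, c, m, rng, tol, max_iter)
            if best_run is None or obj < best_run[2]:
                best_run = (U, centers, obj, hist)
        U, centers, obj, hist = best_run
        pc = float((U ** 2).sum() / X.shape[0])
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        sep = np.inf
        for i in range(c):
            for j in range(i + 1, c):
                sep = min(sep, ((centers[i] - centers[j]) ** 2).sum())
        xb = float(((U ** m) * d2).sum() / (X.shape[0] * sep)) if sep > 0 else np.inf
        hard = U.argmax(axis=1)
        if len(np.unique(hard)) > 1:
            sil = float(silhouette_score(X, hard))
        else:
            sil = -1.0
        best[c] = (U, centers, obj, hist)
        rows.append({"c": c, "partition_coefficient": pc, "xie_beni": xb,
                     "silhouette": sil})
    validity = pd.DataFrame(rows).set_index("c")
    ranks = pd.DataFrame(
        {
            "partition_coefficient": validity["partition_coefficient"].rank(
                ascending=False
            ),
            "xie_beni": validity["xie_beni"].rank(ascending=True),
            "silhouette": validity["silhouette"].rank(ascending=False),
        }
    )
    validity["avg_rank"] = ranks.mean(axis=1)
    chosen_c = int(validity["avg_rank"].idxmin())
    U, centers, obj, hist = best[chosen_c]
    membership = pd.DataFrame(
        U,
        index=profiles.index,
        columns=[f"cluster{j + 1}" for j in range(chosen_c)],
    )
    return ClusterResult(
        membership,
        centers,
        chosen_c,
        m,
        validity,
        objectives={c: best[c][3] for c in c_candidates},
    )
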