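import numpy as np
import pandas as pd
import pytest

from agenet.expr import CountMatrix
from agenet.simdata import SimConfig, generate_counts


def toy_design(n_per_cell=None) -> pd.DataFrame:
    """22-sample two-condition design (3/3/3/2 replicates per condition)."""
    rows = []
    reps = n_per_cell or {1: 3, 5: 3, 10: 3, 20: 2}
    for cond in ("control", "treated"):
        for age, n in reps.items():
            for r in range(1, n + 1):
                rows.append((f"{cond[0]}{age}r{r}", cond, age, r))
    return pd.DataFrame(
        rows, columns=["sample_id", "condition", "age_days", "replicate_index"]
    ).set_index("sample_id")


def make_cm(counts: np.ndarray, design: pd.DataFrame, lengths=None) -> CountMatrix:
    idx = pd.Index([f"g{i}" for i in range(counts.shape[0])], name="gene_id")
    if lengths is None:
        lengths = pd.Series(1000.0, index=idx)
    else:
        lengths = pd.Series(lengths, index=idx)
    return CountMatrix(
        pd.DataFrame(counts, index=idx, columns=design.index), lengths, design
    )


def two_group_design(n_a=3, n_b=3, age=1) -> pd.DataFrame:
    rows = [(f"c{r}", "control", age, r + 1) for r in range(n_a)]
    rows += [(f"t{r}", "treated", age, r + 1) for r in range(n_b)]
    return pd.DataFrame(
        rows, columns=["sample_id", "condition", "age_days", "replicate_index"]
    ).set_index("sample_id")


def nb_counts(rng, mu, phi):
    """Gamma-Poisson NB draw used as the independent generator in tests."""
    mu = np.asarray(mu, dtype=float)
    if phi == 0:
        return rng.poisson(mu)
    return rng.poisson(rng.gamma(1.0 / phi, mu * phi))


@pytest.fixture(scope="session")
def sim_small():
    """A small planted dataset shared by recovery tests."""
    cfg = SimConfig(n_genes=400, seed=11)
    cm, truth = generate_counts(cfg)
    return cfg, cm, truth
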