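"""Synthetic two-condition ageing time-course counts with planted truth.

Emulates the study design of a bulk RNA-seq ageing experiment on
*C. elegans*: two conditions (control vs treated) sampled at ages 1, 5,
10 and 20 days with 3/3/3/2 replicates per condition (22 samples).
Counts are negative-binomial (Gamma-Poisson mixture; variance
mu + phi * mu^2, phi = 0 degenerating to Poisson) around a log-linear
gene model that plants five recoverable gene classes:

* null genes - constant expected expression;
* per-age DE genes - a single age at which the treated mean is shifted
  by +-de_log2fc;
* monotone-up / monotone-down genes - expected log2 expression changes
  by +-monotone_slope per age step in both conditions;
* anti-correlated genes - monotone-up in one condition and monotone-down
  in the other, mimicking genes that reverse their ageing trend under
  treatment;
* co-expression modules - blocks of null-class genes sharing a latent
  per-sample factor whose coupling strength differs between conditions,
  so difference networks have planted signal.

Library sizes are jittered (default +-20%) so normalization is exercised;
gene lengths are log-normal (clamped to >= 150 bp) so RPKM is defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expr import AGES, CONDITIONS, CountMatrix

__all__ = ["SimConfig", "ConfigurationError", "generate_counts", "write_dataset"]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Configuration of the synthetic time-course generator.

    class_fractions maps {"de", "mono_up", "mono_down", "anticorr"} to
    gene-fraction values; the remainder of the genes are null. Module
    genes are drawn from the null block so that module coupling is not
    confounded with planted trends.
    """

    n_genes: int = 2000
    replicate_design: tuple[int, ...] = (3, 3, 3, 2)  # per condition, per age
    ages: tuple[int, ...] = AGES
    class_fractions: dict = field(
        default_factory=lambda: {
            "de": 0.10,
            "mono_up": 0.05,
            "mono_down": 0.05,
            "anticorr": 0.05,
        }
    )
    de_log2fc: float = 2.0
    monotone_slope: float = 0.8  # log2 units per age step
    phi_sim: float = 0.05  # NB dispersion: var = mu + phi * mu^2
    # (size, coupling_control, coupling_treated): by default one module is
    # co-expressed only under treatment and one only in controls, the
    # clearest between-condition coupling change
    modules: tuple = ((20, 0.0, 0.9), (20, 0.9, 0.0))
    # latent-factor scale (log2 units): large vs the ~0.2 log2 measurement
    # noise, so a fully coupled module is tightly co-expressed (|r| near 1)
    # for typical trajectory draws, as real pathway modules are
    module_factor_sd: float = 2.0
    length_lognormal: tuple[float, float] = (7.3, 0.6)  # (mu, sigma) of ln length
    lib_size: float = 2e6  # expected reads per sample
    lib_jitter: float = 0.2
    base_log_sd: float = 1.0  # spread of baseline expression (ln scale)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if any(r <= 0 for r in self.replicate_design):
            raise ConfigurationError("replicate counts must be positive")
        if len(self.replicate_design) != len(self.ages):
            raise ConfigurationError("replicate_design must match the age grid")
        if self.phi_sim < 0:
            raise ConfigurationError("phi_sim must be >= 0")
        fracs = self.class_fractions
        if any(f < 0 for f in fracs.values()) or sum(fracs.values()) > 1 + 1e-12:
            raise ConfigurationError("class fractions must be >= 0 and sum to <= 1")
        unknown = set(fracs) - {"de", "mono_up", "mono_down", "anticorr"}
        if unknown:
            raise ConfigurationError(f"unknown gene classes: {sorted(unknown)}")
        for size, cc, ct in self.modules:
            if size <= 0:
                raise ConfigurationError("module sizes must be positive")
            if not (0 <= cc <= 1 and 0 <= ct <= 1):
                raise ConfigurationError("module couplings must lie in [0, 1]")
        if self.lib_size <= 0:
            raise ConfigurationError("lib_size must be positive")


def _sample_design(config: SimConfig) -> pd.DataFrame:
    rows = []
    for cond in CONDITIONS:
        for age, n_rep in zip(config.ages, config.replicate_design):
            for r in range(1, n_rep + 1):
                rows.append(
                    {
                        "sample_id": f"{cond[0].upper()}{age:02d}d_r{r}",
                        "condition": cond,
                        "age_days": age,
                        "replicate_index": r,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Negative-binomial counts via the Gamma-Poisson mixture.

    phi = 0 is the Poisson special case (the Gamma shape would be infinite).
    """
    if phi == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    return rng.poisson(lam)


def generate_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate a count matrix and the planted truth table.

    Returns the CountMatrix (genes x 22 samples under the default design)
    and a per-gene truth DataFrame with columns ``class``, ``de_age``,
    ``de_direction``, ``mono_control``, ``mono_treated``, ``anticorr``,
    ``module_id``. Identical config (including seed) gives bit-identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    ages = list(config.ages)
    design = _sample_design(config)
    n_samples = len(design)
    gene_ids = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")

    # gene classes, assigned to contiguous blocks of a shuffled order
    n_de = int(round(config.class_fractions.get("de", 0) * n))
    n_up = int(round(config.class_fractions.get("mono_up", 0) * n))
    n_down = int(round(config.class_fractions.get("mono_down", 0) * n))
    n_anti = int(round(config.class_fractions.get("anticorr", 0) * n))
    n_module = sum(size for size, _, _ in config.modules)
    if n_de + n_up + n_down + n_anti + n_module > n:
        raise ConfigurationError("gene classes plus modules exceed n_genes")
    order = rng.permutation(n)
    labels = np.array(["null"] * n, dtype=object)
    cursor = 0
    blocks = {}
    for name, size in (
        ("de", n_de),
        ("mono_up", n_up),
        ("mono_down", n_down),
        ("anticorr", n_anti),
    ):
        blocks[name] = order[cursor : cursor + size]
        labels[blocks[name]] = name
        cursor += size
    module_id = np.array([""] * n, dtype=object)
    module_blocks = []
    for m, (size, _, _) in enumerate(config.modules):
        idx = order[cursor : cursor + size]
        module_blocks.append(idx)
        module_id[idx] = f"mod{m}"
        cursor += size

    lengths = np.exp(
        rng.normal(config.length_lognormal[0], config.length_lognormal[1], size=n)
    )
    lengths = np.maximum(np.round(lengths), 150.0)

    # baseline expected counts, scaled to the target library size
    rel = np.exp(rng.normal(0.0, config.base_log_sd, size=n))
    base = rel / rel.sum() * config.lib_size

    # planted per-gene effects on log2 scale: (gene, condition, age)
    effect = np.zeros((n, 2, len(ages)))
    age_step = np.arange(len(ages), dtype=float)
    de_age = np.full(n, -1)
    de_dir = np.array([""] * n, dtype=object)
    for g in blocks["de"]:
        a = rng.integers(len(ages))
        d = 1 if rng.random() < 0.5 else -1
        de_age[g] = ages[a]
        de_dir[g] = "up" if d > 0 else "down"
        effect[g, 1, a] += d * config.de_log2fc  # treated only
    slope = config.monotone_slope
    effect[blocks["mono_up"], :, :] += slope * age_step
    effect[blocks["mono_down"], :, :] -= slope * age_step
    anti_flip = rng.random(len(blocks["anticorr"])) < 0.5
    mono_c = np.array(["none"] * n, dtype=object)
    mono_t = np.array(["none"] * n, dtype=object)
    mono_c[blocks["mono_up"]] = "up"
    mono_t[blocks["mono_up"]] = "up"
    mono_c[blocks["mono_down"]] = "down"
    mono_t[blocks["mono_down"]] = "down"
    for g, flip in zip(blocks["anticorr"], anti_flip):
        d = -1 if flip else 1  # control direction
        effect[g, 0, :] += d * slope * age_step
        effect[g, 1, :] -= d * slope * age_step
        mono_c[g] = "up" if d > 0 else "down"
        mono_t[g] = "down" if d > 0 else "up"

    # expected counts per sample: baseline * planted effect * module factor
    cond_index = (design["condition"] == "treated").to_numpy().astype(int)
    age_index = np.array([ages.index(a) for a in design["age_days"]])
    log2_mu = np.log2(base)[:, None] + effect[:, cond_index, age_index]
    # module latent factor: one trajectory per (condition, age) shared by all
    # replicates, so module co-expression survives replicate resampling
    for idx, (_, cc, ct) in zip(module_blocks, config.modules):
        z = rng.normal(0.0, config.module_factor_sd, size=(2, len(ages)))
        coupling = np.where(cond_index == 1, ct, cc)
        log2_mu[idx, :] += coupling * z[cond_index, age_index]

    lib_factor = 1.0 + rng.uniform(
        -config.lib_jitter, config.lib_jitter, size=n_samples
    )
    mu = 2.0 ** log2_mu * lib_factor[None, :]
    counts = _nb_draw(rng, mu, config.phi_sim).astype(np.int64)

    cm = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=design.index),
        pd.Series(lengths, index=gene_ids, name="length_bp"),
        design,
    )
    truth = pd.DataFrame(
        {
            "class": labels,
            "de_age": de_age,
            "de_direction": de_dir,
            "mono_control": mono_c,
            "mono_treated": mono_t,
            "anticorr": labels == "anticorr",
            "module_id": module_id,
        },
        index=gene_ids,
    )
    return cm, truth


def write_dataset(
    cm: CountMatrix, truth: pd.DataFrame, out_dir, prefix: str = "sim"
) -> dict[str, Path]:
    """Write counts/metadata/lengths/truth TSVs; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out_dir / f"{prefix}_counts.tsv",
        "metadata": out_dir / f"{prefix}_metadata.tsv",
        "lengths": out_dir / f"{prefix}_lengths.tsv",
        "truth": out_dir / f"{prefix}_truth.tsv",
    }
    cm.write(paths["counts"], paths["metadata"], paths["lengths"])
    t = truth.copy()
    t.index.name = "gene_id"
    t.to_csv(paths["truth"], sep="\t")
    return paths
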