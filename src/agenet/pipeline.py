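"""End-to-end orchestration: deterministic runs producing a text artifact dir.

A run either loads a real count matrix (counts/metadata/lengths TSVs,
optionally a GMT of gene sets) or simulates one with planted truth, then
executes the enabled stages:

``mds``      sample dissimilarity + classical scaling coordinates;
``deg``      per-age consensus NB differential expression + summary +
             constant-DEG intersection;
``temporal`` monotony classification, reversal sets, negative-correlation
             permutation test, fuzzy clustering of significant genes;
``corrnet``  per-condition correlation networks, power-law fits,
             difference network, connectivity enrichment;
``minet``    MI networks per gene set, DPI pruning, topology parameters,
             percentage changes and hub turnover.

One global seed deterministically derives independent stage seeds, so a
repeated run writes byte-identical tables. All artifacts are TSV, JSON,
GMT or GraphML; plotting is opt-in.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .expr import (
    CountMatrix,
    compute_rpkm,
    drop_zero_genes,
    filter_low_counts,
    log2_transform,
    read_counts,
)
from .simdata import SimConfig, generate_counts, write_dataset
from . import corrnet, diffexpr, mds, minet_stats, temporal

logger = logging.getLogger("agenet")

ALL_STAGES = ("mds", "deg", "temporal", "corrnet", "minet")


class DependencyError(RuntimeError):
    pass


class ReportError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the study defaults."""

    # inputs: either paths ...
    counts_path: str | None = None
    meta_path: str | None = None
    lengths_path: str | None = None
    gmt_path: str | None = None
    # ... or simulation mode
    sim: SimConfig | None = None

    min_count: int = 100  # low-count exclusion for DE testing
    alpha_deg: float = 0.01  # 99% confidence consensus calls
    alpha_edge: float = 0.05  # correlation-network p cutoff
    monotony_t: float = temporal.MONOTONY_THRESHOLD
    monotony_B: int = 100
    tau: float = corrnet.TAU_DEFAULT  # difference-network pruning
    n_draws: int = 100  # replicate resamplings for correlations
    n_iter: int = 1000  # permutation iterations
    mi_max: float = minet_stats.MI_MAX_DEFAULT
    hub_n_sd: float = 1.0
    gene_cap: int = 3000  # most-variable-gene cap for all-pairs stages
    background_size: int = 100  # background gene set for MI networks
    cluster_candidates: tuple[int, ...] = tuple(range(2, 13))
    cluster_restarts: int = 30
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    plots: bool = False

    def validate(self) -> None:
        if self.sim is None and not (
            self.counts_path and self.meta_path and self.lengths_path
        ):
            raise ValueError("either sim config or count/meta/length paths required")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for name, lo, hi, v in (
            ("alpha_deg", 0, 1, self.alpha_deg),
            ("alpha_edge", 0, 1, self.alpha_edge),
            ("monotony_t", 0, 1, self.monotony_t),
            ("tau", 0, 1, self.tau),
        ):
            if not lo <= v <= hi:
                raise ValueError(f"{name} must lie in [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            if "modules" in sim_raw:
                sim_raw["modules"] = tuple(tuple(m) for m in sim_raw["modules"])
            cfg.sim = SimConfig(**sim_raw)
        return cfg


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ("sim", "mds", "deg", "temporal", "corrnet", "minet")
    children = ss.spawn(len(names))
    return {
        n: int(c.generate_state(1)[0] % (2 ** 31)) for n, c in zip(names, children)
    }


def _write_tsv(df: pd.DataFrame, path: Path, index_label="gene_id") -> None:
    df = df.copy()
    df.index.name = index_label
    df.to_csv(path, sep="\t", float_format="%.6g")


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the enabled stages and write the artifact directory.

    Returns a dict of in-memory stage results (also all persisted as
    text files under ``out_dir``).
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    results: dict = {}
    manifest = {
        "agenet_version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages_run": [],
        "stages_skipped": [],
        "config": _jsonable_config(config),
    }

    # ------------------------------------------------------------------ input
    if config.sim is not None:
        sim_cfg = config.sim
        cm, truth = generate_counts(sim_cfg)
        write_dataset(cm, truth, out, prefix="sim")
        cm = read_counts(  # round-trip so real and sim modes share one path
            out / "sim_counts.tsv", out / "sim_metadata.tsv", out / "sim_lengths.tsv"
        )
        results["truth"] = truth
        gene_sets = _simulated_gene_sets(truth, seeds["sim"])
        corrnet.write_gmt(gene_sets, out / "gene_sets.gmt")
    else:
        for p in (config.counts_path, config.meta_path, config.lengths_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        cm = read_counts(config.counts_path, config.meta_path, config.lengths_path)
        gene_sets = (
            corrnet.read_gmt(config.gmt_path) if config.gmt_path else {}
        )
    results["counts"] = cm
    logger.info("count matrix: %d genes x %d samples", cm.n_genes, cm.n_samples)

    # expressed-gene universe for temporal/network stages: non-zero in both
    # conditions (the DE stage applies the stricter low-count rule instead)
    cm_expr = drop_zero_genes(drop_zero_genes(cm, "control"), "treated")
    rpkm = compute_rpkm(cm)  # totals from the unfiltered matrix
    rpkm_expr = type(rpkm)(
        rpkm.values.loc[cm_expr.gene_ids], rpkm.design, rpkm.is_log2
    )
    log_expr = log2_transform(rpkm_expr)
    logger.info("expressed genes (non-zero in both conditions): %d", cm_expr.n_genes)

    # ------------------------------------------------------------------- mds
    if "mds" in config.stages:
        diss = mds.sample_dissimilarity(log_expr)
        emb = mds.classical_mds(diss, k=2)
        _write_tsv(diss, out / "sample_dissimilarity.tsv", "sample_id")
        _write_tsv(emb.coords, out / "mds_coordinates.tsv", "sample_id")
        if config.plots:
            mds.plot_embedding(emb, cm.design, out / "mds_plot.png")
        results["mds"] = emb
        manifest["stages_run"].append("mds")
    else:
        manifest["stages_skipped"].append("mds")

    # ------------------------------------------------------------------- deg
    if "deg" in config.stages:
        cm_deg = filter_low_counts(cm, config.min_count)
        logger.info("genes passing the low-count filter: %d", cm_deg.n_genes)
        ages = sorted(cm.design["age_days"].unique())
        tables, summaries = {}, []
        for age in ages:
            res = diffexpr.call_deg(cm_deg, age, alpha=config.alpha_deg)
            tables[age] = res.table
            summaries.append(res.summary)
            _write_tsv(res.table, out / f"deg_age{age}.tsv")
        summary_df = pd.DataFrame(summaries).set_index("age_days")
        _write_tsv(summary_df, out / "deg_summary.tsv", "age_days")
        always_up, always_down = (
            diffexpr.constant_deg(tables) if len(tables) >= 4 else (set(), set())
        )
        with open(out / "constant_deg.json", "w") as fh:
            json.dump(
                {"always_up": sorted(always_up), "always_down": sorted(always_down)},
                fh,
                indent=1,
            )
        results["deg"] = {
            "tables": tables,
            "summary": summary_df,
            "constant": (always_up, always_down),
        }
        manifest["stages_run"].append("deg")
    else:
        manifest["stages_skipped"].append("deg")

    # -------------------------------------------------------------- temporal
    if "temporal" in config.stages:
        results["temporal"] = _run_temporal(config, log_expr, out, seeds["temporal"])
        manifest["stages_run"].append("temporal")
    else:
        manifest["stages_skipped"].append("temporal")

    # --------------------------------------------------------------- corrnet
    if "corrnet" in config.stages:
        results["corrnet"] = _run_corrnet(
            config, log_expr, gene_sets, out, seeds["corrnet"]
        )
        manifest["stages_run"].append("corrnet")
    else:
        manifest["stages_skipped"].append("corrnet")

    # ----------------------------------------------------------------- minet
    if "minet" in config.stages:
        results["minet"] = _run_minet(config, log_expr, gene_sets, out, seeds["minet"])
        manifest["stages_run"].append("minet")
    else:
        manifest["stages_skipped"].append("minet")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return results


def _jsonable_config(config: PipelineConfig) -> dict:
    d = asdict(config)
    if d.get("sim") is not None:
        d["sim"] = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in d["sim"].items()
        }
    return {
        k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()
    }


def _simulated_gene_sets(truth: pd.DataFrame, seed: int) -> dict[str, set]:
    """Gene sets for enrichment in simulation mode: planted modules + decoys.

    Decoy sets are random same-sized draws from the gene universe so the
    enrichment ranking of the planted differential-coupling modules is a
    meaningful recovery check.
    """
    rng = np.random.default_rng(seed)
    sets: dict[str, set] = {}
    module_ids = sorted(m for m in truth["module_id"].unique() if m)
    sizes = []
    for m in module_ids:
        members = set(truth.index[truth["module_id"] == m])
        sets[m] = members
        sizes.append(len(members))
    universe = np.array(truth.index)
    for i in range(20):
        size = sizes[i % len(sizes)] if sizes else 20
        sets[f"decoy{i:02d}"] = set(rng.choice(universe, size=size, replace=False))
    return sets


def _run_temporal(config: PipelineConfig, log_expr, out: Path, seed: int) -> dict:
    pset_c = temporal.profiles_from_expression(log_expr, "control")
    pset_t = temporal.profiles_from_expression(log_expr, "treated")
    rho_c = temporal.monotony_scores(pset_c, B=config.monotony_B, seed=seed)
    rho_t = temporal.monotony_scores(pset_t, B=config.monotony_B, seed=seed + 1)
    cls_c = rho_c.map(lambda r: temporal.classify_monotony(r, config.monotony_t))
    cls_t = rho_t.map(lambda r: temporal.classify_monotony(r, config.monotony_t))
    table = pd.DataFrame(
        {
            "rho_bar_control": rho_c,
            "class_control": cls_c,
            "rho_bar_treated": rho_t,
            "class_treated": cls_t,
        }
    )
    _write_tsv(table, out / "monotony.tsv")
    up_down, down_up = temporal.find_reversals(cls_c, cls_t)
    with open(out / "reversals.json", "w") as fh:
        json.dump(
            {"up_to_down": sorted(up_down), "down_to_up": sorted(down_up)},
            fh,
            indent=1,
        )

    rows = []
    rng = np.random.default_rng(seed + 2)
    for gene in log_expr.gene_ids:
        tp_c, tp_t = pset_c.get(gene), pset_t.get(gene)
        if tp_c.means().std() == 0 or tp_t.means().std() == 0:
            continue
        res = temporal.negcorr_perm_test(
            tp_c, tp_t, n_iter=config.n_iter, seed=int(rng.integers(2 ** 31))
        )
        rows.append(
            {
                "gene_id": gene,
                "r_obs": res.r_obs,
                "p_value": res.p_value,
                "significant": res.significant,
            }
        )
    negcorr = pd.DataFrame(rows).set_index("gene_id")
    _write_tsv(negcorr, out / "negcorr.tsv")

    sig_genes = list(negcorr.index[negcorr["significant"]])
    cluster = None
    if len(sig_genes) > max(config.cluster_candidates):
        profiles = temporal.standardized_profiles(log_expr, sig_genes)
        cluster = temporal.fuzzy_cmeans_cluster(
            profiles,
            c_candidates=config.cluster_candidates,
            restarts=config.cluster_restarts,
            seed=seed + 3,
        )
        _write_tsv(cluster.membership, out / "cluster_membership.tsv")
        _write_tsv(cluster.validity, out / "cluster_validity.tsv", "c")
    logger.info(
        "temporal: %d reversals, %d significantly negatively correlated genes",
        len(up_down) + len(down_up),
        len(sig_genes),
    )
    return {
        "monotony": table,
        "reversals": (up_down, down_up),
        "negcorr": negcorr,
        "cluster": cluster,
    }


def _most_variable(log_expr, cap: int):
    var = log_expr.values.var(axis=1)
    keep = var.sort_values(ascending=False).index[:cap].sort_values()
    return type(log_expr)(
        log_expr.values.loc[keep], log_expr.design, log_expr.is_log2
    )


def _run_corrnet(config, log_expr, gene_sets, out: Path, seed: int) -> dict:
    sub = _most_variable(log_expr, config.gene_cap)
    nets, fits, matrices = {}, {}, {}
    for i, cond in enumerate(("control", "treated")):
        pset = temporal.profiles_from_expression(sub, cond)
        r_bar, p_bar = corrnet.resampled_correlation_matrix(
            pset, n_draws=config.n_draws, seed=seed + i
        )
        matrices[cond] = (r_bar, p_bar)
        net = corrnet.build_corr_network(
            pset, alpha=config.alpha_edge, matrices=(r_bar, p_bar)
        )
        nets[cond] = net
        corrnet.write_edgelist(net, out / f"corr_network_{cond}.tsv")
        try:
            fit = corrnet.fit_power_law(net)
        except ValueError:
            fit = None
        fits[cond] = fit
    dn = corrnet.difference_network(
        matrices["control"][0], matrices["treated"][0], tau=config.tau
    )
    corrnet.write_edgelist(dn, out / "difference_network.tsv")
    enrichment, skipped = (
        corrnet.connectivity_enrichment(dn, gene_sets)
        if gene_sets
        else (pd.DataFrame(), [])
    )
    if len(enrichment):
        enrichment.set_index("set_id").to_csv(
            out / "difference_enrichment.tsv", sep="\t", float_format="%.6g"
        )
    with open(out / "corrnet_summary.json", "w") as fh:
        json.dump(
            {
                cond: {
                    "n_nodes": nets[cond].number_of_nodes(),
                    "n_edges": nets[cond].number_of_edges(),
                    "gamma": fits[cond].gamma if fits[cond] else None,
                    "r_squared": fits[cond].r_squared if fits[cond] else None,
                }
                for cond in nets
            }
            | {"difference_edges": dn.number_of_edges(), "skipped_sets": skipped},
            fh,
            indent=1,
            sort_keys=True,
        )
    logger.info(
        "corrnet: control %d edges, treated %d edges, difference %d edges",
        nets["control"].number_of_edges(),
        nets["treated"].number_of_edges(),
        dn.number_of_edges(),
    )
    return {
        "networks": nets,
        "fits": fits,
        "matrices": matrices,
        "difference": dn,
        "enrichment": enrichment,
    }


def _run_minet(config, log_expr, gene_sets, out: Path, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    universe = list(log_expr.gene_ids)
    sel: dict[str, list] = {}
    bg = min(config.background_size, len(universe))
    sel["background"] = sorted(rng.choice(universe, size=bg, replace=False))
    for set_id, members in gene_sets.items():
        if set_id.startswith("decoy"):
            continue
        present = sorted(set(members) & set(universe))
        if len(present) >= 5:
            sel[set_id] = present

    stats_rows, hub_rows = [], []
    turnover = {}
    per_set = {}
    for set_id, genes in sel.items():
        reports = {}
        stats_by_cond = {}
        for cond in ("control", "treated"):
            means = log_expr.condition_age_means(cond).loc[genes]
            mi = minet_stats.mi_matrix(means, mi_max=config.mi_max)
            net = minet_stats.dpi_prune(mi)
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                st = minet_stats.network_stats(net)
            stats_by_cond[cond] = st
            reports[cond] = minet_stats.find_hubs(net, n_sd=config.hub_n_sd)
            for param, value in st.as_dict().items():
                stats_rows.append(
                    {
                        "gene_set": set_id,
                        "condition": cond,
                        "parameter": param,
                        "value": value,
                    }
                )
        delta = minet_stats.percent_change(
            stats_by_cond["control"], stats_by_cond["treated"]
        )
        for param, value in delta.items():
            stats_rows.append(
                {
                    "gene_set": set_id,
                    "condition": "percent_change",
                    "parameter": param,
                    "value": value,
                }
            )
        gained, lost = minet_stats.hub_turnover(reports["control"], reports["treated"])
        turnover[set_id] = {"gained": sorted(gained), "lost": sorted(lost)}
        for cond in ("control", "treated"):
            for g in sorted(reports[cond].hubs):
                hub_rows.append({"gene_set": set_id, "condition": cond, "hub": g})
        per_set[set_id] = {
            "stats": stats_by_cond,
            "delta": delta,
            "reports": reports,
        }
    pd.DataFrame(stats_rows).to_csv(
        out / "mi_network_stats.tsv", sep="\t", index=False, float_format="%.6g"
    )
    pd.DataFrame(hub_rows).to_csv(out / "mi_hubs.tsv", sep="\t", index=False)
    with open(out / "mi_hub_turnover.json", "w") as fh:
        json.dump(turnover, fh, indent=1, sort_keys=True)
    logger.info("minet: %d gene sets analysed", len(sel))
    return {"sets": per_set, "turnover": turnover}


def summarize_run(artifact_dir) -> pd.DataFrame:
    """Condensed per-run report recomputed from the stage output tables.

    Returns a long-format DataFrame (section, key, value) and writes
    nothing; raises ReportError naming any missing artifact file.
    """
    art = Path(artifact_dir)
    required = ["deg_summary.tsv", "monotony.tsv", "negcorr.tsv", "manifest.json"]
    missing = [f for f in required if not (art / f).exists()]
    if missing:
        raise ReportError(f"incomplete artifact directory, missing: {missing}")
    rows = []
    deg = pd.read_csv(art / "deg_summary.tsv", sep="\t", index_col="age_days")
    for age, row in deg.iterrows():
        total, down = int(row["n_total"]), int(row["n_down"])
        frac = 100.0 * down / total if total else 0.0
        rows.append(("deg", f"n_total_age{age}", total))
        rows.append(("deg", f"fraction_down_age{age}", round(frac, 4)))
    mono = pd.read_csv(art / "monotony.tsv", sep="\t", index_col="gene_id")
    for cond in ("control", "treated"):
        counts = mono[f"class_{cond}"].value_counts()
        for cls in ("up", "down", "nonuniform"):
            rows.append(("monotony", f"{cond}_{cls}", int(counts.get(cls, 0))))
    with open(art / "reversals.json") as fh:
        rev = json.load(fh)
    rows.append(("reversals", "up_to_down", len(rev["up_to_down"])))
    rows.append(("reversals", "down_to_up", len(rev["down_to_up"])))
    neg = pd.read_csv(art / "negcorr.tsv", sep="\t", index_col="gene_id")
    rows.append(("negcorr", "n_significant", int(neg["significant"].sum())))
    stats_path = art / "mi_network_stats.tsv"
    if stats_path.exists():
        ms = pd.read_csv(stats_path, sep="\t")
        pc = ms[ms["condition"] == "percent_change"]
        for _, r in pc.iterrows():
            rows.append(
                ("mi_percent_change", f"{r['gene_set']}_{r['parameter']}", r["value"])
            )
    report = pd.DataFrame(rows, columns=["section", "key", "value"])
    report.to_csv(art / "report.tsv", sep="\t", index=False)
    return report
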