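"""End-to-end orchestration of the four analysis stages.

A single JSON-serializable config drives simulate -> decay-fit -> pairs ->
coupling.  Every output table carries a provenance header (package
version, config JSON, root seed) from which the run can be reproduced
byte-for-byte.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import coupling, decay, io, pairs, synthetic

log = logging.getLogger(__name__)

LN2 = np.log(2.0)

STAGES = ("simulate", "decay_fit", "pairs", "coupling")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "stages": list(STAGES),
    "simulate": {
        "decay": {
            "n_genes": 12,
            "model": "independent",
            "sd_bio": 0.7,
            "sd_noise": 0.1,
            "timepoints": [0, 20, 40, 60],
            "n_replicates": 3,
            "t_half_median": 20.0,
            "t_half_sd_log2": 0.5,
        },
        "genome": {
            "n_divergent": 150,
            "n_convergent": 150,
            "n_tandem": 150,
            "coupling_strength": 0.7,
            "length_coupling_scale": None,
        },
        "labeling": {
            "n_genes": 2000,
            "model": "coupled",
            "beta": 2.0,
            "t_label": 60.0,
            "replicate_sd": 0.1,
            "capture_sd": 0.5,
        },
        "regulators": {
            "n_genes": 300,
            "n_regulators": 30,
            "targets_per_regulator": 30,
        },
    },
    "decay_fit": {
        "reference": None,  # None -> levels used as-is (already relative)
        "interval": 20.0,
        "alpha": 0.05,
        "mode": "pooled",
        "banned_references": [],
    },
    "pairs": {
        "n_bins": 4,
        "binned_method": "spearman",
        "unbinned_method": "pearson",
        "min_shared": 3,
        "n_strata": 5,
    },
    "coupling": {
        "fold": 1.75,
        "t_label": 60.0,
        "center": "median",
        "min_intensity_quantile": 0.05,
        "max_abs_delta": 5.0,
        "best_fit_fraction": None,
        "null_seed": 0,
    },
}


def merge_config(overrides: dict | None) -> dict:
    """DEFAULT_CONFIG with nested overrides applied."""

    def merge(base, over):
        out = copy.deepcopy(base)
        for key, val in (over or {}).items():
            if isinstance(val, dict) and isinstance(out.get(key), dict):
                out[key] = merge(out[key], val)
            else:
                out[key] = val
        return out

    return merge(DEFAULT_CONFIG, overrides)


def validate_config(config: dict, outdir: Path) -> None:
    unknown = set(config.get("stages", [])) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)} (valid: {STAGES})")
    cc = config["coupling"]
    if not cc["fold"] > 1:
        raise ValueError("coupling.fold must be > 1")
    if not 0 < config["decay_fit"]["alpha"] < 1:
        raise ValueError("decay_fit.alpha must be in (0, 1)")
    stages = config["stages"]
    if "simulate" not in stages:
        # downstream stages need their inputs on disk before running
        needed = {
            "decay_fit": ["timecourse.tsv", "half_lives.tsv"],
            "pairs": ["genome.bed", "gene_changes.tsv", "expression.tsv"],
            "coupling": ["total_1.tsv", "total_2.tsv", "new_1.tsv",
                         "new_2.tsv", "orthologs.tsv"],
        }
        for stage in stages:
            for fname in needed.get(stage, []):
                if not (outdir / fname).exists():
                    raise FileNotFoundError(
                        f"stage {stage!r} needs {outdir / fname} "
                        "(run the simulate stage or provide inputs)"
                    )


def _provenance(config: dict) -> dict:
    blob = json.dumps(config, sort_keys=True)
    return {
        "seed": config["seed"],
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "config": config,
    }


def run_pipeline(config: dict | None, outdir) -> dict:
    """Execute the toggled stages; returns a dict of result summaries."""
    config = merge_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    validate_config(config, outdir)
    prov = _provenance(config)
    seed = int(config["seed"])
    results: dict = {}

    if "simulate" in config["stages"]:
        results["simulate"] = _stage_simulate(config, outdir, prov, seed)
    if "decay_fit" in config["stages"]:
        results["decay_fit"] = _stage_decay_fit(config, outdir, prov)
    if "pairs" in config["stages"]:
        results["pairs"] = _stage_pairs(config, outdir, prov)
    if "coupling" in config["stages"]:
        results["coupling"] = _stage_coupling(config, outdir, prov, seed)
    return results


def _stage_simulate(config, outdir, prov, seed):
    sim = config["simulate"]

    dc = sim["decay"]
    scen = synthetic.CouplingScenario(
        model=dc["model"], n_genes=dc["n_genes"],
        sd_bio=dc["sd_bio"], seed=seed,
    )
    kin = synthetic.simulate_kinetics(
        scen, t_half_median=dc["t_half_median"],
        t_half_sd_log2=dc["t_half_sd_log2"], gene_prefix="yd",
    )
    course = synthetic.simulate_decay_timecourse(
        kin, dc["timepoints"], sd_noise=dc["sd_noise"],
        n_replicates=dc["n_replicates"], seed=seed,
    )
    io.write_table(course, outdir / "timecourse.tsv", prov)
    half = pd.DataFrame(
        {"gene": kin["gene"], "t_half_min": LN2 / kin["k_deg_1"]}
    )
    io.write_table(half, outdir / "half_lives.tsv", prov)
    io.write_table(kin, outdir / "kinetics_truth.tsv", prov)

    gc = sim["genome"]
    layout = synthetic.simulate_genome(
        gc["n_divergent"], gc["n_convergent"], gc["n_tandem"],
        coupling_strength=gc["coupling_strength"],
        length_coupling_scale=gc["length_coupling_scale"], seed=seed,
    )
    io.write_bed(layout.genes, outdir / "genome.bed", prov)
    io.write_table(layout.changes, outdir / "gene_changes.tsv", prov)
    io.write_table(
        layout.expression.rename_axis("gene").reset_index(),
        outdir / "expression.tsv", prov,
    )

    lc = sim["labeling"]
    lscen = synthetic.CouplingScenario(
        model=lc["model"], n_genes=lc["n_genes"],
        beta=lc.get("beta", 0.0) if lc["model"] != "independent" else 0.0,
        seed=seed,
    )
    lkin = synthetic.simulate_kinetics(lscen, gene_prefix="mt")
    lab = synthetic.simulate_labeling(
        lkin, lc["t_label"], sd_noise=lc["replicate_sd"],
        sd_assay=lscen.sd_noise, capture_sd=lc["capture_sd"], seed=seed,
    )
    for name in ("total_1", "total_2", "new_1", "new_2"):
        mat = getattr(lab, name)
        io.write_table(
            mat.rename_axis("gene").reset_index(), outdir / f"{name}.tsv", prov
        )
    io.write_table(lab.ortholog_map, outdir / "orthologs.tsv", prov)
    io.write_table(lkin, outdir / "labeling_truth.tsv", prov)

    rc = sim["regulators"]
    matrix, gstats = synthetic.simulate_regulator_matrix(
        rc["n_genes"], rc["n_regulators"], rc["targets_per_regulator"],
        seed=seed,
    )
    io.write_table(
        matrix.rename_axis("regulator").reset_index(),
        outdir / "regulators.tsv", prov,
    )
    io.write_table(gstats, outdir / "regulator_gene_stats.tsv", prov)
    return {"n_decay_genes": dc["n_genes"], "n_labeling_genes": lc["n_genes"]}


def _stage_decay_fit(config, outdir, prov):
    dfc = config["decay_fit"]
    course = io.read_table(
        outdir / "timecourse.tsv",
        schema=["gene", "strain", "replicate", "time_min", "level"],
    )
    half = io.read_table(
        outdir / "half_lives.tsv", schema=["gene", "t_half_min"]
    ).set_index("gene")["t_half_min"]

    reference = dfc["reference"]
    if reference in dfc.get("banned_references", []):
        raise ValueError(f"reference gene {reference!r} is banned by config")
    rows = []
    for gene in course["gene"].unique():
        if gene == reference:
            continue
        if reference is None:
            sub = course[course["gene"] == gene]
            ratios = (
                sub.pivot_table(index=["replicate", "time_min"],
                                columns="strain", values="level")
            )
            y = np.log2(ratios["SW"] / ratios["WT"]).rename("log2_ratio")
            y = y.reset_index()
            fit = decay.fit_decay_slope(
                y["time_min"], y["log2_ratio"], mode=dfc["mode"]
            )
            sw_rel = sub[sub["strain"] == "SW"][
                ["replicate", "time_min", "level"]]
            wt_rel = sub[sub["strain"] == "WT"][
                ["replicate", "time_min", "level"]]
            t_stat, p = decay.paired_interval_test(
                sw_rel, wt_rel, dfc["interval"])
            d_swap = float(y.loc[y["time_min"] == 0, "log2_ratio"].mean())
            try:
                d_deg = decay.delta_deg(fit.slope, float(half.loc[gene]))
            except ValueError:
                d_deg = float("nan")
            rows.append(decay.SwapEffect(
                gene=gene, delta_swap=d_swap, slope=fit.slope,
                slope_stderr=fit.stderr, delta_deg=d_deg, t_statistic=t_stat,
                p_value=p,
                classification=decay.classify_effect(
                    fit.slope, p, dfc["alpha"]),
            ))
        else:
            rows.append(decay.analyze_gene(
                course, gene, reference, float(half.loc[gene]),
                interval=dfc["interval"], alpha=dfc["alpha"],
                mode=dfc["mode"],
            ))
    effects = pd.DataFrame([vars(r) for r in rows])
    io.write_table(effects, outdir / "swap_effects.tsv", prov)
    return {"n_genes": len(effects),
            "n_significant": int((effects["p_value"] <= dfc["alpha"]).sum())}


def _stage_pairs(config, outdir, prov):
    pc = config["pairs"]
    genes = io.read_annotation(outdir / "genome.bed")
    changes = io.read_table(
        outdir / "gene_changes.tsv", schema=["gene", "delta_deg"]
    ).set_index("gene")
    expression = io.read_matrix(outdir / "expression.tsv")

    pair_table, report = pairs.classify_pairs(genes)
    values = changes["delta_deg"]
    unbinned = pairs.pair_correlation(
        pair_table, values, method=pc["unbinned_method"])
    io.write_table(unbinned.reset_index(), outdir / "pair_correlations.tsv", prov)

    by_len = pairs.bin_pairs(
        pair_table, values, pair_table["intergenic_length"].astype(float),
        pc["n_bins"], method=pc["binned_method"],
    )
    io.write_table(by_len, outdir / "pair_bins_length.tsv", prov)
    coexpr = pairs.coexpression_covariates(expression, pair_table)
    by_co = pairs.bin_pairs(
        pair_table, values, coexpr, pc["n_bins"], method=pc["binned_method"],
    )
    io.write_table(by_co, outdir / "pair_bins_coexpression.tsv", prov)

    out = {"pair_report": report,
           "divergent_r": float(unbinned.loc["divergent", "r"])}

    reg_path = outdir / "regulators.tsv"
    if reg_path.exists():
        matrix = io.read_matrix(reg_path)
        matrix.index.name = "regulator"
        gstats = io.read_table(
            outdir / "regulator_gene_stats.tsv",
            schema=["gene", "delta_deg", "delta_expr"],
        ).set_index("gene")
        rep = pairs.shared_regulator_analysis(
            matrix, gstats["delta_deg"], gstats["delta_expr"],
            min_shared=pc["min_shared"], n_strata=pc["n_strata"],
        )
        io.write_table(rep.per_stratum, outdir / "shared_regulator.tsv", prov)
        out["shared_regulator_pooled_p"] = rep.pooled_p
    return out


def _stage_coupling(config, outdir, prov, seed):
    cc = config["coupling"]
    mats = {name: io.read_matrix(outdir / f"{name}.tsv")
            for name in ("total_1", "total_2", "new_1", "new_2")}
    omap = io.read_table(outdir / "orthologs.tsv", schema=["gene_1", "gene_2"])
    data = synthetic.LabelingData(
        total_1=mats["total_1"], total_2=mats["total_2"],
        new_1=mats["new_1"], new_2=mats["new_2"],
        ortholog_map=omap, t_label=cc["t_label"],
    )
    tab = coupling.comparison_table(
        data, center=cc["center"], fold=cc["fold"],
        min_intensity_quantile=cc["min_intensity_quantile"],
        max_abs_delta=cc["max_abs_delta"],
    )
    io.write_table(tab, outdir / "turnover_comparison.tsv", prov)
    rep = coupling.shift_report(tab)
    med = rep.medians.rename_axis("deg_class").reset_index()
    med["n"] = rep.class_counts.to_numpy()
    io.write_table(med, outdir / "shift_report.tsv", prov)

    null = coupling.nonortholog_null(
        data, seed=seed + cc["null_seed"], center=cc["center"], fold=cc["fold"]
    )
    dd = tab["delta_new"] - tab["delta_total"]
    fit_scores, fraction = None, cc.get("best_fit_fraction")
    if fraction is not None:
        course_path = outdir / "timecourse.tsv"
        scores = {}
        if course_path.exists():
            course = io.read_table(course_path)
            wt = course[course["strain"] == "WT"]
            for gene, grp in wt.groupby("gene"):
                lv = grp.groupby("time_min")["level"].mean()
                if len(lv) >= 3:
                    scores[gene] = decay.exponential_fit_quality(
                        lv.index, lv.to_numpy())
        common = set(scores) & set(tab["gene_1"])
        if common:
            fit_scores = pd.Series(scores)
        else:
            log.warning("best_fit_fraction set but no arrest courses match "
                        "the labeling genes; filter skipped")
            fraction = None
    r, p, n = coupling.degradation_level_correlation(
        dd.set_axis(tab["gene_1"]),
        tab.set_index("gene_1")["delta_total"],
        fit_scores=fit_scores, best_fit_fraction=fraction)
    summary = (
        f"pattern call: {rep.pattern_call}\n"
        f"d_new={rep.d_new:.4f} d_total={rep.d_total:.4f}\n"
        f"class counts: {rep.class_counts.to_dict()}\n"
        f"non-ortholog null call: {null.pattern_call}\n"
        f"degradation-level spearman: r={r:.4f} p={p:.3g} n={n}\n"
    )
    (outdir / "coupling_summary.txt").write_text(summary)
    return {"pattern_call": rep.pattern_call,
            "null_call": null.pattern_call,
            "deg_level_spearman": r}


def report(outdir) -> str:
    """Plain-text digest of whatever outputs are present in ``outdir``."""
    outdir = Path(outdir)
    lines = [f"promcoupling report for {outdir}"]
    f = outdir / "swap_effects.tsv"
    if f.exists():
        eff = io.read_table(f)
        lines.append(
            f"decay-fit: {len(eff)} genes, "
            f"{(eff['classification'] != 'not_significant').sum()} with a "
            "significant degradation effect"
        )
    f = outdir / "pair_correlations.tsv"
    if f.exists():
        pc = io.read_table(f).set_index("architecture")
        lines.append(
            "pair correlations (unbinned): "
            + ", ".join(f"{a}={pc.loc[a, 'r']:.3f}" for a in pc.index)
        )
    f = outdir / "coupling_summary.txt"
    if f.exists():
        lines.append(f.read_text().strip())
    return "\n".join(lines) + "\n"
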