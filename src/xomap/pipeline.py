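"""Orchestration: simulate (optional) -> QC -> CO calling -> landscapes ->
interference -> group statistics, with all results written as TSV/JSON.

Each stage can also be run on its own through the library API or the CLI;
``run_pipeline`` simply composes them, labels failures with the stage name,
and guarantees reproducibility from the single top-level seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import bin_landscape, call_population, per_sample_counts
from .chromspec import tair10_chromosomes
from .config import RunConfig
from .interference import coc_curve, inter_co_distances, permutation_null
from .popstats import landscape_chisq, nested_anova
from .qc import run_qc
from .simulate import ObservationModel, RecombinationModel, build_population, uniform_marker_panel
from .vcfio import read_vcf, write_events_bed, write_events_tsv, write_truth_tsv, write_vcf

log = logging.getLogger("xomap")

__all__ = ["run_pipeline", "simulate_group"]


class StageError(RuntimeError):
    pass


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:  # label failures with the stage
                raise StageError(f"stage '{name}' failed: {e}") from e

        return wrapped

    return deco


def simulate_group(group, cfg: RunConfig, specs, seed):
    """Simulate one offspring group from its GroupConfig."""
    rng = np.random.default_rng(seed)
    panel = uniform_marker_panel(specs, n_per_chrom=cfg.n_markers_per_chrom, rng=rng)
    model = RecombinationModel.from_transmitted_mean(
        specs, group.transmitted_mean, sex=group.sex, nu=group.nu, obligate_co=group.obligate_co
    )
    obs = ObservationModel(
        p_missing=cfg.p_missing,
        e_het_to_hom=cfg.e_het_to_hom,
        e_hom_to_het=cfg.e_hom_to_het,
        e_hom_ler=cfg.e_hom_ler,
        depth_mean=cfg.depth_mean,
        read_based_het_calls=cfg.read_based_het_calls,
    )
    gm, truths, summaries = build_population(
        group.n_samples,
        specs,
        model,
        panel,
        obs,
        seed=int(rng.integers(2**31 - 1)),
        sample_prefix=f"{group.label}_",
    )
    return gm, truths, summaries


def run_pipeline(cfg: RunConfig, specs=None):
    """Execute the full analysis; returns the result bundle as a dict.

    The bundle contains, per dataset: the QC report, called events, per-
    sample counts, 1-Mb landscape, inter-CO distances, permutation result
    and CoC curve, plus cross-group statistics (nested ANOVA when at least
    two sexes x genotypes are present) and a machine-readable summary.
    """
    specs = list(specs) if specs is not None else tair10_chromosomes()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    chash = cfg.config_hash()
    header = [f"config_hash={chash}", f"seed={cfg.seed}"]
    cfg.to_yaml(outdir / "config_echo.yaml")

    datasets = {}
    if cfg.vcf:
        gm, stats = read_vcf(cfg.vcf, return_stats=True)
        datasets["input"] = {"gm": gm, "truths": None, "sex": "unknown", "genotype": "unknown"}
        log.info("loaded %s: %d samples, %d markers", cfg.vcf, gm.n_samples, gm.n_markers)
    elif cfg.groups:
        for group in cfg.groups:
            seed = int(rng.integers(2**31 - 1))
            gm, truths, summaries = _stage("simulate")(simulate_group)(group, cfg, specs, seed)
            datasets[group.label] = {
                "gm": gm,
                "truths": truths,
                "summaries": summaries,
                "sex": group.sex,
                "genotype": group.genotype,
            }
            write_vcf(gm, outdir / f"{group.label}.vcf", specs=specs, extra_header=[f"xomapConfigHash={chash}"])
            write_truth_tsv(truths, outdir / f"{group.label}.truth.tsv")
    else:
        raise StageError("stage 'input' failed: config needs either a vcf path or simulation groups")

    summary = {"config_hash": chash, "seed": cfg.seed, "datasets": {}}
    all_counts = []
    landscapes = {}
    for label, ds in datasets.items():
        gm = ds["gm"]
        gm_f, report = _stage("qc")(run_qc)(
            gm,
            maf_range=cfg.maf_range,
            min_dp=cfg.min_dp,
            max_dp=cfg.max_dp,
            mean_dp_range=cfg.mean_dp_range,
            dp_scope=cfg.dp_scope,
            max_missing=cfg.max_missing,
            percentile_lo=cfg.percentile_lo,
            percentile_hi=cfg.percentile_hi,
        )
        report.to_frame().to_csv(outdir / f"{label}.qc.tsv", sep="\t", index=False)
        events = _stage("call")(call_population)(
            gm_f, w=cfg.window, s=cfg.step, min_run_markers=cfg.min_run_markers
        )
        write_events_tsv(events, outdir / f"{label}.events.tsv", header_lines=header)
        write_events_bed(events, outdir / f"{label}.events.bed", header_lines=header)
        counts = per_sample_counts(events, gm_f.samples)
        counts.to_csv(outdir / f"{label}.counts.tsv", sep="\t")
        landscape = _stage("landscape")(bin_landscape)(events, specs, gm_f.n_samples, bin_size=cfg.bin_size)
        landscape.to_csv(outdir / f"{label}.landscape.tsv", sep="\t", index=False)
        landscapes[label] = landscape

        ds_summary = {
            "n_samples_post_qc": gm_f.n_samples,
            "n_markers_post_qc": gm_f.n_markers,
            "mean_co_per_offspring": float(counts["genome"].mean()) if len(counts) else 0.0,
            "n_events": len(events),
        }
        interco = inter_co_distances(events, label=label)
        interco.table.to_csv(outdir / f"{label}.interco.tsv", sep="\t", index=False)
        if len(interco.table):
            perm = _stage("interference")(permutation_null)(
                interco, events, n_perm=cfg.n_perm, seed=int(rng.integers(2**31 - 1))
            )
            ds_summary["interference"] = {
                "n_two_co_chromosomes": int(len(interco.table)),
                "observed_mean_distance_bp": perm.observed_mean,
                "null_mean_distance_bp": float(perm.null_means.mean()),
                "p_value": perm.p_value,
                "n_perm": perm.n_perm,
                "direction": perm.direction,
                "scheme": perm.scheme,
            }
        coc = _stage("interference")(coc_curve)(
            events,
            specs,
            gm_f.samples,
            d_range=range(1, cfg.d_max_mb + 1),
            bin_size=cfg.bin_size,
            span=cfg.loess_span,
            degree=cfg.loess_degree,
        )
        coc.points.to_csv(outdir / f"{label}.coc_points.tsv", sep="\t", index=False)
        coc.pooled.to_csv(outdir / f"{label}.coc_pooled.tsv", sep="\t", index=False)
        if coc.fit is not None:
            coc.fit.to_csv(outdir / f"{label}.coc_fit.tsv", sep="\t", index=False)
        ds_summary["coc_pooled"] = {
            f"{row.d_mb:g}": row.coc for row in coc.pooled.itertuples(index=False)
        }
        if ds["truths"] is not None:
            truth_mean = float(np.mean([t.n_cos() for t in ds["truths"]]))
            ds_summary["true_mean_co_per_offspring"] = truth_mean
        summary["datasets"][label] = ds_summary
        c = counts[["genome"]].copy()
        c["sex"] = ds["sex"]
        c["genotype"] = ds["genotype"]
        c["dataset"] = label
        all_counts.append(c)

    stacked = pd.concat(all_counts) if all_counts else pd.DataFrame()
    if len(stacked) and stacked["sex"].nunique() >= 2 and stacked["genotype"].nunique() >= 2:
        res = _stage("stats")(nested_anova)(stacked["genome"], stacked["sex"], stacked["genotype"])
        res.anova_table.to_csv(outdir / "anova.tsv", sep="\t")
        res.tukey.to_csv(outdir / "tukey.tsv", sep="\t", index=False)
        summary["anova_p_sex"] = float(res.anova_table["p"].iloc[0])
        summary["anova_p_genotype_within_sex"] = float(res.anova_table["p"].iloc[1])
    labels = list(landscapes)
    if len(labels) >= 2:
        chisq = _stage("stats")(landscape_chisq)(landscapes[labels[0]], landscapes[labels[1]])
        chisq.to_csv(outdir / f"chisq_{labels[0]}_vs_{labels[1]}.tsv", sep="\t", index=False)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %s", outdir / "summary.json")
    return summary
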