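"""Pipeline orchestration: simulate -> normalize -> metrics -> zones ->
rate -> brdu, with every artifact written as TSV/BED plus a manifest.

Each stage is a function of (config, ctx) where ``ctx`` carries in-memory
products of earlier stages; requesting a stage whose inputs are missing
raises an error naming the stage.  All randomness derives from the config
seed, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import os

import numpy as np
import pandas as pd

from . import __version__
from .brdu import (
    brdu_enrichment,
    compare_zone_groups,
    dog_delta_point,
    smooth_moving_average,
    stratify_by_zones,
    subtract_conditions,
)
from .config import RunConfig
from .io import write_bedgraph, write_gene_table, write_scored_bed, write_tsv
from .metrics import (
    TerminationComparison,
    classify_ndt_nit,
    comparison_table,
    elongation_index_profile,
    metagene_matrix,
    pausing_index,
    splicing_efficiency,
    termination_index,
    termination_table,
)
from .normalize import spike_factor
from .rate import filter_wave_genes, rate_table, replicate_consistency
from .rizones import classify_pa_pna, high_confidence_perturbed, quantify_zone_signal, zone_gene_distance
from .simulate import SimulationScenario, simulate_brdu_counts, simulate_genome, simulate_junction_reads, simulate_point_coverage, simulate_tt_timecourse

STAGES = ("simulate", "normalize", "metrics", "zones", "rate", "brdu")


def make_scenario(config: RunConfig) -> SimulationScenario:
    return SimulationScenario(seed=config.seed, bin_width=config.bin_width,
                              **config.scenario)


def _require(ctx: dict, key: str, stage: str) -> None:
    if key not in ctx:
        raise RuntimeError(
            f"stage '{stage}' is missing its input '{key}'; run the "
            "prerequisite stages first"
        )


def stage_simulate(config: RunConfig, ctx: dict, outdir: str | None = None) -> dict:
    scenario = make_scenario(config)
    genes, zones = simulate_genome(scenario)
    ctx["scenario"] = scenario
    ctx["genes"] = genes
    ctx["zones"] = zones
    for condition in ("control", "perturbed"):
        cov, spike, endo = simulate_point_coverage(genes, scenario, condition)
        ctx[f"point_{condition}"] = cov
        ctx[f"tallies_{condition}"] = (spike, endo)
    reads = simulate_junction_reads(genes, scenario)
    ctx["junction_reads"] = reads
    if outdir:
        write_gene_table(genes, os.path.join(outdir, "genes.tsv"))
        write_scored_bed(zones, os.path.join(outdir, "zones.bed"))
        write_tsv(zones, os.path.join(outdir, "truth_zones.tsv"))
        write_tsv(reads, os.path.join(outdir, "junction_reads.tsv"))
        for condition in ("control", "perturbed"):
            for strand, tag in (("+", "fwd"), ("-", "rev")):
                write_bedgraph(ctx[f"point_{condition}"], strand,
                               os.path.join(outdir, f"point_{condition}_{tag}.bedgraph"))
    return ctx


def stage_normalize(config: RunConfig, ctx: dict, outdir: str | None = None) -> dict:
    _require(ctx, "point_control", "normalize")
    rows = []
    for condition in ("control", "perturbed"):
        spike, endo = ctx[f"tallies_{condition}"]
        norm = spike_factor(spike, endo)
        ctx[f"spiked_{condition}"] = norm.apply(ctx[f"point_{condition}"])
        rows.append((condition, spike, endo, norm.factor, norm.scale))
    table = pd.DataFrame(
        rows, columns=["condition", "spike_reads", "endogenous_reads",
                       "factor", "scale"],
    )
    ctx["spike_table"] = table
    if outdir:
        write_tsv(table, os.path.join(outdir, "spike_factors.tsv"))
    return ctx


def stage_metrics(config: RunConfig, ctx: dict, outdir: str | None = None) -> dict:
    _require(ctx, "spiked_control", "metrics")
    genes = ctx["genes"]
    calls = {}
    for condition in ("control", "perturbed"):
        cov = ctx[f"spiked_{condition}"]
        calls[condition] = [
            termination_index(cov, g, dog_length=config.dog_length) for g in genes
        ]
    comparisons = [
        TerminationComparison(gene_id=c.gene_id, ti_control=c.ti,
                              ti_perturbed=p.ti)
        for c, p in zip(calls["control"], calls["perturbed"])
    ]
    comparisons = classify_ndt_nit(comparisons, config.delta_ti_threshold)
    ctx["ti_comparison"] = comparison_table(comparisons)
    pausing = pd.DataFrame(
        [(c.gene_id, c.pause_density, c.body_density, c.pausing_index)
         for c in (pausing_index(ctx["spiked_control"], g,
                                 pause_window=config.pause_window)
                   for g in genes)],
        columns=["gene_id", "pause_density", "body_density", "pausing_index"],
    )
    ctx["pausing"] = pausing
    units = pd.DataFrame(
        [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in genes],
        columns=["name", "chrom", "start", "end", "strand"],
    )
    sp_calls = splicing_efficiency(ctx["junction_reads"], units)
    splicing = pd.DataFrame(
        [(c.unit_id, c.spliced_reads, c.total_reads, c.efficiency)
         for c in sp_calls if c.ok],
        columns=["unit_id", "spliced_reads", "total_reads", "efficiency"],
    )
    ctx["splicing"] = splicing
    regions = pd.DataFrame(
        [(g.chrom, g.start, g.end, g.strand) for g in genes],
        columns=["chrom", "start", "end", "strand"],
    )
    _, profile = metagene_matrix(
        ctx["spiked_control"], regions,
        body_bins=config.metagene_body_bins,
        up_bins=config.metagene_up_bins,
        down_bins=config.metagene_down_bins,
        flank_bin_width=config.metagene_flank_bin_width,
    )
    meta = pd.DataFrame({"bin": np.arange(profile.size), "mean_signal": profile})
    ctx["metagene"] = meta
    tt_tracks, _ = simulate_tt_timecourse(ctx["genes"], ctx["scenario"])
    ei = elongation_index_profile(tt_tracks[0.0], ctx["point_control"], genes,
                                  n_bins=config.ei_bins)
    ctx["ei_profile"] = pd.DataFrame(
        {"bin": np.arange(config.ei_bins), "ei": ei.profile}
    )
    if outdir:
        for cond in ("control", "perturbed"):
            write_tsv(termination_table(calls[cond]),
                      os.path.join(outdir, f"ti_calls_{cond}.tsv"))
        write_tsv(ctx["ti_comparison"], os.path.join(outdir, "ti_comparison.tsv"))
        write_tsv(pausing, os.path.join(outdir, "pausing.tsv"))
        write_tsv(splicing, os.path.join(outdir, "splicing.tsv"))
        write_tsv(meta, os.path.join(outdir, "metagene.tsv"))
        write_tsv(ctx["ei_profile"], os.path.join(outdir, "ei_profile.tsv"))
    return ctx


def stage_zones(config: RunConfig, ctx: dict, outdir: str | None = None) -> dict:
    _require(ctx, "spiked_control", "zones")
    zones = quantify_zone_signal(
        {"control": ctx["spiked_control"], "perturbed": ctx["spiked_perturbed"]},
        ctx["zones"],
    )
    zones = classify_pa_pna(zones, "perturbed", "control",
                            cutoff_log2=config.pa_cutoff_log2)
    zones = zone_gene_distance(zones, ctx["genes"])
    high = high_confidence_perturbed(zones, score_min=config.ri_score_min,
                                     fold_min=config.ri_fold_min)
    ctx["zones_classified"] = zones
    ctx["zones_high_confidence"] = high
    if outdir:
        write_tsv(zones, os.path.join(outdir, "zones_classified.tsv"))
        write_tsv(high, os.path.join(outdir, "zones_high_confidence.tsv"))
    return ctx


def rate_scenario(config: RunConfig) -> SimulationScenario:
    """Wave-calling needs genes long enough to contain the 30-min front;
    the rate stage therefore runs on long (100-kb) genes."""
    base = dict(config.scenario)
    base.update(gene_length=100000, n_genes=base.get("n_genes", 20))
    return SimulationScenario(seed=config.seed, bin_width=config.bin_width,
                              **base)


def stage_rate(config: RunConfig, ctx: dict, outdir: str | None = None) -> dict:
    scenario = rate_scenario(config)
    genes, _ = simulate_genome(scenario)
    tracks, truth = simulate_tt_timecourse(genes, scenario)
    minutes = scenario.nvp2_times[0]
    kept = filter_wave_genes(
        tracks[0.0], tracks[minutes], genes,
        min_length=config.wave_min_length,
        proximal_window=(config.wave_proximal_start, config.wave_proximal_end),
        min_reduction=config.wave_min_reduction,
    )
    table = rate_table(kept, tracks[minutes], minutes,
                       bin_width=config.rate_bin_width)
    ctx["rate_table"] = table
    ctx["rate_truth"] = truth
    if outdir:
        write_tsv(table, os.path.join(outdir, "rates.tsv"))
        write_tsv(truth, os.path.join(outdir, "truth_fronts.tsv"))
    return ctx


def stage_brdu(config: RunConfig, ctx: dict, outdir: str | None = None) -> dict:
    _require(ctx, "spiked_control", "brdu")
    scenario = ctx["scenario"]
    genes = ctx["genes"]
    L = scenario.effective_chrom_length
    defective = [
        g.downstream_interval(0, scenario.defective_replication_span)
        for i, g in enumerate(genes) if scenario.is_planted(i)
    ]
    defective = [(min(a, b), max(a, b)) for a, b in defective]
    tracks = {}
    for condition in ("control", "perturbed"):
        cb, ci = simulate_brdu_counts(
            L, scenario, condition,
            defective_regions=defective if condition == "perturbed" else None,
            bin_width=config.brdu_bin_width,
        )
        track = brdu_enrichment(cb, ci, min_input=config.brdu_min_input,
                                bin_width=config.brdu_bin_width)
        # percent scale for the background band, matching the +/-10 default
        tracks[condition] = 100.0 * smooth_moving_average(
            track.eb, m=config.brdu_smooth_m
        )
    delta_zones = subtract_conditions(
        tracks["perturbed"], tracks["control"],
        background=config.brdu_background, bin_width=config.brdu_bin_width,
    )
    deltas = dog_delta_point(
        ctx["spiked_perturbed"], ctx["spiked_control"], genes,
        window=(config.brdu_dog_start, config.brdu_dog_end),
    )
    stratified = stratify_by_zones(deltas, delta_zones)
    result, info = compare_zone_groups(stratified)
    ctx["brdu_zone_table"] = delta_zones.zone_table()
    ctx["brdu_stratified"] = stratified
    ctx["brdu_test"] = pd.DataFrame(
        [{"p_hat": result.p_hat, "statistic": result.statistic,
          "df": result.df, "p_value": result.p_value, **info}]
    )
    if outdir:
        write_tsv(ctx["brdu_zone_table"], os.path.join(outdir, "brdu_zones.tsv"))
        write_tsv(stratified, os.path.join(outdir, "brdu_stratified.tsv"))
        write_tsv(ctx["brdu_test"], os.path.join(outdir, "brdu_test.tsv"))
    return ctx


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "normalize": stage_normalize,
    "metrics": stage_metrics,
    "zones": stage_zones,
    "rate": stage_rate,
    "brdu": stage_brdu,
}


def run_pipeline(config: RunConfig, stages=STAGES, outdir: str | None = None) -> dict:
    """Execute the requested stages in order; write artifacts and a manifest
    under ``outdir`` when given.  Returns the in-memory context."""
    config.validate()
    outdir = outdir or config.outdir
    os.makedirs(outdir, exist_ok=True)
    ctx: dict = {}
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        _STAGE_FUNCS[stage](config, ctx, outdir=outdir)
    thresholds = dataclasses.asdict(config)
    thresholds.pop("outdir", None)  # paths are not part of the run identity
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(stages),
        "thresholds": thresholds,
        "outputs": sorted(f for f in os.listdir(outdir) if f != "manifest.json"),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return ctx
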