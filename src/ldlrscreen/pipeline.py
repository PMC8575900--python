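"""End-to-end orchestration of the hit-calling funnel on one screen.

Stages: viability QC and robust-z normalization of the primary screen;
replicate hit calling and ranking; t-test/fold-change classification of the
expression experiment; integration with annotation flags into cherry-picked
candidates; deconvolution rescreen of the candidates and validation; funnel
report.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import expression, hits, plates, simulate
from .integrate import FunnelReport, funnel_report
from .integrate import integrate as integrate_candidates
from .io import PipelineConfig
from .simulate import SimulationConfig


@dataclass
class ScreenRun:
    """All stage outputs of one simulated screen analysis."""

    truth: pd.DataFrame
    wells: pd.DataFrame
    wellz: pd.DataFrame
    plate_stats: pd.DataFrame
    excluded: pd.DataFrame
    summaries: pd.DataFrame          # with hit_call
    ranked: pd.DataFrame
    expr: pd.DataFrame
    de_results: pd.DataFrame
    modulated: pd.DataFrame
    flags: pd.DataFrame
    candidates: pd.DataFrame
    deconv_wells: pd.DataFrame
    deconv_records: pd.DataFrame     # with validated
    report: FunnelReport


def analyze_screen(
    wells: pd.DataFrame,
    expr: pd.DataFrame,
    flags: pd.DataFrame | None,
    cfg: PipelineConfig,
    design: pd.DataFrame | None = None,
) -> dict:
    """Run QC, normalization, hit calling, DE classification and integration
    on measured tables (no simulation, no deconvolution)."""
    wellz, stats, excluded = plates.normalize_screen(wells, cfg)
    summaries = hits.summarize_genes(wellz, design=design)
    called = hits.call_primary_hits(
        summaries, t=cfg.primary_z_threshold, k=cfg.primary_min_replicates
    )
    de_results = expression.de_all(
        expr,
        alpha=cfg.de_alpha,
        fc_threshold=cfg.de_fc_threshold,
        log_scale=cfg.de_log_scale,
        fdr=cfg.de_fdr,
    )
    modulated = expression.classify_modulated(
        de_results, alpha=cfg.de_alpha, fc_threshold=cfg.de_fc_threshold
    )
    candidates = integrate_candidates(
        called, modulated, flags, policy=cfg.integration_policy
    )
    return {
        "wellz": wellz,
        "plate_stats": stats,
        "excluded": excluded,
        "summaries": called,
        "ranked": hits.rank_hits(called),
        "de_results": de_results,
        "modulated": modulated,
        "candidates": candidates,
    }


def run_simulated_screen(
    sim: SimulationConfig, cfg: PipelineConfig | None = None
) -> ScreenRun:
    """Simulate a screen and push it through the full funnel."""
    cfg = cfg or PipelineConfig(random_seed=sim.seed)
    design, wells, truth = simulate.simulate_screen(sim)
    expr = simulate.simulate_expression(sim, truth)
    flags = truth[["gene", "lipid_gwas_flag"]]

    stage = analyze_screen(wells, expr, flags, cfg, design=design)
    candidates = stage["candidates"]
    candidate_genes = candidates.loc[candidates["candidate"], "gene"].tolist()

    deconv_wells = simulate.simulate_deconvolution(sim, truth, candidate_genes)
    if len(deconv_wells):
        dz, _, _ = plates.normalize_screen(deconv_wells, cfg)
        records = hits.summarize_deconvolution(dz, stage["summaries"])
        records = hits.validate_deconvolution(
            records, t=cfg.deconv_z_threshold, m=cfg.deconv_min_sirnas
        )
    else:
        records = pd.DataFrame(
            columns=["gene", "primary_direction", "sirna_z", "validated"]
        )

    report = funnel_report(stage["summaries"], candidates, records)
    return ScreenRun(
        truth=truth,
        wells=wells,
        wellz=stage["wellz"],
        plate_stats=stage["plate_stats"],
        excluded=stage["excluded"],
        summaries=stage["summaries"],
        ranked=stage["ranked"],
        expr=expr,
        de_results=stage["de_results"],
        modulated=stage["modulated"],
        flags=flags,
        candidates=candidates,
        deconv_wells=deconv_wells,
        deconv_records=records,
        report=report,
    )
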