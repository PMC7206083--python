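"""Pipeline orchestration: run enabled stages in order and assemble one
JSON-able report.

Stage order is somatic -> amplicon -> tcr -> rtca -> dsrt.  Every enabled
stage must have resolvable inputs before anything executes (fail fast);
each stage writes its outputs under its own subdirectory of the output
directory, and the combined report records thresholds and seeds so a run
is reproducible from its report alone.  Reports carry no timestamps, so
identical configurations produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

from . import __version__
from .amplicon import (
    AmpliconThresholds,
    cohort_prevalence,
    confinement_report,
    track_vaf,
)
from .drug_response import dss, fit_dose_response
from .io import (
    amplicon_measurements_from_df,
    read_amplicon_tsv,
    read_pileup_genes,
    read_pileup_tsv,
    read_plate_csv,
    read_repertoire_tsv,
    read_rtca_csv,
)
from .rtca import cytolysis_series, dose_monotonicity, normalized_cell_index
from .somatic import CallerParams, call_paired_somatic, write_vcf
from .tcr import (
    clonotype_frequencies,
    diversity,
    merge_orphan_chains_with_report,
    top_clone_fraction,
)

__all__ = ["RunConfig", "run_pipeline", "StageError"]

logger = logging.getLogger("clonetrack")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    # stage toggles + inputs
    somatic_normal: str | None = None
    somatic_tumor: str | None = None
    amplicon_table: str | None = None
    repertoire_table: str | None = None
    rtca_traces: str | None = None
    rtca_meta: str | None = None
    plate_table: str | None = None
    # thresholds
    caller: CallerParams = field(default_factory=CallerParams)
    amplicon_thresholds: AmpliconThresholds = field(default_factory=AmpliconThresholds)
    rtca_horizon: float = 21.0
    dss_variant: int = 2
    dss_threshold: float = 10.0

    def enabled_stages(self) -> list[str]:
        stages = []
        if self.somatic_normal or self.somatic_tumor:
            stages.append("somatic")
        if self.amplicon_table:
            stages.append("amplicon")
        if self.repertoire_table:
            stages.append("tcr")
        if self.rtca_traces or self.rtca_meta:
            stages.append("rtca")
        if self.plate_table:
            stages.append("dsrt")
        return stages

    def validate(self) -> None:
        pairs = {
            "somatic": [self.somatic_normal, self.somatic_tumor],
            "rtca": [self.rtca_traces, self.rtca_meta],
        }
        for stage, paths in pairs.items():
            present = [p for p in paths if p]
            if present and len(present) != len(paths):
                raise ValueError(f"stage {stage!r} needs all of its inputs")
        for stage in self.enabled_stages():
            for path in self._stage_inputs(stage):
                if not os.path.exists(path):
                    raise FileNotFoundError(
                        f"stage {stage!r} input not found: {path}"
                    )

    def _stage_inputs(self, stage: str) -> list[str]:
        return {
            "somatic": [self.somatic_normal, self.somatic_tumor],
            "amplicon": [self.amplicon_table],
            "tcr": [self.repertoire_table],
            "rtca": [self.rtca_traces, self.rtca_meta],
            "dsrt": [self.plate_table],
        }[stage]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages and write ``report.json`` plus per-stage
    outputs under ``cfg.outdir``; returns the report dict."""
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": {},
        "thresholds": {
            "caller": dataclasses.asdict(cfg.caller) | {
                "known_variant_set": sorted(
                    list(t) for t in cfg.caller.known_variant_set
                )
            },
            "amplicon": dataclasses.asdict(cfg.amplicon_thresholds),
            "rtca_horizon": cfg.rtca_horizon,
            "dss_variant": cfg.dss_variant,
            "dss_threshold": cfg.dss_threshold,
        },
    }
    runners = {
        "somatic": _run_somatic,
        "amplicon": _run_amplicon,
        "tcr": _run_tcr,
        "rtca": _run_rtca,
        "dsrt": _run_dsrt,
    }
    manifest: list[str] = []
    for stage in cfg.enabled_stages():
        stage_dir = os.path.join(cfg.outdir, stage)
        os.makedirs(stage_dir, exist_ok=True)
        logger.info("stage=%s level=INFO msg=starting", stage)
        try:
            report["stages"][stage] = runners[stage](cfg, stage_dir)
        except Exception as exc:  # keep partial outputs + manifest
            manifest.append(f"{stage}: FAILED ({exc})")
            _write_report(cfg.outdir, report, manifest)
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        manifest.append(f"{stage}: ok")
        logger.info("stage=%s level=INFO msg=done", stage)
    _write_report(cfg.outdir, report, manifest)
    return report


def _write_report(outdir: str, report: dict, manifest: list[str]) -> None:
    with open(os.path.join(outdir, "manifest.txt"), "w") as fh:
        fh.write("\n".join(manifest) + ("\n" if manifest else ""))
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _run_somatic(cfg: RunConfig, outdir: str) -> dict:
    normal = read_pileup_tsv(cfg.somatic_normal)
    tumor = read_pileup_tsv(cfg.somatic_tumor)
    genes = read_pileup_genes(cfg.somatic_tumor)
    calls = call_paired_somatic(normal, tumor, cfg.caller, genes=genes)
    from .io import write_calls_tsv

    write_vcf(calls, os.path.join(outdir, "somatic.vcf"))
    write_calls_tsv(calls, os.path.join(outdir, "somatic.tsv"))
    candidates = [c for c in calls if c.status == "candidate"]
    return {
        "n_sites": len(calls),
        "n_candidates": len(candidates),
        "candidates": [
            {
                "gene": c.gene, "chrom": c.chrom, "pos": c.pos,
                "tumor_vaf": c.tumor_vaf, "somatic_p": c.somatic_p,
            }
            for c in candidates
        ],
    }


def _run_amplicon(cfg: RunConfig, outdir: str) -> dict:
    df = read_amplicon_tsv(cfg.amplicon_table)
    measurements = amplicon_measurements_from_df(df)
    series = {}
    for key in sorted({(m.subject, m.gene, m.compartment) for m in measurements}):
        subj, gene, comp = key
        s = track_vaf(measurements, subj, gene, comp)
        series["/".join(key)] = {
            "years": list(s.years),
            "vafs": list(s.vafs),
            "direction": s.direction,
            "slope_pct_per_year": s.slope_pct_per_year,
        }
    confinement = {}
    for (subj, gene, year) in sorted(
        {(m.subject, m.gene, m.sample_year) for m in measurements}
    ):
        rows = [
            m for m in measurements
            if (m.subject, m.gene, m.sample_year) == (subj, gene, year)
        ]
        confinement[f"{subj}/{gene}/{year}"] = {
            comp: {"vaf": f.vaf, "flag": f.flag, "ratio_to_max": f.ratio_to_max}
            for comp, f in confinement_report(rows).items()
        }
    out = {"longitudinal": series, "confinement": confinement}
    with open(os.path.join(outdir, "amplicon_report.json"), "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
    return out


def _run_tcr(cfg: RunConfig, outdir: str) -> dict:
    sample = read_repertoire_tsv(cfg.repertoire_table)
    merged, mrep = merge_orphan_chains_with_report(sample)
    top, frac = top_clone_fraction(merged)
    h, clonality = diversity(merged)
    freqs = clonotype_frequencies(merged)
    out = {
        "total_cells": merged.total_cells,
        "n_clonotypes": len(merged.clonotypes),
        "n_orphans_merged": len(mrep.merged),
        "n_ambiguous_orphans": len(mrep.ambiguous),
        "top_clone_beta_aa": top.beta_aa,
        "top_clone_cells": top.cells,
        "top_clone_fraction": frac,
        "shannon_entropy_nats": h,
        "clonality": clonality,
        "top10": [
            {"beta_aa": c.beta_aa, "cells": n, "fraction": f}
            for c, n, f in freqs[:10]
        ],
    }
    with open(os.path.join(outdir, "tcr_report.json"), "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
    return out


def _run_rtca(cfg: RunConfig, outdir: str) -> dict:
    traces = read_rtca_csv(cfg.rtca_traces, cfg.rtca_meta)
    meta_t_add = {}
    import pandas as pd

    meta = pd.read_csv(cfg.rtca_meta)
    for r in meta.itertuples(index=False):
        meta_t_add[str(r.well)] = float(getattr(r, "t_add", 0.0))
    control = next(t for t in traces if t.condition == "control")
    t_norm = meta_t_add.get(control.well, 0.0)
    control_nci = normalized_cell_index(control, t_norm)
    horizon_t = t_norm + cfg.rtca_horizon
    lysis_by_ratio: dict[float, float] = {}
    conditions = {}
    for tr in traces:
        if tr is control:
            continue
        nci = normalized_cell_index(tr, meta_t_add.get(tr.well, t_norm))
        times, lysis = cytolysis_series(nci, control_nci)
        idx = int(min(range(len(times)), key=lambda i: abs(times[i] - horizon_t)))
        terminal = float(lysis[idx])
        conditions[tr.condition] = {"terminal_cytolysis_pct": terminal}
        if tr.condition.startswith("E:T "):
            ratio = float(tr.condition.split()[1].split(":")[0])
            lysis_by_ratio[ratio] = terminal
    out: dict = {"conditions": conditions, "horizon_h": cfg.rtca_horizon}
    if len(lysis_by_ratio) >= 2:
        verdict = dose_monotonicity(lysis_by_ratio)
        out["dose_dependent"] = verdict.dose_dependent
        out["violations"] = [list(v) for v in verdict.violations]
    with open(os.path.join(outdir, "rtca_report.json"), "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
    return out


def _run_dsrt(cfg: RunConfig, outdir: str) -> dict:
    curves = read_plate_csv(cfg.plate_table)
    out = {}
    for drug, (doses, inhibition) in curves.items():
        curve = fit_dose_response(doses, inhibition, drug=drug)
        res = dss(curve, variant=cfg.dss_variant, activity_threshold=cfg.dss_threshold)
        out[drug] = {
            "dss": res.dss,
            "ic50_nM": curve.ic50,
            "slope": curve.slope,
            "top": curve.top,
            "bottom": curve.bottom,
            "flat": curve.flat,
        }
    with open(os.path.join(outdir, "dsrt_report.json"), "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
    return out


def cohort_prevalence_report() -> dict:
    """Carrier-prevalence arithmetic over the published screening cohorts."""
    from .fixtures import COHORT_COUNTS

    out = {}
    for (mutation, cohort), (carriers, total) in sorted(COHORT_COUNTS.items()):
        flags = [True] * carriers + [False] * (total - carriers)
        count, n, pct = cohort_prevalence(flags)
        out[f"{mutation}/{cohort}"] = {"carriers": count, "total": n, "pct": pct}
    return out
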