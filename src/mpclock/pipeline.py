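"""End-to-end orchestration of the two experiments.

``run_fig2_experiment`` is the sequencing arm: simulate (or load)
paired raw/bisulfite pileups and variant calls, call M and P levels,
apply the coverage filter, partition loci by variant overlap, and
compute the M/P correction plus mutation-stratified correlations.

``run_clock_experiment`` is the array arm: simulate (or load) paired
converted/unconverted array channels and a genotyping cohort, impute,
run the resampled multi-condition clock protocol, compare conditions by
ANOVA + Tukey, correlate age acceleration across modalities, and test
the cross-channel overlap of selected loci against the hypergeometric
null.

Every run can write its tables plus a manifest (config, seeds, digests,
row counts) sufficient to reproduce the outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, clockkit, io, methcall, mpadjust, synthio
from .config import ClockConfig, SimConfig
from .containers import (
    BetaMatrix,
    ClockReplicate,
    EvaluationSummary,
    LocusPartition,
    StratifiedCorrelation,
)
from .enrich import set_overlap_rf
from .errors import InputError

logger = logging.getLogger(__name__)

COVERAGE_THRESHOLD = 10  # strict: loci must exceed this in every sample/modality


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def write_manifest(outdir: Path, config: SimConfig, stages: dict, clock: ClockConfig | None = None) -> Path:
    manifest = {
        "tool": "mpclock",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "clock_config": dataclasses.asdict(clock) if clock else None,
        "stages": stages,
        "output_digests": {
            p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv"))
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


# ---------------------------------------------------------------------------
# sequencing experiment

@dataclass
class Fig2Report:
    """Summary of the mutation-leakage (M vs P) experiment."""

    n_loci_common: int
    n_mutated: int
    n_unmutated: int
    correlations: list[StratifiedCorrelation]
    mp: pd.DataFrame  # per (locus, sample): M, P, mp_ratio, delta, flags
    partition: LocusPartition
    delta_summary: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "n_loci_common": self.n_loci_common,
            "n_mutated": self.n_mutated,
            "n_unmutated": self.n_unmutated,
            "correlations": [dataclasses.asdict(c) for c in self.correlations],
            "delta_summary": self.delta_summary,
        }


def run_fig2_experiment(
    config: SimConfig,
    coverage_threshold: int = COVERAGE_THRESHOLD,
    outdir: str | Path | None = None,
    pileup: pd.DataFrame | None = None,
    variants=None,
) -> Fig2Report:
    """Simulate (or accept) paired pileups + variants and run the M/P analysis."""
    if pileup is None:
        truth = synthio.simulate_truth(config)
        pileup = pd.concat(
            [
                synthio.simulate_reads(truth, config, "bisulfite"),
                synthio.simulate_reads(truth, config, "raw"),
            ],
            ignore_index=True,
        )
        if variants is None:
            variants = truth.variant_records()
    elif variants is None:
        raise InputError("user-supplied pileups require variant records")

    levels = methcall.call_levels(pileup)
    common = methcall.filter_by_coverage(levels, coverage_threshold)
    logger.info("coverage filter (> %d): %d loci retained", coverage_threshold, len(common))
    partition = methcall.partition_by_variants(common, variants)
    logger.info(
        "variant intersection: %d mutated / %d unmutated",
        len(partition.mutated), len(partition.unmutated),
    )
    wide = methcall.levels_wide(levels, common)
    mp = mpadjust.adjust_table(wide)
    correlations = mpadjust.stratified_correlation(mp, partition)
    deltas = mp["delta"].to_numpy()
    delta_summary = {
        "mean": float(np.mean(deltas)) if len(deltas) else float("nan"),
        "q05": float(np.quantile(deltas, 0.05)) if len(deltas) else float("nan"),
        "q95": float(np.quantile(deltas, 0.95)) if len(deltas) else float("nan"),
        "frac_zero": float(np.mean(deltas == 0)) if len(deltas) else float("nan"),
    }
    report = Fig2Report(
        n_loci_common=len(common),
        n_mutated=len(partition.mutated),
        n_unmutated=len(partition.unmutated),
        correlations=correlations,
        mp=mp,
        partition=partition,
        delta_summary=delta_summary,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        levels.to_csv(outdir / "site_levels.tsv", sep="\t", index=False)
        mp.to_csv(outdir / "mp_adjusted.tsv", sep="\t", index=False)
        pd.DataFrame([dataclasses.asdict(c) for c in correlations]).to_csv(
            outdir / "stratified_correlations.tsv", sep="\t", index=False
        )
        (outdir / "fig2_report.json").write_text(
            json.dumps(report.to_dict(), indent=2) + "\n"
        )
        write_manifest(
            outdir, config,
            stages={
                "levels_rows": int(len(levels)),
                "common_loci": len(common),
                "mutated": len(partition.mutated),
            },
        )
    return report


# ---------------------------------------------------------------------------
# clock experiment

@dataclass
class ClockReport:
    """Summary of the clock-training experiment across conditions."""

    replicates: list[ClockReplicate]
    score_summary: EvaluationSummary
    mae_summary: EvaluationSummary
    mean_scores: dict[str, float]
    mean_maes: dict[str, float]
    acceleration_r_mean: float
    acceleration_r_first: float
    acceleration_p_first: float
    overlap_rf: float
    overlap_p: float
    selected: dict[str, set] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mean_scores": self.mean_scores,
            "mean_maes": self.mean_maes,
            "anova_score": {"f": self.score_summary.anova_f, "p": self.score_summary.anova_p},
            "anova_mae": {"f": self.mae_summary.anova_f, "p": self.mae_summary.anova_p},
            "tukey_score": self.score_summary.tukey.to_dict(orient="records"),
            "acceleration_r_mean": self.acceleration_r_mean,
            "acceleration_r_first": self.acceleration_r_first,
            "acceleration_p_first": self.acceleration_p_first,
            "overlap_rf": self.overlap_rf,
            "overlap_p": self.overlap_p,
        }


def replicates_frame(replicates: list[ClockReplicate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "iteration": [r.iteration for r in replicates],
            "condition": [r.condition for r in replicates],
            "n_selected": [len(r.selected_loci) for r in replicates],
            "test_score": [r.test_score for r in replicates],
            "test_mae": [r.test_mae for r in replicates],
            "converged": [r.converged for r in replicates],
        }
    )


def run_clock_experiment(
    config: SimConfig,
    clock_config: ClockConfig,
    include_genotype: bool = True,
    outdir: str | Path | None = None,
    channels: dict[str, BetaMatrix] | None = None,
) -> ClockReport:
    """Simulate (or accept) array channels and run the full clock protocol."""
    if channels is None:
        conv, unconv, _ = synthio.simulate_array_cohort(config)
        channels = {"converted": conv, "unconverted": unconv}
        if include_genotype:
            allele, signal, _ = synthio.simulate_genotype_cohort(config)
            channels["allele_call"] = allele
            channels["array_signal"] = signal
    channels = {
        name: clockkit.impute_missing(bm, k=clock_config.knn_k)
        for name, bm in channels.items()
    }
    ages = channels[next(iter(channels))].ages

    replicates = clockkit.repeated_evaluation(channels, clock_config)
    score_summary = clockkit.compare_conditions(replicates, "test_score")
    mae_summary = clockkit.compare_conditions(replicates, "test_mae")
    frame = replicates_frame(replicates)
    mean_scores = frame.groupby("condition")["test_score"].mean().to_dict()
    mean_maes = frame.groupby("condition")["test_mae"].mean().to_dict()

    # age acceleration across modalities, per shared train/test split
    accel_rs, accel_ps = [], []
    if "converted" in channels and "unconverted" in channels:
        by_iter: dict[int, dict[str, ClockReplicate]] = {}
        for rep in replicates:
            if rep.condition in ("converted", "unconverted"):
                by_iter.setdefault(rep.iteration, {})[rep.condition] = rep
        for i in sorted(by_iter):
            pair = by_iter[i]
            if len(pair) == 2:
                r, p = clockkit.correlate_acceleration(
                    clockkit.age_acceleration(pair["converted"], ages),
                    clockkit.age_acceleration(pair["unconverted"], ages),
                )
                if np.isfinite(r):
                    accel_rs.append(r)
                    accel_ps.append(p)

    selected = {
        name: clockkit.selected_union(replicates, name)
        for name in channels
    }
    universe = set(channels[next(iter(channels))].loci)
    if selected.get("converted") and selected.get("unconverted"):
        overlap_rf, overlap_p = set_overlap_rf(
            selected["converted"], selected["unconverted"], universe
        )
    else:
        overlap_rf, overlap_p = float("nan"), float("nan")

    report = ClockReport(
        replicates=replicates,
        score_summary=score_summary,
        mae_summary=mae_summary,
        mean_scores=mean_scores,
        mean_maes=mean_maes,
        acceleration_r_mean=float(np.mean(accel_rs)) if accel_rs else float("nan"),
        acceleration_r_first=accel_rs[0] if accel_rs else float("nan"),
        acceleration_p_first=accel_ps[0] if accel_ps else float("nan"),
        overlap_rf=overlap_rf,
        overlap_p=overlap_p,
        selected=selected,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        frame.to_csv(outdir / "clock_replicates.tsv", sep="\t", index=False)
        score_summary.tukey.to_csv(outdir / "tukey_score.tsv", sep="\t", index=False)
        mae_summary.tukey.to_csv(outdir / "tukey_mae.tsv", sep="\t", index=False)
        (outdir / "clock_report.json").write_text(
            json.dumps(report.to_dict(), indent=2, default=str) + "\n"
        )
        write_manifest(
            outdir, config, clock=clock_config,
            stages={"replicates": len(replicates), "conditions": sorted(mean_scores)},
        )
    return report
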