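"""Self-validation experiments for the whole pipeline.

Each function runs one designed experiment on synthetic cohorts and
returns summary numbers: the M/P algebraic identities, the
mutation-leakage correlation contrast, clock parameter recovery against
dummy/permutation nulls, calibration under a no-age-signal cohort, the
cross-channel overlap null, and train/test leakage of the MI filter.
They are used by the test suite and by the reproduction script; sizes
default to the standard study conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import clockkit, mpadjust, synthio
from .config import ClockConfig, SimConfig, default_array_config
from .enrich import set_overlap_rf
from .pipeline import ClockReport, run_clock_experiment, run_fig2_experiment


def mp_identity_deviation() -> dict[str, float]:
    """Max deviation of the M/P identities over a percent sweep."""
    M = np.linspace(0.0, 100.0, 101)
    P = np.full_like(M, 100.0)
    ratio_dev = float(np.abs(mpadjust.mp_ratio(M, P) - M).max())
    shift_dev = float(np.abs(mpadjust.apparent_shift(M, P)).max())
    return {"ratio_identity_max_dev": ratio_dev, "shift_identity_max_dev": shift_dev}


def delta_point_mass(seed: int = 0, n_loci: int = 2000) -> dict[str, float]:
    """Fraction of exactly-zero deltas on an error-free, mutation-free cohort."""
    cfg = SimConfig(
        n_loci=n_loci, mutation_rate=0.0, conversion_efficiency=1.0,
        seq_error_rate=0.0, seed=seed,
    )
    report = run_fig2_experiment(cfg)
    deltas = report.mp["delta"].to_numpy()
    return {"frac_delta_zero": float(np.mean(deltas == 0.0)), "n_pairs": float(len(deltas))}


def stratified_contrast(base_seed: int = 0, n_seeds: int = 20) -> dict[str, float]:
    """Mutation-leakage pattern over seeds: r(mutated) - r(unmutated).

    Also summarizes the level distributions of the first seed: the raw
    (pseudomethylation) mode must sit in the top decile bin and the
    bisulfite distribution must be bimodal (both extreme bins above
    every interior bin).
    """
    contrasts = []
    first = None
    for s in range(n_seeds):
        report = run_fig2_experiment(SimConfig(seed=base_seed + s))
        res = {c.stratum: c for c in report.correlations}
        if res["mutated"].defined and res["unmutated"].defined:
            contrasts.append(res["mutated"].r - res["unmutated"].r)
        if first is None:
            first = report
    bins = np.linspace(0.0, 100.0000001, 11)
    h_raw, _ = np.histogram(first.mp["P"], bins=bins)
    h_bis, _ = np.histogram(first.mp["M"], bins=bins)
    interior_max = int(h_bis[2:8].max())
    return {
        "median_contrast": float(np.median(contrasts)),
        "n_seeds": float(len(contrasts)),
        "raw_mode_bin": float(np.argmax(h_raw)),
        "bisulfite_low_bin": float(h_bis[0]),
        "bisulfite_high_bin": float(h_bis[-1]),
        "bisulfite_interior_max": float(interior_max),
    }


def clock_recovery(seed: int = 0, n_iterations: int = 100) -> tuple[dict[str, float], ClockReport]:
    """Full clock protocol on the standard aging cohort (n=38, 2000 loci)."""
    cfg = default_array_config(seed=seed)
    report = run_clock_experiment(
        cfg, ClockConfig(n_iterations=n_iterations, seed=seed), include_genotype=True
    )
    tukey = report.score_summary.tukey
    def _reject(a: str, b: str) -> bool:
        row = tukey[
            ((tukey["cond_a"] == a) & (tukey["cond_b"] == b))
            | ((tukey["cond_a"] == b) & (tukey["cond_b"] == a))
        ]
        return bool(row["reject"].iloc[0])

    out = {f"mean_score_{k}": float(v) for k, v in report.mean_scores.items()}
    out.update({f"mean_mae_{k}": float(v) for k, v in report.mean_maes.items()})
    out["anova_f_score"] = float(report.score_summary.anova_f)
    out["tukey_rejects_converted_vs_dummy"] = float(_reject("converted", "dummy"))
    out["tukey_rejects_converted_vs_permuted"] = float(_reject("converted", "permuted"))
    out["acceleration_r_mean"] = float(report.acceleration_r_mean)
    out["overlap_rf"] = float(report.overlap_rf)
    return out, report


def null_calibration(
    base_seed: int = 0, n_seeds: int = 50, n_iterations: int = 10
) -> dict[str, float]:
    """Behaviour with age_effect_slope = 0: nothing should look predictive.

    Reports the fraction of seeds where the cross-condition ANOVA on
    test score does not reject at 0.05, and the fraction of seeds where
    the MI filter (applied to a 75% training split of the converted
    channel) selects zero loci.
    """
    non_reject = 0
    empty_selection = 0
    for s in range(n_seeds):
        seed = base_seed + s
        cfg = default_array_config(seed=seed).replace(
            age_effect_slope=0.0, genotype_age_slope=0.0
        )
        clock_cfg = ClockConfig(n_iterations=n_iterations, seed=seed)
        report = run_clock_experiment(cfg, clock_cfg, include_genotype=False)
        non_reject += report.score_summary.anova_p >= 0.05

        conv, _, ages = synthio.simulate_array_cohort(cfg)
        conv = clockkit.impute_missing(conv, k=clock_cfg.knn_k)
        rng = np.random.default_rng([seed, 1000])
        n = len(ages)
        train = sorted(rng.permutation(n)[: int(round(0.75 * n))])
        train_samples = [conv.samples[i] for i in train]
        selected = clockkit.select_features_mi(
            conv.values[train_samples], ages.iloc[train], 0.20, seed=seed
        )
        empty_selection += len(selected) == 0
    return {
        "anova_nonrejection_rate": non_reject / n_seeds,
        "mi_empty_selection_rate": empty_selection / n_seeds,
        "n_seeds": float(n_seeds),
    }


def overlap_null(
    seed: int = 0, n_iterations: int = 10, n_resamples: int = 1000
) -> dict[str, float]:
    """Cross-channel selected-loci overlap under disjoint designated loci.

    The observed representation factor of the converted/unconverted
    selected-locus unions is compared against a Monte-Carlo null of
    equally sized random sets; reported as a z-like deviation in units
    of the null's spread.
    """
    cfg = default_array_config(seed=seed).replace(frac_age_loci_shared=0.0)
    conv, unconv, _ = synthio.simulate_array_cohort(cfg)
    channels = {
        "converted": clockkit.impute_missing(conv),
        "unconverted": clockkit.impute_missing(unconv),
    }
    reps = clockkit.repeated_evaluation(channels, ClockConfig(n_iterations=n_iterations, seed=seed))
    A = clockkit.selected_union(reps, "converted")
    B = clockkit.selected_union(reps, "unconverted")
    universe = set(channels["converted"].loci)
    rf_obs, p_obs = set_overlap_rf(A, B, universe)

    rng = np.random.default_rng(seed)
    pool = np.array(sorted(universe))
    null_rfs = np.empty(n_resamples)
    for i in range(n_resamples):
        ra = set(rng.choice(pool, size=len(A), replace=False).tolist())
        rb = set(rng.choice(pool, size=len(B), replace=False).tolist())
        null_rfs[i] = set_overlap_rf(ra, rb, universe)[0]
    sd = float(null_rfs.std(ddof=1))
    return {
        "rf_observed": float(rf_obs),
        "rf_p": float(p_obs),
        "null_mean": float(null_rfs.mean()),
        "null_sd": sd,
        "z_abs": abs(rf_obs - 1.0) / sd if sd > 0 else float("inf"),
        "n_resamples": float(n_resamples),
    }


def leakage_scan(seed: int = 0, n_iterations: int = 100, n_loci: int = 2000) -> dict[str, float]:
    """Train/test leakage probe for the MI filter.

    Metamorphic check: for each iteration's train/test split, the filter
    runs on two cohorts that are identical except that one locus is made
    perfectly age-informative in the *test* samples of that split.  A
    leakage-free filter, which only ever sees training samples, must
    return the same selection on both cohorts in every iteration; any
    difference is a leakage event.  (A pure-noise locus can still be
    selected by chance on its training values — that is the filter's
    null exceedance, not leakage, and is reported separately.)
    """
    cfg = default_array_config(seed=seed)
    rng = np.random.default_rng(seed)
    n = cfg.n_samples
    ages = synthio.simulate_ages(cfg)
    samples = list(ages.index)
    labels = synthio.locus_labels(n_loci)
    noise = rng.uniform(0.0, 100.0, size=(n_loci, n))
    planted = labels[0]
    n_train = int(round(0.75 * n))
    leakage_events = 0
    chance_selections = 0
    for i in range(n_iterations):
        split_rng = np.random.default_rng([seed, 1000 + i])
        perm = split_rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        values = noise.copy()
        values[0, test_idx] = np.clip(ages.to_numpy()[test_idx] * 4.0, 0.0, 100.0)
        train_samples = [samples[j] for j in train_idx]
        ages_train = ages.iloc[train_idx]
        sel_noise = clockkit.select_features_mi(
            pd.DataFrame(noise, index=labels, columns=samples)[train_samples],
            ages_train, 0.20, seed=seed + i,
        )
        sel_planted = clockkit.select_features_mi(
            pd.DataFrame(values, index=labels, columns=samples)[train_samples],
            ages_train, 0.20, seed=seed + i,
        )
        leakage_events += set(sel_noise) != set(sel_planted)
        chance_selections += planted in sel_noise
    return {
        "leakage_events": float(leakage_events),
        "chance_selections": float(chance_selections),
        "n_iterations": float(n_iterations),
    }
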