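"""M/P correction: adjust bisulfite methylation for mutation leakage.

The M/P ratio divides a locus's bisulfite methylation level (M) by its
pseudomethylation level from raw reads (P), rescaled to percent.  With
no variants P is 100 and the ratio reduces to M; loci where mutation
has removed methylatable cytosines have P < 100 and their methylation
is revised upward toward "fraction of surviving cytosines that are
methylated".  Two boundary policies apply (both flagged): a ratio above
100 (M > P, possible under methylation-biased capture) is capped at
100, and P = 0 — where the ratio is undefined — is reported as the
sentinel 0 so such loci remain visible in downstream distributions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import LocusPartition, StratifiedCorrelation
from .errors import InputError

STRATA = ("all", "mutated", "unmutated")


def _validate_percent(name: str, x: np.ndarray) -> None:
    if np.any((x < 0) | (x > 100) | ~np.isfinite(x)):
        raise InputError(f"{name} values must lie in [0, 100]")


def mp_ratio_flagged(M, P) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized M/P ratio with (degenerate, capped) flags.

    Returns (ratio, degenerate, capped): degenerate marks P == 0 rows
    (sentinel ratio 0); capped marks rows where 100*M/P exceeded 100.
    """
    M = np.asarray(M, dtype=float)
    P = np.asarray(P, dtype=float)
    _validate_percent("M", M)
    _validate_percent("P", P)
    degenerate = P == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(degenerate, 0.0, 100.0 * M / np.where(degenerate, 1.0, P))
    # P == 100 is the identity case; bypass the division so that
    # mp_ratio(M, 100) == M holds exactly in floating point
    raw = np.where(P == 100.0, M, raw)
    capped = raw > 100.0
    ratio = np.clip(raw, 0.0, 100.0)
    return ratio, degenerate, capped


def mp_ratio(M, P):
    """M/P ratio in percent (scalar or array); see ``mp_ratio_flagged``."""
    ratio, _, _ = mp_ratio_flagged(M, P)
    return float(ratio) if ratio.ndim == 0 else ratio


def apparent_shift(M, P):
    """Change in apparent methylation after correction: M - mp_ratio(M, P)."""
    M_arr = np.asarray(M, dtype=float)
    shift = M_arr - np.asarray(mp_ratio(M, P))
    return float(shift) if shift.ndim == 0 else shift


def adjust_table(pairs: pd.DataFrame) -> pd.DataFrame:
    """Apply the M/P correction to a (chrom, pos, sample, M, P) table.

    Adds mp_ratio, delta (= M - mp_ratio) and the degenerate/capped
    flags; input rows are preserved.
    """
    required = {"M", "P"}
    if not required <= set(pairs.columns):
        raise InputError("pairs table needs M and P columns")
    out = pairs.copy()
    ratio, degenerate, capped = mp_ratio_flagged(out["M"].to_numpy(), out["P"].to_numpy())
    out["mp_ratio"] = ratio
    out["delta"] = out["M"].to_numpy() - ratio
    out["degenerate"] = degenerate
    out["capped"] = capped
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, bool, str]:
    if len(x) < 3:
        return float("nan"), False, f"fewer than 3 pairs (n={len(x)})"
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), False, "zero-variance input"
    r = float(stats.pearsonr(x, y).statistic)
    return r, True, ""


def stratified_correlation(
    pairs: pd.DataFrame, partition: LocusPartition
) -> list[StratifiedCorrelation]:
    """Pearson r between M and P within all / mutated / unmutated loci.

    Pairs are (M, P) per (locus, sample) row; stratum membership is
    decided by the locus key (chrom, pos).  Strata with fewer than 3
    pairs or zero variance report an undefined r, never 0.
    """
    required = {"chrom", "pos", "M", "P"}
    if not required <= set(pairs.columns):
        raise InputError("pairs table needs chrom, pos, M, P columns")
    keys = list(zip(pairs["chrom"], pairs["pos"]))
    in_mut = np.array([k in partition.mutated for k in keys])
    in_common = np.array([k in partition.common_loci for k in keys])

    masks = {
        "all": in_common,
        "mutated": in_common & in_mut,
        "unmutated": in_common & ~in_mut,
    }
    out = []
    for stratum in STRATA:
        sub = pairs[masks[stratum]]
        r, defined, note = _pearson(sub["M"].to_numpy(), sub["P"].to_numpy())
        out.append(
            StratifiedCorrelation(
                stratum=stratum, r=r, n=len(sub), defined=defined, note=note
            )
        )
    return out
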