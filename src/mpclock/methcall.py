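"""Methylation / pseudomethylation calling from pileup counts.

The level of a site is simple cytosine retention, 100 * C / (C + T),
computed identically for bisulfite reads (where it measures
methylation, M) and for raw shotgun reads (where it measures
"pseudomethylation", P — deviations from 100% reflect genetic variants,
not methylation).  Loci are then filtered to those confidently covered
in every sample under every modality, and partitioned by overlap with
independently called variants.
"""

from __future__ import annotations

import logging

import pandas as pd

from .containers import LocusPartition, VariantRecord
from .errors import InputError

logger = logging.getLogger(__name__)

#: locus identity used throughout this module
LocusKey = tuple  # (chrom, pos)


def call_levels(pileup: pd.DataFrame) -> pd.DataFrame:
    """Compute percent-C levels per (locus, sample, modality).

    Returns the pileup rows with positive coverage plus ``coverage`` and
    ``level`` columns; zero-coverage rows are dropped (and counted in the
    log) because the level is undefined there.
    """
    required = {"chrom", "pos", "sample", "modality", "count_C", "count_T"}
    missing = required - set(pileup.columns)
    if missing:
        raise InputError(f"pileup lacks columns {sorted(missing)}")
    if (pileup["count_C"] < 0).any() or (pileup["count_T"] < 0).any():
        raise InputError("read counts must be nonnegative")
    out = pileup.copy()
    out["coverage"] = out["count_C"] + out["count_T"]
    n_zero = int((out["coverage"] == 0).sum())
    if n_zero:
        logger.info("dropping %d zero-coverage rows", n_zero)
    out = out[out["coverage"] > 0].copy()
    out["level"] = 100.0 * out["count_C"] / out["coverage"]
    return out


def filter_by_coverage(
    levels: pd.DataFrame,
    threshold: int,
    samples: list[str] | None = None,
    modalities: list[str] | None = None,
) -> set[LocusKey]:
    """Loci whose coverage strictly exceeds ``threshold`` everywhere.

    "Everywhere" means in every listed sample under every listed
    modality; a locus absent from any required (sample, modality) cell
    has coverage 0 there and is excluded.
    """
    if threshold < 0:
        raise InputError("coverage threshold must be >= 0")
    if samples is None:
        samples = sorted(levels["sample"].unique())
    if modalities is None:
        modalities = sorted(levels["modality"].unique())
    if not samples:
        raise InputError("sample list must be non-empty")
    if not modalities:
        raise InputError("modality list must be non-empty")

    sub = levels[levels["sample"].isin(samples) & levels["modality"].isin(modalities)]
    wide = sub.pivot_table(
        index=["chrom", "pos"],
        columns=["sample", "modality"],
        values="coverage",
        aggfunc="sum",
        fill_value=0,
    )
    needed = [(s, m) for s in samples for m in modalities]
    for cell in needed:
        if cell not in wide.columns:
            return set()  # an entire sample x modality layer is absent
    ok = (wide[needed] > threshold).all(axis=1)
    return set(map(tuple, wide.index[ok]))


def partition_by_variants(
    loci: set[LocusKey], variants: list[VariantRecord]
) -> LocusPartition:
    """Split coverage-passing loci by overlap with variant calls.

    A locus (chrom, pos) is mutated iff some variant's reference span
    covers pos: a single position for SNVs, the full deleted stretch for
    deletions (multi-base REF).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v.span)
    mutated = set()
    for locus in loci:
        chrom, pos = locus[0], int(locus[1])
        for start, end in by_chrom.get(chrom, ()):
            if start <= pos < end:
                mutated.add(locus)
                break
    common = frozenset(loci)
    mutated_f = frozenset(mutated)
    return LocusPartition(
        common_loci=common, mutated=mutated_f, unmutated=common - mutated_f
    )


def levels_wide(levels: pd.DataFrame, loci: set[LocusKey] | None = None) -> pd.DataFrame:
    """Pivot levels to one row per (locus, sample) with M and P columns.

    M is the bisulfite level and P the raw level; rows lacking either
    modality are dropped.  Restricting to ``loci`` applies first.
    """
    sub = levels
    if loci is not None:
        key = list(zip(sub["chrom"], sub["pos"]))
        sub = sub[[k in loci for k in key]]
    wide = sub.pivot_table(
        index=["chrom", "pos", "sample"], columns="modality", values="level"
    ).reset_index()
    wide.columns.name = None
    if "bisulfite" not in wide.columns or "raw" not in wide.columns:
        raise InputError("both bisulfite and raw modalities are required")
    wide = wide.rename(columns={"bisulfite": "M", "raw": "P"}).dropna(subset=["M", "P"])
    return wide[["chrom", "pos", "sample", "M", "P"]]
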