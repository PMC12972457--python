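"""Core in-memory containers shared across modules.

Tabular data (pileups, site levels, M/P tables) travel as pandas
DataFrames with documented column contracts; the dataclasses here wrap
the objects that carry extra structure (ground truth, matrices with
ages, fitted clock replicates, test summaries).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import InputError

#: columns of a pileup table (one row per locus x sample x modality)
PILEUP_COLUMNS = ["locus", "chrom", "pos", "sample", "modality", "count_C", "count_T"]

MODALITIES = ("bisulfite", "raw")


class VariantRecord(NamedTuple):
    """A called variant in 0-based coordinates (``pos`` is the first ref base)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float = float("nan")

    @property
    def span(self) -> tuple[int, int]:
        """Half-open interval of reference bases the variant touches."""
        return self.pos, self.pos + max(1, len(self.ref))


@dataclass
class TruthState:
    """Simulated ground truth for the sequencing experiment.

    ``loci`` has columns chrom, pos (0-based), strand, context (CpG/CH),
    ref; ``true_methylation`` is a fraction per locus; ``variants`` has
    columns locus (index into ``loci``), ref, alt, vaf.
    """

    loci: pd.DataFrame
    true_methylation: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.loci)
        if len(self.true_methylation) != n:
            raise InputError("true_methylation length must match loci")
        if len(self.variants) and (
            (self.variants["locus"] < 0) | (self.variants["locus"] >= n)
        ).any():
            raise InputError("variant locus index out of range")
        if len(self.variants) and (
            (self.variants["vaf"] <= 0) | (self.variants["vaf"] > 1)
        ).any():
            raise InputError("variant VAF must lie in (0, 1]")

    def variant_records(self) -> list[VariantRecord]:
        out = []
        for row in self.variants.itertuples(index=False):
            locus = self.loci.iloc[int(row.locus)]
            out.append(
                VariantRecord(str(locus["chrom"]), int(locus["pos"]), row.ref, row.alt, row.vaf)
            )
        return out


@dataclass
class BetaMatrix:
    """A loci x samples percent-signal matrix with per-sample ages.

    ``values`` is indexed by locus label with one column per sample id;
    entries are percent-scale (or {0,1,2} for the allele-call channel)
    and may be NaN before imputation.  ``ages`` is indexed by sample id.
    """

    values: pd.DataFrame
    ages: pd.Series
    channel: str

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.ages.index):
            raise InputError("sample ids of values and ages must match in order")
        if len(self.ages) and not np.isfinite(self.ages.to_numpy()).all():
            raise InputError("ages must be finite")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def loci(self) -> list[str]:
        return list(self.values.index)


@dataclass
class LocusPartition:
    """Coverage-passing loci split by somatic-variant overlap."""

    common_loci: frozenset
    mutated: frozenset
    unmutated: frozenset

    def __post_init__(self) -> None:
        if self.mutated | self.unmutated != self.common_loci:
            raise InputError("mutated and unmutated must partition common_loci")
        if self.mutated & self.unmutated:
            raise InputError("mutated and unmutated must be disjoint")


@dataclass
class StratifiedCorrelation:
    """Pearson r of (M, P) pairs within one locus stratum."""

    stratum: str
    r: float
    n: int
    defined: bool
    note: str = ""


@dataclass
class ClockReplicate:
    """One train/test split's fitted model under one condition."""

    iteration: int
    condition: str
    selected_loci: list[str]
    coefficients: np.ndarray
    intercept: float
    test_score: float
    test_mae: float
    train_samples: list[str]
    test_samples: list[str]
    predictions: pd.Series  # indexed by test sample id
    converged: bool = True

    def __post_init__(self) -> None:
        if self.test_mae < 0:
            raise InputError("test_mae must be >= 0")
        if self.condition == "dummy" and len(self.coefficients):
            raise InputError("dummy replicates carry no coefficients")


@dataclass
class EvaluationSummary:
    """One-way ANOVA + Tukey HSD across clock conditions for one metric."""

    metric: str
    groups: dict[str, np.ndarray]
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # columns: cond_a, cond_b, mean_diff, p_adj, reject
    excluded: list[str] = field(default_factory=list)

    def rejected_pairs(self) -> set[frozenset]:
        return {
            frozenset((row.cond_a, row.cond_b))
            for row in self.tukey.itertuples(index=False)
            if row.reject
        }


@dataclass
class EnrichmentResult:
    """A 2x2 interval-overlap test against a background."""

    feature: str
    k: int
    n: int
    K: int
    N: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    representation_factor: float
    window: int = 0
    corrected: bool = False  # Haldane-Anscombe 0.5 applied to a zero cell
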