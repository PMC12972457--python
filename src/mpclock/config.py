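"""Simulation and clock-training configuration.

``SimConfig`` holds every knob of the synthetic-data generators.  The
defaults describe the study conditions the generators emulate: a small
panel of clonally expanded cancer lines (6 samples, ~30x shotgun
coverage, 5% of loci carrying a somatic variant enriched for C>T at
CpGs) for the sequencing experiment, and a hippocampal aging cohort
(38 samples, 4-24 months, ~1.5% of array loci carrying a ~1 %/month
linear age effect with ~2% assay noise) for the array experiment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .errors import ConfigError


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class VafLaw:
    """Mixture law for somatic variant allele frequencies.

    A ``clonal_weight`` fraction of variants are near-clonal (VAF drawn
    uniformly from ``clonal_vafs``, i.e. heterozygous-like 0.5 or fixed
    1.0 after clonal expansion); the rest are subclonal with
    Beta(``subclonal_a``, ``subclonal_b``)-distributed low frequencies.
    """

    clonal_weight: float = 0.6
    clonal_vafs: tuple[float, ...] = (0.5, 1.0)
    subclonal_a: float = 1.5
    subclonal_b: float = 6.0

    def validate(self) -> None:
        _check_fraction("vaf_law.clonal_weight", self.clonal_weight)
        if not self.clonal_vafs:
            raise ConfigError("vaf_law.clonal_vafs must be non-empty")
        for v in self.clonal_vafs:
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"clonal VAF must lie in (0, 1], got {v!r}")
        if self.subclonal_a <= 0 or self.subclonal_b <= 0:
            raise ConfigError("subclonal Beta parameters must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic sequencing / array / genotype cohorts.

    Units: ages in months, coverage in reads per locus, levels and noise
    in percent methylation, slopes in percent per month.
    """

    n_loci: int = 2000
    n_samples: int = 6
    age_range: tuple[float, float] = (4.0, 24.0)
    coverage_mean: float = 30.0
    #: probability that an unmethylated cytosine is read as T after bisulfite
    conversion_efficiency: float = 0.99
    #: strength of methylated-read retention during capture; unmethylated
    #: molecules survive with relative probability exp(-capture_bias).
    #: Kept mild so the converted level distribution stays bimodal.
    capture_bias: float = 0.3
    mutation_rate: float = 0.05
    #: per-read probability of a C<->T miscall (both modalities); gives the
    #: raw channel its sub-100% tail at unmutated loci
    seq_error_rate: float = 0.002
    vaf_law: VafLaw = field(default_factory=VafLaw)
    #: probabilities of (C>T, C>A, T>C) given that a locus carries a variant
    variant_type_probs: tuple[float, float, float] = (0.8, 0.1, 0.1)
    #: weight of the high mode in the bimodal true-methylation mixture
    methylated_weight: float = 0.45
    frac_age_loci_converted: float = 0.015
    frac_age_loci_unconverted: float = 0.015
    frac_age_loci_shared: float = 0.005
    age_effect_slope: float = 1.0
    noise_sd: float = 2.0
    #: the mock-converted channel is noisier than the converted one
    unconverted_noise_multiplier: float = 2.0
    #: sd (months) of a per-sample "apparent age" offset shared by all
    #: age-informative loci in both channels; induces correlated age
    #: acceleration across modalities
    sample_noise_sd: float = 1.0
    #: genotype cohort: fraction of loci whose allele frequency drifts with
    #: age, and the drift slope (allele-frequency units per month)
    frac_age_loci_genotype: float = 0.004
    genotype_age_slope: float = 0.045
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci <= 0 or self.n_samples <= 0:
            raise ConfigError("n_loci and n_samples must be positive")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigError(f"age_range must satisfy min < max, got {self.age_range!r}")
        if self.coverage_mean <= 0:
            raise ConfigError("coverage_mean must be positive")
        for name in (
            "conversion_efficiency",
            "mutation_rate",
            "frac_age_loci_converted",
            "frac_age_loci_unconverted",
            "frac_age_loci_shared",
            "frac_age_loci_genotype",
            "missing_rate",
            "methylated_weight",
            "seq_error_rate",
        ):
            _check_fraction(name, getattr(self, name))
        if self.capture_bias < 0:
            raise ConfigError("capture_bias must be >= 0")
        if self.frac_age_loci_shared > min(
            self.frac_age_loci_converted, self.frac_age_loci_unconverted
        ):
            raise ConfigError(
                "frac_age_loci_shared must not exceed either channel's fraction"
            )
        if abs(sum(self.variant_type_probs) - 1.0) > 1e-9 or min(self.variant_type_probs) < 0:
            raise ConfigError("variant_type_probs must be nonnegative and sum to 1")
        if self.noise_sd < 0 or self.sample_noise_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if self.unconverted_noise_multiplier < 0 or self.genotype_age_slope < 0:
            raise ConfigError("multipliers and slopes must be >= 0")
        self.vaf_law.validate()

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


def default_sequencing_config(seed: int = 0, **overrides) -> SimConfig:
    """The paired WGSS/bisulfite experiment: 6 clones at 30x."""
    return SimConfig(seed=seed, **overrides)


def default_array_config(seed: int = 0, **overrides) -> SimConfig:
    """The paired converted/unconverted array cohort: 38 samples, 4-24 months."""
    overrides.setdefault("n_samples", 38)
    return SimConfig(seed=seed, **overrides)


@dataclass(frozen=True)
class ClockConfig:
    """Two-layer cross-validated clock protocol parameters."""

    mi_threshold: float = 0.20
    train_fraction: float = 0.75
    n_iterations: int = 100
    cv_folds: int = 2
    max_iterations: int = 10_000
    l1_ratios: tuple[float, ...] = (0.1, 0.5, 0.7, 0.9, 0.95, 0.99, 1.0)
    knn_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError("train_fraction must lie strictly in (0, 1)")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if self.n_iterations <= 0 or self.max_iterations <= 0 or self.knn_k <= 0:
            raise ConfigError("iteration counts and knn_k must be positive")
        if self.mi_threshold < 0 and self.mi_threshold != float("-inf"):
            raise ConfigError("mi_threshold must be >= 0")

    def replace(self, **kwargs) -> "ClockConfig":
        return dataclasses.replace(self, **kwargs)
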