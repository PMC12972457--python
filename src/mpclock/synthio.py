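"""Synthetic-data generators for every stage of the analysis.

Three cohorts are emulated:

* a paired sequencing experiment — clonally expanded cell lines carrying
  somatic variants (C>T-enriched at CpGs), read both raw (shotgun) and
  after bisulfite conversion with imperfect efficiency and a capture
  step that preferentially retains methylated molecules;
* a paired methylation-array cohort — converted and mock-converted
  channels over the same samples, with partially overlapping sets of
  age-informative loci, a noisier unconverted channel, a shared
  per-sample apparent-age offset, and missing entries;
* a genotyping-array cohort — trinary allele calls plus continuous
  fluorescence, with a handful of loci whose allele frequency drifts
  with age, giving a weak but real age signal.

Every generator is a pure function of its ``SimConfig``: a fixed seed
reproduces the output exactly.  Per-read events are simulated with
vectorized binomial thinning rather than read loops, which is exact for
the per-locus C/T counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimConfig
from .containers import MODALITIES, PILEUP_COLUMNS, BetaMatrix, TruthState
from .errors import ConfigError

# rng stream tags, so each generator draws from an independent stream of
# the same seed
_STREAM_TRUTH = 1
_STREAM_READS = {"bisulfite": 2, "raw": 3}
_STREAM_AGES = 9
_STREAM_ARRAY = 10
_STREAM_GENOTYPE = 11

# variant type codes on the loci table
VT_NONE, VT_CT, VT_CA, VT_TC = 0, 1, 2, 3
_VT_REF_ALT = {VT_CT: ("C", "T"), VT_CA: ("C", "A"), VT_TC: ("T", "C")}


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def locus_labels(n_loci: int) -> list[str]:
    return [f"L{i:05d}" for i in range(n_loci)]


def simulate_truth(config: SimConfig) -> TruthState:
    """Draw loci, bimodal true methylation, and somatic variants.

    True methylation is a mixture of Beta(1, 8) (unmethylated mode) and
    Beta(8, 1) (methylated mode).  A ``mutation_rate`` fraction of loci
    carry one variant; types are drawn from ``variant_type_probs``
    (C>T majority, C>A and T>C minorities) and VAFs from the clonal /
    subclonal mixture law.  Loci hosting a T>C variant have reference
    base T (a site that a mutation renders methylatable).
    """
    rng = _rng(config, _STREAM_TRUTH)
    n = config.n_loci

    pos = np.sort(rng.choice(n * 200, size=n, replace=False)).astype(int)
    strand = np.where(rng.random(n) < 0.5, "+", "-")
    context = np.where(rng.random(n) < 0.9, "CpG", "CH")

    is_meth_mode = rng.random(n) < config.methylated_weight
    true_m = np.where(
        is_meth_mode, rng.beta(8.0, 1.0, size=n), rng.beta(1.0, 8.0, size=n)
    )

    has_variant = rng.random(n) < config.mutation_rate
    idx = np.flatnonzero(has_variant)
    vtypes = rng.choice(
        [VT_CT, VT_CA, VT_TC], size=idx.size, p=list(config.variant_type_probs)
    )

    law = config.vaf_law
    clonal = rng.random(idx.size) < law.clonal_weight
    vaf = np.where(
        clonal,
        rng.choice(list(law.clonal_vafs), size=idx.size),
        np.clip(rng.beta(law.subclonal_a, law.subclonal_b, size=idx.size), 0.02, 1.0),
    )

    ref = np.full(n, "C", dtype=object)
    ref[idx[vtypes == VT_TC]] = "T"

    loci = pd.DataFrame(
        {"chrom": "chr1", "pos": pos, "strand": strand, "context": context, "ref": ref}
    )
    variants = pd.DataFrame(
        {
            "locus": idx,
            "ref": [_VT_REF_ALT[t][0] for t in vtypes],
            "alt": [_VT_REF_ALT[t][1] for t in vtypes],
            "vaf": vaf,
            "vtype": vtypes,
        }
    )
    return TruthState(loci=loci, true_methylation=true_m, variants=variants)


def _variant_arrays(truth: TruthState) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (vaf, vtype) arrays; vaf 0 / VT_NONE where unmutated."""
    n = len(truth.loci)
    vaf = np.zeros(n)
    vtype = np.full(n, VT_NONE)
    if len(truth.variants):
        li = truth.variants["locus"].to_numpy()
        vaf[li] = truth.variants["vaf"].to_numpy()
        vtype[li] = truth.variants["vtype"].to_numpy()
    return vaf, vtype


def simulate_reads(truth: TruthState, config: SimConfig, modality: str) -> pd.DataFrame:
    """Simulate a pileup table (C/T read counts) for one modality.

    Per read: the mutant allele is drawn with probability VAF.  In the
    ``raw`` modality a reference C reads C (pseudomethylated) and a C>T
    mutant reads T.  In the ``bisulfite`` modality a methylated C stays
    C, an unmethylated C converts to T with ``conversion_efficiency``,
    and a C>T mutant reads T; capture then retains methylated-molecule
    reads preferentially (unmethylated molecules survive with relative
    probability exp(-capture_bias)).  C>A mutant reads fall outside the
    C/T pileup and are discarded; T>C loci read T on the reference
    allele and behave as new unmethylated cytosines on the mutant one.
    Finally a ``seq_error_rate`` fraction of calls flips C<->T in either
    modality, giving the raw channel its sub-100% tail at unmutated loci.
    """
    if modality not in MODALITIES:
        raise ConfigError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
    rng = _rng(config, _STREAM_READS[modality])
    n = len(truth.loci)
    m = np.asarray(truth.true_methylation, dtype=float)
    vaf, vtype = _variant_arrays(truth)
    retain = np.exp(-config.capture_bias)
    eff = config.conversion_efficiency

    frames = []
    for s in range(config.n_samples):
        cov = rng.poisson(config.coverage_mean, size=n)
        n_alt = rng.binomial(cov, vaf)
        n_ref = cov - n_alt

        count_C = np.zeros(n, dtype=int)
        count_T = np.zeros(n, dtype=int)

        ref_is_c = vtype != VT_TC
        if modality == "raw":
            count_C += np.where(ref_is_c, n_ref, 0)
            count_T += np.where(ref_is_c, 0, n_ref)
            count_T += np.where(vtype == VT_CT, n_alt, 0)
            count_C += np.where(vtype == VT_TC, n_alt, 0)
            # C>A mutant reads are neither C nor T: dropped
        else:
            ref_c = np.where(ref_is_c, n_ref, 0)
            n_meth = rng.binomial(ref_c, m)
            n_unmeth = ref_c - n_meth
            conv_T = rng.binomial(n_unmeth, eff)
            unconv_C = n_unmeth - conv_T
            ref_T = np.where(ref_is_c, 0, n_ref)

            alt_T = np.where(vtype == VT_CT, n_alt, 0)
            tc_alt = np.where(vtype == VT_TC, n_alt, 0)
            tc_conv_T = rng.binomial(tc_alt, eff)
            tc_unconv_C = tc_alt - tc_conv_T

            if config.capture_bias > 0:
                # methylated molecules always survive capture; everything
                # else is thinned
                unconv_C = rng.binomial(unconv_C, retain)
                conv_T = rng.binomial(conv_T, retain)
                ref_T = rng.binomial(ref_T, retain)
                alt_T = rng.binomial(alt_T, retain)
                tc_conv_T = rng.binomial(tc_conv_T, retain)
                tc_unconv_C = rng.binomial(tc_unconv_C, retain)

            count_C = n_meth + unconv_C + tc_unconv_C
            count_T = conv_T + ref_T + alt_T + tc_conv_T

        if config.seq_error_rate > 0:
            c_to_t = rng.binomial(count_C, config.seq_error_rate)
            t_to_c = rng.binomial(count_T, config.seq_error_rate)
            count_C = count_C - c_to_t + t_to_c
            count_T = count_T - t_to_c + c_to_t

        frames.append(
            pd.DataFrame(
                {
                    "locus": np.arange(n),
                    "chrom": truth.loci["chrom"].to_numpy(),
                    "pos": truth.loci["pos"].to_numpy(),
                    "sample": f"S{s + 1}",
                    "modality": modality,
                    "count_C": count_C,
                    "count_T": count_T,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[PILEUP_COLUMNS]


def expected_bisulfite_fraction_c(
    m: float, vaf: float, efficiency: float, capture_bias: float
) -> float:
    """Closed-form expected %C among retained bisulfite reads at a C>T locus.

    Retention weight is 1 for methylated molecules and exp(-capture_bias)
    otherwise; the reference allele has probability 1 - vaf.
    """
    p = np.exp(-capture_bias)
    c_weight = (1 - vaf) * m + (1 - vaf) * (1 - m) * (1 - efficiency) * p
    t_weight = (1 - vaf) * (1 - m) * efficiency * p + vaf * p
    total = c_weight + t_weight
    return float(c_weight / total) if total > 0 else float("nan")


def simulate_ages(config: SimConfig) -> pd.Series:
    """Sample ages (months) uniformly over ``age_range``, sorted ascending.

    Drawn from a dedicated stream so the array and genotype cohorts of
    the same config see identical samples and ages.
    """
    rng = _rng(config, _STREAM_AGES)
    lo, hi = config.age_range
    ages = np.sort(rng.uniform(lo, hi, size=config.n_samples))
    samples = [f"S{i + 1}" for i in range(config.n_samples)]
    return pd.Series(ages, index=samples, name="age_months")


def _age_locus_sets(rng: np.random.Generator, config: SimConfig):
    n = config.n_loci
    n_conv = int(round(config.frac_age_loci_converted * n))
    n_unconv = int(round(config.frac_age_loci_unconverted * n))
    n_shared = int(round(config.frac_age_loci_shared * n))
    n_shared = min(n_shared, n_conv, n_unconv)
    need = n_conv + n_unconv - n_shared
    if need > n:
        raise ConfigError("age-informative fractions exceed the locus panel")
    perm = rng.permutation(n)
    shared = perm[:n_shared]
    conv_only = perm[n_shared:n_conv]
    unconv_only = perm[n_conv : n_conv + (n_unconv - n_shared)]
    conv = np.concatenate([shared, conv_only])
    unconv = np.concatenate([shared, unconv_only])
    return conv, unconv, shared


def simulate_array_cohort(
    config: SimConfig,
) -> tuple[BetaMatrix, BetaMatrix, pd.Series]:
    """Paired converted / unconverted percent matrices plus ages.

    Each channel has its own designated age-informative loci (sizes set
    by the ``frac_age_loci_*`` fields, overlapping in the shared set).
    An informative locus follows baseline + s * slope * (age - midpoint
    + u_sample) + noise, where s is a per-locus random sign and
    u_sample is the shared apparent-age offset; other loci are baseline
    + noise.  The unconverted channel's noise is inflated by
    ``unconverted_noise_multiplier``.  Values are clipped to [0, 100]
    and a ``missing_rate`` fraction of entries is set to NaN.
    """
    rng = _rng(config, _STREAM_ARRAY)
    ages = simulate_ages(config)
    n, k = config.n_loci, config.n_samples
    conv_idx, unconv_idx, _ = _age_locus_sets(rng, config)

    age_mid = float(np.mean(config.age_range))
    u = rng.normal(0.0, config.sample_noise_sd, size=k)
    age_term = ages.to_numpy() - age_mid + u  # shared across channels

    labels = locus_labels(n)
    out = {}
    for channel, idx, mult in (
        ("converted", conv_idx, 1.0),
        ("unconverted", unconv_idx, config.unconverted_noise_multiplier),
    ):
        baseline = rng.uniform(5.0, 95.0, size=n)
        sign = rng.choice([-1.0, 1.0], size=n)
        values = np.tile(baseline[:, None], (1, k))
        if idx.size:
            values[idx, :] += (
                sign[idx, None] * config.age_effect_slope * age_term[None, :]
            )
        values += rng.normal(0.0, config.noise_sd * mult, size=(n, k))
        values = np.clip(values, 0.0, 100.0)
        if config.missing_rate > 0:
            mask = rng.random((n, k)) < config.missing_rate
            values = np.where(mask, np.nan, values)
        df = pd.DataFrame(values, index=labels, columns=list(ages.index))
        out[channel] = BetaMatrix(values=df, ages=ages.copy(), channel=channel)
    return out["converted"], out["unconverted"], ages


def array_informative_loci(config: SimConfig) -> dict[str, list[str]]:
    """Designated age-informative locus labels per array channel."""
    rng = _rng(config, _STREAM_ARRAY)
    conv_idx, unconv_idx, shared = _age_locus_sets(rng, config)
    labels = np.array(locus_labels(config.n_loci))
    return {
        "converted": sorted(labels[conv_idx]),
        "unconverted": sorted(labels[unconv_idx]),
        "shared": sorted(labels[shared]),
    }


def simulate_genotype_cohort(
    config: SimConfig,
) -> tuple[BetaMatrix, BetaMatrix, pd.Series]:
    """Genotyping-array cohort: trinary allele calls and continuous signal.

    Genotypes are Binomial(2, p) draws; at the few age-informative loci
    the allele frequency drifts linearly with age (slope
    ``genotype_age_slope`` per month, clipped to [0.02, 0.98]), a
    cross-sectional stand-in for age-associated somatic allele shifts.
    The signal channel is an affine dosage readout with Gaussian noise,
    so both channels share the same informative loci and the signal
    carries strictly less information than the calls.
    """
    rng = _rng(config, _STREAM_GENOTYPE)
    ages = simulate_ages(config)
    n, k = config.n_loci, config.n_samples
    n_info = int(round(config.frac_age_loci_genotype * n))
    info_idx = rng.permutation(n)[:n_info]

    maf = rng.uniform(0.1, 0.5, size=n)
    p = np.tile(maf[:, None], (1, k))
    age_mid = float(np.mean(config.age_range))
    if n_info:
        sign = rng.choice([-1.0, 1.0], size=n_info)
        drift = sign[:, None] * config.genotype_age_slope * (
            ages.to_numpy()[None, :] - age_mid
        )
        p[info_idx, :] = np.clip(0.5 + drift, 0.02, 0.98)
    calls = rng.binomial(2, p).astype(float)
    signal = np.clip(10.0 + 40.0 * calls + rng.normal(0.0, 4.0, size=(n, k)), 0.0, 100.0)

    labels = locus_labels(n)
    samples = list(ages.index)
    allele = BetaMatrix(
        values=pd.DataFrame(calls, index=labels, columns=samples),
        ages=ages.copy(),
        channel="allele_call",
    )
    sig = BetaMatrix(
        values=pd.DataFrame(signal, index=labels, columns=samples),
        ages=ages.copy(),
        channel="array_signal",
    )
    return allele, sig, ages


def genotype_informative_loci(config: SimConfig) -> list[str]:
    rng = _rng(config, _STREAM_GENOTYPE)
    n_info = int(round(config.frac_age_loci_genotype * config.n_loci))
    info_idx = rng.permutation(config.n_loci)[:n_info]
    labels = np.array(locus_labels(config.n_loci))
    return sorted(labels[info_idx])
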