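# Methods

## Background and model

Bisulfite-based methylation assays encode methylation as a base
difference: unmethylated cytosine deaminates to uracil and is read as
T, methylated cytosine stays C, and the methylation level of a locus is
the cytosine retention fraction, 100·C/(C+T), over reads covering a
reference cytosine. The same counting applied to *unconverted* DNA
yields **pseudomethylation** (P): absent mutations every raw read
matches the reference and P = 100; somatic C>T variants pull P below
100 in proportion to their allele frequency, and are indistinguishable
from loss of methylation in the converted channel. `mpclock` implements
this confound end to end: a generative model of the paired readouts, the
calling/filtering/partitioning pipeline, the **M/P correction**, a
cross-validated age-clock protocol on paired converted/unconverted
array channels, and hypergeometric enrichment audits.

## Sequencing generator (`synthio.simulate_truth` / `simulate_reads`)

Per locus the generator draws:

* **True methylation** from a bimodal mixture, Beta(1, 8) with weight
  0.55 and Beta(8, 1) with weight 0.45 — methylation in real tissue is
  strongly bimodal, and these shapes give clear modes near 0% and 100%
  without forbidding intermediate values.
* **Coverage** ~ Poisson(`coverage_mean`, default 30) independently per
  sample and modality — the standard shotgun model.
* **Somatic variants** at a `mutation_rate` = 0.05 fraction of loci,
  with types C>T : C>A : T>C = 0.8 : 0.1 : 0.1 (deamination-dominated,
  as in aged and mutagenized genomes). VAFs follow a clonal/subclonal
  mixture: with probability 0.6 a near-clonal value from {0.5, 1.0}
  (heterozygous-like, or fixed by clonal expansion), otherwise
  Beta(1.5, 6) subclonal frequencies. C>A mutant reads are neither C
  nor T and leave the pileup; T>C loci carry reference base T and
  become methylatable only on the mutant allele.
* **Chemistry**: unmethylated C converts with probability
  `conversion_efficiency` (default 0.99, typical of real kits);
  capture retains methylated molecules preferentially — an unmethylated
  molecule survives with relative probability exp(−`capture_bias`).
  The default bias 0.3 is deliberately mild: it reproduces the
  capped (M > P) and degenerate (P = 0 with M > 0) ratio classes while
  leaving the converted level distribution clearly bimodal. Stronger
  bias shifts the unmethylated mode toward mid-range levels, which real
  capture data do not show.
* **Miscalls**: each C/T call flips with probability `seq_error_rate`
  (default 0.002, an Illumina-like substitution rate). Without this
  term P is *exactly* 100 at every unmutated locus and the unmutated
  stratum correlation is undefined; with it, the raw channel acquires
  its realistic sub-100% tail.

Per-read sampling is realized as exact vectorized binomial thinning,
so a 10^5-read locus costs the same as a 30-read locus. The closed-form
expected retained %C (implemented in
`expected_bisulfite_fraction_c` and re-derived independently in the
tests) is

    %C = [(1−v)m + (1−v)(1−m)(1−e)p] / [(1−v)m + (1−v)(1−m)p + v·p],

with m true methylation, v VAF (C>T), e conversion efficiency and
p = exp(−capture_bias).

## Calling, filtering, partitioning (`methcall`)

Levels are 100·C/(C+T) per (locus, sample, modality); zero-coverage
rows are undefined and dropped with a log entry. The coverage filter
keeps loci whose coverage **strictly exceeds** the threshold (default
10) in *every* sample under *both* modalities; it is monotone in the
threshold by construction. Variant intersection marks a locus mutated
iff a variant's reference span covers its position (a single base for
SNVs, the deleted stretch for multi-base REF alleles). Coordinates are
0-based internally; VCF is converted at the I/O boundary, BED is
half-open. Cytosines are tracked per strand with no cross-strand CpG
collapsing.

## The M/P correction (`mpadjust`)

`mp_ratio(M, P) = 100·M/P`, with two explicit boundary policies, both
flagged per row:

* **P = 0** (complete apparent C>T conversion in raw reads): the ratio
  diverges rather than vanishes, so the value is reported as the
  sentinel 0 with a `degenerate` flag. This keeps such loci — which
  are produced by near-fixed C>T variants combined with
  methylation-biased capture in the bisulfite channel — visible in the
  corrected distribution instead of silently dropped.
* **M > P** (bisulfite retention exceeding the raw cytosine fraction):
  ratios above 100 are capped at 100 with a `capped` flag, treating 100
  as "apparent methylation fully explained by the surviving cytosine
  fraction".

`P == 100` bypasses the division entirely so the identity
`mp_ratio(M, 100) == M` holds exactly in floating point, and the
apparent shift `delta = M − mp_ratio` is exactly 0 on an error-free,
mutation-free cohort. Stratified Pearson correlations of (M, P) are
reported for all / mutated / unmutated loci; strata with fewer than 3
pairs or zero variance are reported as undefined, never as 0.

## Clock protocol (`clockkit`)

The protocol is two-layered, designed for a small paired cohort
(n = 38) where a held-out validation set is unaffordable:

1. **Outer resampling**: 75/25 train/test splits of the samples,
   redrawn each of `n_iterations` = 100 iterations. All conditions in
   an iteration share the identical split.
2. **Feature pre-selection**: mutual information of each locus with
   chronological age, estimated on the *training samples only* by the
   Kraskov k-nearest-neighbour estimator (k = 3, Chebyshev joint
   metric, variance-scaled marginals, one-ulp radius shrink, negative
   clip). Loci with MI ≥ 0.20 nats survive. The estimator is written
   as a single vectorized pass over loci — thousands of loci per call
   in milliseconds — and is checked against scikit-learn's
   per-feature implementation, with which it agrees to ~1e-15 on
   tie-free data.
3. **Regression**: elastic net with mixing parameter chosen from
   {0.1, 0.5, 0.7, 0.9, 0.95, 0.99, 1.0} and a 60-point auto-scaled
   strength path, by 2-fold cross-validation inside the training split
   (`ElasticNetCV`, max 10,000 iterations; non-convergence is recorded
   on the replicate, not raised). An empty selection degrades to the
   training-mean predictor.

Conditions per iteration: `converted`, `unconverted`, `both`
(column-wise concatenation with channel-tagged locus labels),
`allele_call` and `array_signal` when a genotyping cohort is supplied,
`dummy` (training-mean age predictor, the score floor), and `permuted`
(age labels shuffled across samples, then the *entire* pipeline —
including MI selection — rerun; this is the selection-inclusive
permutation null). Metrics are the coefficient of determination and
MAE on the test samples; conditions are compared by one-way ANOVA and
Tukey HSD (α = 0.05, two-tailed) with single-replicate conditions
excluded. Age acceleration is predicted minus chronological age per
test sample; its cross-channel Pearson correlation is computed per
iteration over the shared test set.

Missing array entries are KNN-imputed (k = 5 neighbour *samples*,
Euclidean distance on shared observed loci, uniform-weight mean);
loci missing everywhere are dropped. Imputation runs once per channel
before resampling, mirroring standard array preprocessing.

## Array, genotype and null cohorts (`synthio`)

The array generator emulates a lifespan cohort: 38 samples with ages
uniform on 4–24 months; 1.5% of 2,000 loci age-informative per channel
(0.5% shared between channels), each following
baseline + s·slope·(age − midpoint + u_sample) + noise with a random
per-locus sign s, slope 1 %/month, Gaussian noise 2% (converted) and
2× that (unconverted — the mock-converted channel is visibly noisier
in real paired data). The per-sample offset u ~ N(0, 1 month), shared
by all informative loci in both channels, models coherent
"apparent-age" variation and is what makes cross-channel age
acceleration positively correlated. Values clip to [0, 100]; 2% of
entries go missing.

The genotyping cohort draws Binomial(2, p) allele calls; at 0.4% of
loci the allele frequency drifts with age at 0.045/month (clipped to
[0.02, 0.98]), a cross-sectional stand-in for age-associated allele
shifts. The slope is derived from the MI threshold, not tuned: for a
trinary dosage to carry MI ≈ 0.2 nats with age at n ≈ 28 training
samples it needs a dosage–age correlation near 0.6–0.7, i.e. a dosage
drift comparable to the binomial noise (sd ≈ 0.7) over the age range.
This yields clocks that clearly beat the dummy while remaining well
below either methylation channel. The signal channel is an affine
dosage readout (10 + 40·dosage + N(0, 4)) so it shares the informative
loci and carries no extra information.

Setting `age_effect_slope = 0` (and `genotype_age_slope = 0`) produces
the null cohort used for calibration checks. One property of this
regime is worth stating plainly: the Kraskov MI estimate of a
pure-noise locus against age at n = 28 exceeds 0.20 nats in roughly 4%
of draws, so across 2,000 loci the filter passes ~50–90 spurious loci
in *every* null split, and models fitted on them score systematically
*below* the dummy. A null cohort therefore does not make all
conditions statistically identical — the fitted conditions share the
null distribution with `permuted` but not with `dummy`. The
leakage probe is accordingly metamorphic (selection must be invariant
to test-split values), not a "never selects noise" claim.

## What the generators do not model

No read sequences, alignment, base qualities, indel realization,
duplicate reads or strand-specific coverage; no probe-chemistry
effects (type I/II design, dye bias, Noob-style normalization); no
genetic relatedness or population structure in the genotype cohort;
array noise is homoscedastic Gaussian rather than
intensity-dependent. Passing tests therefore demonstrate the internal
consistency and statistical behaviour of the pipeline under the stated
generative assumptions — not performance on any particular real
dataset.

## Numerical and design choices

* Two-sided hypergeometric p defaults to the minimum-likelihood
  (Fisher-style) definition — the sum of all outcome probabilities no
  larger than the observed one — which matches exhaustive enumeration
  and `fisher_exact`; a doubled-smaller-tail variant is available and
  is used for the set-overlap representation factor.
* Odds-ratio CIs: Woolf log-odds ± 1.96·SE with Haldane–Anscombe 0.5
  on every cell (flagged) when any cell is zero.
* Array probes are 1-bp intervals before window expansion; feature
  intervals are merged before counting; window expansion is symmetric
  and k is nondecreasing in the window.
* ANOVA degenerate inputs: all-identical data reports F = 0, p = 1
  with no rejections rather than NaN.
* Train fraction is 0.75 (28–29 of 38 samples): 2-fold internal CV is
  infeasible on a 25% training split of 38 samples, so the larger
  share must train.
* All generators are pure functions of (config, seed); every stage of
  an experiment writes into its manifest the config, seeds, row counts
  and output digests needed for exact re-runs.

## Problem sizes used by the validation suite

The self-validation experiments run at the study's native sizes: 2,000
loci; the 6-sample sequencing panel at 30× (20 seeds for the
stratified-correlation contrast); the 38-sample array cohort with 100
clock iterations; 50 null-cohort seeds at 10 iterations each; 1,000
Monte-Carlo resamples for the overlap null; 100 split iterations for
the leakage probe.

## Known limitations

* The M/P sentinel for P = 0 is a reporting convention; the underlying
  ratio is undefined and downstream statistics on corrected values
  should exclude or separately model degenerate rows (flags are
  provided).
* Mutation adjacency is direct positional overlap; no proximity window
  is applied when partitioning loci (the enrichment module provides
  windows where proximity matters).
* The KSG MI threshold of 0.20 nats is a hard cutoff with a fat null
  tail at small n; it is a pre-filter, not an inference procedure, and
  selected-locus lists always contain a chance component (quantified
  by the null-cohort validation numbers).
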