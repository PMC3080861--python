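# Methods

This note documents the statistical models implemented in `admixkit`, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not demonstrate.

## f-statistics

All three estimators are means (or ratios of sums) of per-SNP products of
allele-frequency differences, with uncertainty from a weighted
delete-one-block jackknife.

**4 Population Test.** For a proposed unrooted tree ((A,B),(C,D)) the
statistic is the mean over retained SNPs of (p_A − p_B)(p_C − p_D). Under
the tree the two differences accumulate on disjoint branches and the mean
is zero; gene flow correlates them. The Z-score uses the jackknife SE over
5 cM contiguous blocks (blocks never span chromosomes; block weights are
SNP counts), and |Z| > 3 is the significance convention. We report the
mean product (the f4 form) as the primary statistic and additionally a
normalized correlation Σxy/√(Σx²·Σy²) for reporting; the sign and Z
behaviour, which carry the inference, are identical. SNPs with any
undefined frequency among the four populations, or monomorphic across all
of them, are dropped.

**3 Population Test.** The statistic is the mean of
(p̂_X − p̂_A)(p̂_X − p̂_B) − p̂_X(1 − p̂_X)/(n_X − 1), where n_X is the
number of observed alleles in X at the SNP. The subtraction matters: both
factors contain the same sampling noise of p̂_X, whose variance
p_X(1 − p_X)/n inflates the raw product and would make small-sample
unadmixed targets look less tree-like. With the correction (on by
default, switchable), a simple descendant gives a positive statistic and
Z < −3 proves mixture. SNPs with n_X < 4 are dropped when the correction
is active. Note a positive f3 does not rule out mixture — post-admixture
drift can mask the signal.

**f4-ratio ancestry.** With outgroups O1, O2 and references R1, R2, the
proportion of R1-side ancestry in X is
Σ(p_O1 − p_O2)(p_X − p_R2) / Σ(p_O1 − p_O2)(p_R1 − p_R2), both sums over
the same retained SNPs. The jackknife is applied to the ratio itself
(leave one block out of numerator and denominator simultaneously), which
is the correct treatment for a ratio estimator. Estimates may fall
slightly outside [0, 1] from sampling noise and are reported as computed.
If the denominator is within three jackknife SEs of zero the
configuration is rejected as uninformative.

**Weighted jackknife.** For unequal block sizes we use the weighted
delete-one jackknife (Busing, Meijer & van der Leeden 1999): with block
weights m_j summing to n, h_j = n/m_j, full-data estimate θ̂ and
leave-one-out estimates θ̂_{−j},

    θ̂_J = g·θ̂ − Σ_j (1 − m_j/n)·θ̂_{−j}
    σ̂²  = (1/g) Σ_j (h_j·θ̂ − (h_j − 1)·θ̂_{−j} − θ̂_J)² / (h_j − 1).

With equal weights this reduces to the classical
se² = ((g−1)/g)·Σ(θ̂_{−j} − mean)².

## Admixture-LD dating

**Weights.** w(s) = (a − b)/√(p(1 − p)) with p = (a + b)/2, from the
empirical reference-panel frequencies a, b. SNPs with p ∈ {0, 1} are
undefined and excluded. When no surrogate ancestral panels exist, the
un-normalised difference a − b is available
(`normalized_weights=False`); on simulated data the two modes give dates
within sampling error of each other.

**Pair LD score.** For each within-chromosome SNP pair: Pearson
correlation r of the diploid genotypes over the N samples non-missing at
both markers; pairs with N < 4 or a constant genotype vector are skipped;
r is clipped to [−0.9, 0.9]; z = atanh(r)·√(N − 3), the
variance-stabilised Fisher score, approximately standard normal for
unlinked markers.

**Binning and the decay curve.** Pairs with 0 < d ≤ 30 cM are
accumulated into half-open bins of 0.1 cM by streaming per-bin sums
(count, Σz, Σww, Σz², Σww², Σz·ww), one accumulator per chromosome, so
memory is O(bins) and leave-one-chromosome-out curves are formed by
subtraction without re-scanning genotypes. The per-bin statistic is the
unweighted Pearson correlation between z and w·w across the pairs in the
bin (bins with fewer than two pairs are unusable). Bin abscissa is the
bin midpoint. Bin widths below ~0.05 cM are not recommended: very short
inter-SNP intervals are dominated by background LD.

**Fitting.** corr(d) is fitted by unweighted nonlinear least squares as

    corr(d) = A·exp(−n·d) + c ,   d in Morgans,

over usable bins in [0.5, 30] cM (the lower bound excludes the range
where background LD confounds admixture LD; the upper bound is
configurable). Initial values come from a log-linear regression on the
positive bins. A fit with non-positive rate or amplitude, or fewer than
five usable bins, raises "no detectable admixture LD decay".

The additive constant c deserves explanation, because the admixture-LD
decay itself is a pure exponential. When the genome-wide ancestry
proportion varies across individuals — sampled cohorts always vary, and
cohorts with genuinely heterogeneous ancestry vary a lot — the pairwise
genotype covariance contains a distance-independent term: for diploids
with per-individual proportion θ_i,

    Cov(g_s1, g_s2) ∝ 2·E[θ(1−θ)]·e^{−nd} + 4·Var(θ).

Fitting a bare exponential to e^{−nd} + offset biases the rate downward
(numerically: a 6-generation pulse with Var(θ) = 0.01 fits at ~4.3–5.2
without the constant, and exactly 6 with it). The constant term is
therefore on by default; `with_offset=False` gives the bare exponential.
Optional pair-count weighting of bins (`weight_fit_by_pairs`) is off by
default. A sum-of-two-exponentials fit exists for diagnostics but is
flagged experimental — separating exponential components in noisy data is
notoriously ill-conditioned.

**Standard errors.** Whole chromosomes are the jackknife blocks: admixture
LD can extend far enough that sub-chromosome blocks would not remove the
correlation between retained and deleted data. Each leave-one-chromosome
fit is weighted by the SNPs on the dropped chromosome; chromosomes whose
leave-one-out fit fails are excluded with a warning, and chromosomes that
contributed no usable pairs get zero weight. With 22 chromosomes the SE
rests on 22 outcomes only and should be read with that caution.

**Bias correction.** `estimate_bias` reruns the whole pipeline on cohorts
simulated at the empirically estimated parameters (date, proportion,
sample size), reports bias = mean(replicate dates) − true date, and the
corrected estimate date − bias. Upward bias grows with older dates,
smaller proportions and smaller samples, i.e. with weaker signal.

## The synthetic-data generator

**Ancestral pools.** Per-SNP ancestral frequencies are uniform on
[0.1, 0.9]; each population's frequency is a Balding–Nichols Beta deviate
around the ancestral value with drift parameter F, so the Hudson F_ST
between the two emitted population-frequency vectors equals F in
expectation. The default F_ST is 0.15, the differentiation typical of the
continental population pairs this method is used on. Haplotypes are drawn
through a Gaussian-copula AR(1) along each chromosome: the latent process
decorrelates as exp(−d/ld_scale) (default ld_scale 0.05 cM), giving
background LD confined well below the 0.5 cM fitting floor. Real
haplotype panels have block-structured LD, allele-frequency spectra
skewed toward rare variants, and array ascertainment; the generator does
not emulate those, so passing tests demonstrate correctness of the
estimators under the model's assumptions, not robustness to every
property of real arrays.

**Genome geometry.** Default 22 chromosomes × 1 Morgan with 22,000
uniformly spaced SNPs and 200 haplotypes per pool — the autosome count
(and roughly the pool size) of the phased reference panels this
simulator emulates, at about one-quarter genetic length and ~6% of the
SNP density of a real array dataset. The chromosome count matters for
the jackknife (22 leave-one-out outcomes); the reduced length and
density mainly cost precision, which the validation absorbs by taking
medians over 20 replicate seeds. All sizes are keyword-configurable.

**Mosaic admixture.** Each admixed haploid chromosome starts in ancestry
Bernoulli(θ) and walks the markers left to right, resampling with
probability 1 − e^{−λg} per inter-marker gap g; a resampling event draws
a fresh Bernoulli(θ) ancestry *and* a fresh donor haplotype even when the
ancestry comes out the same — the marker process resamples lineage, not
merely ancestry label. (Whether a same-ancestry resample should keep the
donor is genuinely open; switching donors matches the marker-process
description and only affects within-ancestry haplotype continuity, not
the ancestry tract process that dating relies on.) Donor segments are
sampled without replacement: an interval ledger guarantees no donor
chromosomal segment is copied twice. For cohorts needing more than the
pool provides, `large_n` mode builds each admixed haploid from one
dedicated donor per ancestry. True tracts are recorded with boundaries
placed uniformly within the inter-marker interval where the switch
occurred, so recorded tract lengths are free of marker-lattice artifacts;
interior A-tract lengths are exponential with mean 1/(λ(1−θ)) Morgans.

**Multi-pulse histories.** A double pulse (older event λ1, then λ2 < λ1)
is composed as an outer walk at rate λ2 choosing first-mixture versus
fresh-B lineages, and an inner walk at rate λ1 − λ2, cut additionally at
outer events, choosing ancestry within first-mixture lineages — so the
old mosaic decorrelates at the full rate λ1 and the marginal ancestry is
exactly θ1·θ2. Continuous gene flow over [a, b] generations solves the
per-generation migrant fraction m from (1 − m)^(b−a+1) = 1 − θ_total and
layers one walk per generation (rate = generations of residence), the
most recent entry winning; layer walks are independent, which reproduces
the marginal entry-time distribution and each cohort's tract-breakdown
rate, while between-layer boundary correlations are approximated.

**A caution on single-exponential dates under multiple pulses.** The
ancestry covariance of a two-pulse history is a two-exponential mixture;
for the 50/50-then-50/50 history (30 then 10 generations) it is exactly
0.125·e^{−30d} + 0.0625·e^{−10d} — the *older* component carries twice
the amplitude. A least-squares single-exponential fit of that curve lands
at ~17–20 generations (depending on the affine term), between the events
but pulled toward the older one, and our simulations reproduce that
expectation. Single-exponential dates for populations with multi-pulse or
continuous histories should be read as signal-weighted averages of the
event times, not as the date of the most recent event; for continuous
flow over [a, b] the fitted date falls inside the interval. The
two-exponential diagnostic fit does recover both components on clean
simulated curves.

## Post-estimation summaries

Regional mean dates combine member populations by inverse-variance
weights 1/SE² — the minimum-variance combination of independent
estimates. When averaging bias-corrected dates, members without a
simulation-calibrated bias contribute their uncorrected date (the
correction does not change the SE). Reported averages are rounded to the
nearest integer generation. Years before present use 29 years per
generation. The module bundles a published compilation of admixture-LD
dates for Southern European, Levantine and Jewish populations as a worked
input; the bundled numbers are inputs to the averaging arithmetic, not
outputs of this package.

## Validation problem sizes

The acceptance script and the heavy tests use the default genome (22 × 1
Morgan, 22k SNPs), 10-diploid cohorts, independent 100-haplotype
reference panels for the weights, and medians over 20 replicate seeds;
calibration properties use 200 simulated trees (4-population null), 100
replicates (jackknife-versus-scatter agreement), and 15 replicates per
time depth for the 10/50/100-generation recovery grid. These sizes were
chosen so the whole validation runs in minutes on one core while leaving
the per-replicate estimator noise small relative to the tolerances being
checked.
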