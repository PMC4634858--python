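# Methods

This note documents the models, algorithms, defaults and design choices
behind `tmtflow`, and what the synthetic benchmarks do and do not show
about real data.

## Pipeline model

The pipeline assumes a multiplexed isobaric-label experiment: each
peptide row carries one reporter-ion intensity per channel, channels map
one-to-one to samples, and samples belong to one of two histology groups
(canonically 3 ADC vs 3 SCC on TMT 126–131). Intensities are linear and
strictly positive where observed; an intensity of 0 in the input dialect
means "no reporter signal" and is treated as missing, never as a
measured zero.

### QC filtering

Rows are removed when: PEP strictly exceeds 0.1; the sequence is a
reversed decoy; the row is flagged contaminant; or the number of missing
reporter intensities strictly exceeds the larger of the two group sizes
(for 3 vs 3: rows missing in 4+ of 6 channels go, 3 of 6 stay). A row
failing several rules is counted once under the first rule in the fixed
order PEP → reverse → contaminant → missingness, which makes the filter
report deterministic and conservative of the row total. Contaminant
status is taken from the table's flag column; no sequence-level species
inference is attempted.

### Normalization

The reference sample is the one whose mean (over observed values) is
closest to the median of all sample means, ties going to the earlier
sample in design order. Every other sample is scaled onto the reference
by a single global log2 offset — a rank-invariant surrogate for
reference-based rank-order normalization of intensity data. Over the
features observed in both sample and reference, the algorithm trims 5%
of features at each intensity extreme, keeps features whose relative
rank disagreement is ≤ 5%, takes the one-step biweight of the kept
value differences as the offset, subtracts it, and repeats until the
kept set stabilizes (a pure shift leaves ranks unchanged, so the loop
converges on the second pass; `max_iter=20` is a guard). A nonlinear
intensity-dependent response curve is deliberately out of scope: only a
global multiplicative scale per sample is estimated, which is exact for
loading/labeling offsets and is what the offset-recovery benchmark
measures. Samples sharing fewer than 20 features with the reference fall
back to a median-difference offset with a warning.

### Protein rollup

Peptides map to **all** proteins in their accession list; no razor
assignment, no fractional apportionment — a shared peptide contributes
its full value to every parent. Per protein and sample, the intensity is
the one-step Tukey biweight of the peptides' log2 values:
`u_i = (x_i − M)/(c·S + ε)` with `M` the median, `S` the **unscaled**
MAD (no 1.4826 consistency factor — this follows the robust-
summarization convention of the expression-array ecosystem and does
change the weights), `c = 5`, `ε = 1e-4`; weights `(1 − u_i²)²` inside
`|u| < 1`, zero outside; the median is returned if all weights vanish.
The estimate is one-step (not re-iterated) by default; an iterated
variant exists behind a flag. For n = 2 the formula is applied as stated
(median = mean, MAD = half-range; no special-casing). The biweight is
computed per sample over peptides — the only reading consistent with a
protein × sample output matrix.

A known property of per-sample robust rollup: when peptides differ
substantially in ionization efficiency, the per-sample MAD differs
between samples, so an extreme-efficiency peptide can be zero-weighted
in one sample but not another. Efficiency then no longer cancels exactly
in fold-changes, adding variance beyond the channel-noise scale. This is
inherent to any per-sample outlier-rejection scheme and is why the
controlled recovery benchmark (below) sets the efficiency spread to
zero.

`razor_rollup` implements the comparator convention (assign each peptide
to the parent with the most peptides, sum linear intensities): it is for
benchmarking only and inherits the missing-value sensitivity that
motivates the biweight.

### Differential testing and calls

Welch's unequal-variance two-sided t-test with Satterthwaite df per
protein; fold-change is the difference of group means on the log2 scale
(log2(SCC/ADC)); calls require *P* < 0.05 and linear FC strictly > 1.5
or < 1/1.5; no multiple-testing adjustment. All published thresholds are
strict inequalities as printed. Zero-variance degenerate cases are
flagged rather than raised so pipeline runs never abort on constant
features. Note that the Welch test is conservative at n = 3 vs 3: its
true size at nominal 0.05 is ≈ 0.035 (we verified this against scipy
and R on 10⁵ null replicates), which matters when interpreting null
rejection rates.

### Correlation, rank-sum, clustering, probe filter

Pearson and Spearman correlations use pairwise-complete deletion,
average ranks for ties, and the two-sided t-approximation
`t = r·sqrt((n−2)/(1−r²))` (for Spearman the same transform after
ranking; the approximate rather than exact null is used and labeled).
The Mann-Whitney rank-sum test uses the normal approximation with tie
correction and a 0.5 continuity correction; its worst-case deviation
from the exhaustive-permutation p, enumerated over every attainable U,
is 0.0375 / 0.0305 / 0.0172 for 3v3 / 4v4 / 5v5 — an inherent property
of the approximation, frozen into the unit tests. Sample clustering uses
d = 1 − Pearson R between sample columns (features with any missing
value dropped), complete linkage, deterministic index-order
tie-breaking, and a two-cluster cut for comparison with the design; the
probe filter keeps features with sample SD (n−1 denominator) strictly
above 1 log2 unit.

### Gene–protein integration

Proteins are restricted to those measured on both platforms. A protein
with several mapped probes uses the probe with the highest mean over
non-missing values (ties: lexicographically smallest probe id); probe
averaging exists as an off-by-default option. Concordance is reported
globally (all gene/protein points pooled) and per pair (one correlation
across samples per protein; the mean includes all positive and negative
values; constant profiles are undefined, excluded, and counted), with
counts of pairs at p < 0.05 and r > 0.5. Cross-study comparison matches
peptides by stripped uppercase sequence (modification annotations
removed, I ≠ L) and reports inventory sizes, missingness, peptide
lengths (rank-sum test), mean-intensity correlations over shared
peptides, and differential-call overlap with direction agreement.

## Synthetic-data generator

The generator realizes a known truth so every stage has a recovery
target.

**Truth.** Protein baseline log2 abundance ~ Normal(11.4, 1.43), the
location and spread of log2 reporter intensities typical of 6-plex TMT
tissue data. A fraction `frac_de` of proteins (exact count, rounded)
carries a signed effect of magnitude `de_log2fc` (default 2.0) applied
to the second group. True abundance of protein p in sample s is
`baseline_p + δ_p·1[s ∈ group2] + loading_s`; per-sample loading offsets
default to zero. An optional `biological_sd` knob (default 0) adds
per-protein-per-sample variation; it is off by default so the enumerated
noise sources of the recovery benchmarks are exhaustive, at the cost
that non-differential proteins have constant true profiles (see
limitations).

**Peptides.** Counts per protein are 1 + NegBin(mean 6, shape 0.28);
with 10% of peptides given a second random parent, the *realized*
single-peptide-protein fraction lands at ~21% and the mean at ~7
peptides/protein, matching TMT tissue inventories. A shared peptide's
linear signal is the **sum** of its parents' linear abundances (reporter
signal is additive across co-isolated origins), scaled by a per-peptide
efficiency (log2 sd 0.5), with Normal channel noise (sd 0.25) per cell
on the log2 scale. Cells drop out missing-not-at-random with probability
`logistic(α − β·log2 intensity)`; presets `tmt_like` (~0.1% missing, the
reporter-ion regime) and `labelfree_like` (~18%, the label-free regime)
set α at β = 0.5 for the nominal rate at the typical intensity 11.4 —
with β > 0 the realized rate shifts slightly with the intensity spread
(≈ 0.13% for the nominal 0.1%). MCAR is available via β = 0. Decoy rows
(1%) carry PEP = 0.1 + 0.9·Beta(2,2) (all above the filter threshold);
true and contaminant rows draw PEP from Beta(0.5, 87), mean ≈ 0.0057.
Sequences are synthetic unique tokens (`PEP000001`…); lengths are drawn
Normal(12.26, 3.0) clipped to [7, 40] — tryptic realism is out of scope.

**Microarray.** One gene per protein; probes per gene 1 + NegBin(mean 1,
shape 5). The gene latent profile is `ρ·z_p + sqrt(1−ρ²)·z_g`, with
`z_p` the standardized true protein profile (`z_p = 0` when the profile
is constant — such transcripts carry no protein-tracking signal) and
`z_g` iid standard normal; each probe reads `affinity + scale·latent +
Normal(0, array_noise_sd)` with affinity ~ Normal(8, 1.5), scale 1,
array noise 0.25. `gene_protein_corr` (default 0.3, the regime reported
for tumor proteogenomics) therefore sets the latent transcript–protein
correlation *for proteins whose expression varies*; the measured
per-pair correlation is attenuated by array and measurement noise.

**What the generator does not emulate.** Tissue heterogeneity
(biological variance is a single optional knob); isotopic impurity and
ratio compression; retention-time or spectral effects; realistic
digestion. With `biological_sd = 0`, 90% of default-generated proteins
have constant true profiles, so the dataset-wide mean per-pair
gene–protein correlation of *measured* data is far below the latent ρ —
recovery of ρ is therefore benchmarked on all-varying configurations.
Passing benchmarks demonstrate correctness of the estimators and
plumbing under the stated noise models, not performance on real tissue.

## Benchmark conditions (scripts/acceptance.py, tests/test_acceptance.py)

Oracle-agreement checks (biweight vs directly coded formula; Welch vs
closed form and scipy; rank-sum vs exhaustive permutation) use random
instances at the sizes stated in their docstrings. The statistical
recovery experiments use a **controlled configuration**: 300 proteins,
10% DE at |log2FC| = 2, channel noise 0.25, reporter-style missingness,
fixed 7 peptides per protein, no shared peptides, zero efficiency
spread — so channel noise and missingness are the only stochastic
inputs and the expected FC-recovery error has a known scale
(sd ≈ 0.25/sqrt(7)·sqrt(2/3) ≈ 0.08 per protein). Shared-peptide
ambiguity and heavy-tailed peptide counts are exercised separately by
the rollup unit tests (razor contrast, robustness and missingness
contrasts) and by the marginal checks on the default generator. The
concordance benchmark runs 500 all-varying genes over 20 samples at
ρ = 0.6 against an independently coded Monte-Carlo of the same
generative chain, plus an exact noise-free ρ = 1 limit; clustering
recovery runs 100 seeded replicates of the controlled configuration.
Problem sizes throughout were chosen so the full suite completes in a
few minutes on one CPU while keeping binomial/Monte-Carlo intervals
tight enough to be meaningful.

## Numerical choices and degenerate inputs

- Reporter intensity 0 → missing on read; writes serialize missing as 0,
  so write/read round trips preserve values and missingness exactly.
- One TSV dialect: tabs, UTF-8, "." decimal, blank = missing.
- Ties: reference selection → earlier sample; probe choice →
  lexicographically smaller id; clustering merges → index order;
  razor assignment → most peptides, then lexicographic.
- Correlation of a constant vector, tests with < 2 values per group, and
  pairs with < 3 complete observations are undefined-marked (NaN), never
  raised, and excluded from means with recorded counts.
- Zero variance in both Welch groups: t = 0, p = 1 on equal means;
  p → 0 flagged degenerate otherwise.
- All randomness flows from integer seeds through
  `numpy.random.default_rng([seed, stream])`; identical seeds and inputs
  give byte-identical output files (no timestamps in any output).

## Known limitations

- The normalization is offsets-only; data with genuinely nonlinear
  intensity response between samples will retain that distortion.
- Accession-level protein identifiers only; no isoform collapsing or
  protein-group FDR.
- The Spearman p-value uses the t-approximation even at n = 6, where the
  exact null differs; counts of "significant" per-pair correlations at
  small n inherit that approximation.
- Per-sample biweight rollup couples outlier rejection to per-sample
  MADs (see above); fold-changes of proteins with extreme-efficiency
  peptides carry extra variance.
- Cross-study peptide matching is by stripped sequence with I ≠ L;
  studies differing in modification reporting conventions may
  under-overlap.
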