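# Methods

## Model

`poolmaf` estimates, per genomic site, the posterior distribution of the
population frequency *f* of the non-reference allele from pooled
sequencing reads. The observation model has two layers:

1. **Pooling.** A pool of *N* homologous chromosomes (2× individuals for
   diploid autosomes) contains an unknown number *k* of copies of the
   alternative allele; given *f*, *k* ~ Binomial(*N*, *f*). *N* is a user
   input; a rough value suffices, and no attempt is made to infer it.
2. **Sequencing.** Given *k*, the number of alternative reads among the
   *C* used reads is Binomial(*C*, *p̃_k*), where *p̃_k* corrects the true
   alternative fraction *k/N* for sequencing errors (below).

The likelihood is the sum over *k* of the product of the two binomials,
and the posterior multiplies it by a prior over *f* discretized on the
grid 0, 1/N_d, …, 1 (N_d = 100, i.e. a 1% step; configurable via
`FrequencyGrid`). The decision statistic is the posterior mass on
0 < *f* < 1 ("probability of segregating"); both fixed classes *f* = 0 and
*f* = 1 are excluded, since a population fixed for the alternative allele
is not a segregating site. A site is called when this mass *strictly*
exceeds the threshold (default 0.9).

Assumptions worth stating: sites are treated independently; the model is
strictly two-class (every non-reference base counts toward *n_A*; the
reported `alt` label — most frequent non-reference base, ties broken
alphabetically — is metadata only); reads sample chromosomes
exchangeably, so unequal individual contributions are not modelled inside
the likelihood (they shift read frequencies toward intermediate values
and inflate the variance of frequency estimates, but leave the mean
unchanged); indels and deletion placeholders are excluded from the used
depth rather than modelled.

## Error model

Each read base carries a Phred quality: error probability
ε = 10^(−(c−33)/10) for ASCII code *c* (offset configurable). Per site,
the reference-class and alternative-class error rates ε_R, ε_A are the
geometric means of the per-read error probabilities in each class. With
symmetric base priors P(A) = P(R) = ½ (a fixed modelling choice, not a
knob), Bayes inversion gives the misread probabilities

    ρ = ε_R(1 − 2ε_A)/(1 − ε_A − ε_R),   α = ε_A(1 − 2ε_R)/(1 − ε_A − ε_R)

(ρ: an alternative-carrying read is observed as reference; α: a reference
read is observed as alternative), and the corrected read probability is
p̃ = (1 − ρ)p + α(1 − p) with p = k/N.

Numerical guards:

* **Clamp.** Class rates are clamped to [1e−6, 0.25]. The ceiling keeps
  1 − ε_A − ε_R > 0.5, so ρ, α ∈ [0, 1]; the floor keeps p̃ strictly
  inside (0, 1), so log-space likelihoods never hit log 0.
* **Empty classes.** A class with no reads (most commonly the alternative
  class at n_A = 0) has no qualities of its own; it borrows the geometric
  mean over all reads at the site, and a completely empty site falls back
  to 1e−3 (a typical short-read base error). This case is not pinned down
  by the model definition; the choice is documented here and tested.

## Priors

Four variants, all exactly normalized on the grid (β is the harmonic
number H_{N_d−1} = Σ_{i=1}^{N_d−1} 1/i, the unique constant that makes the
informative columns sum to one under this discretization):

| variant | P(f=0) | P(f=1) | P(f), 0<f<1 |
|---|---|---|---|
| flat, unfolded | 1−θ−D | D | θ/(N_d−1) |
| flat, folded | (1−θ)/2 | (1−θ)/2 | θ/(N_d−1) |
| informative, unfolded | 1−θβ−D | D | θ/(N_d·f) |
| informative, folded | (1−θβ)/2 | (1−θβ)/2 | θ/(2·N_d·f(1−f)) |

θ is the prior nucleotide diversity (default 0.001, per-site), D the prior
divergence — the probability that the site is fixed for the non-reference
allele relative to the reference (default 0.1; the benchmark harness uses
0.01 explicitly, and folded priors ignore D). The informative interior is
the neutral spectrum θ/f (folded: θ/f + θ/(1−f), giving the 1/(f(1−f))
shape). The continuous 1/f prior is improper; the grid discretization is
what makes it (and the posterior) well defined. Prior masses are used as
written — no renormalization — and configurations whose fixed-class mass
would go negative (large θβ + D) are rejected with an error.

Folded priors are invariant under f → 1−f, and with equal class error
rates the posterior for mirrored counts (n_A ↔ C−n_A) is exactly the
reversed vector; both properties are tested at 1e−10.

## Numerics

Likelihood terms are computed in log space (gammaln-based binomial
coefficients) and combined by log-sum-exp over k (scalar path) or by
shifting each site by its max-over-k before exponentiating and taking a
single (sites × k) @ (k × grid) matrix product (batch path). The two
paths agree to ~1e−12 and are both exercised against a literal double-sum
enumeration for all N ≤ 4, C ≤ 6 at 1e−10 relative tolerance. Depths up
to at least C = 1000 are safe. MAP ties break toward the smaller
frequency (conservative toward non-segregation; with a symmetric folded
posterior the reported MAP is therefore the lower mode).

## Simulator

`poolmaf.simulate` generates the benchmark's study conditions directly
rather than running a coalescent simulator, a read simulator and an
aligner:

* Segregating-site count ~ Poisson(θ·L·H_{N−1}) (Watterson's expectation);
  per-site alternative count k with P(k) ∝ 1/k, k = 1..N−1 (the neutral
  sample spectrum); positions uniform without replacement; reference and
  alternative bases uniform.
* Per-site depth ~ Poisson(mean 20 by default); each read picks a
  chromosome independently — uniformly, or with the skewed scheme in
  which half of the diploid individuals are weighted 1.5 and half 0.5
  (an odd individual count leaves the middle individual at 1.0). Both
  chromosomes of an individual share its weight.
* Phred scores are drawn from a discrete profile
  Q ∈ {20, 25, 30, 35, 40} with weights {0.05, 0.10, 0.25, 0.30, 0.30}
  (mean per-base error ≈ 1.2e−3), standing in for short-read Illumina
  base qualities; with probability 10^(−Q/10) the emitted base is
  replaced by a uniform choice among the other three. Strands are
  uniform. Output is deterministic given the seed (byte-identical
  pileups).

What this deliberately does **not** emulate: linkage and recombination
(the benchmark summaries depend only on marginal site frequencies and
depths), read length and paired-end geometry, alignment and
mapping-quality filtering, PCR duplicates, strand bias, GC bias, indels,
and ART-style position-dependent error profiles. Passing benchmarks
therefore show that the caller has the intended operating characteristics
on data that match its observation model; they overstate absolute power
on real data, where alignment losses and dirtier error profiles reduce
usable depth and inflate the error floor — precisely the regime where
published full-pipeline numbers sit several points lower (see the depth
and MAF breakdowns in `poolmaf evaluate` for where the difference
concentrates: low-MAF sites). The benchmark harness (`run_replicate`,
`scripts/acceptance.py`) consumes the simulator's in-memory counts table;
the pileup write → parse round trip is asserted equivalent in the test
suite.

## Evaluation

Power = recovered fraction of true segregating sites whose realized used
depth lies in the calling window (default 5–40X); FDR = fraction of calls
not at a true segregating position. Both numerator and denominator are
restricted to the depth window, matching the fact that calling itself is.
Eligibility uses the same depth the caller sees (after deletion/N
exclusion). A call at a monomorphic position is a false positive even if
sequencing errors made it look variant. Binned curves use 1-read depth
bins and 0.05-wide true-MAF bins over (0, 0.5].

Two folded spectra are produced: the "true pooled" SFS — each truth site
subsampled to 20 chromosomes with replacement (alt probability k/N),
monomorphic subsamples dropped — and the "estimated" SFS from raw read
frequencies n_A/C at called sites with exactly C = 20, folded to
min(n_A, C−n_A). The exact-depth restriction keeps frequency classes
comparable across sites.

## Problem sizes and checks

The packaged benchmark runs 200 kb regions (≈450 truth sites per
replicate at N = 50): 20 replicates per setting in
`scripts/acceptance.py` (~75 s total on one CPU), 4–6 replicates in the
test suite. Monte-Carlo bands used in the tests are ±10 percentage points
for power-type quantities and ±5 for FDR. The likelihood-calibration
check ("parameter recovery") simulates 1000 sites at N = 50, C = 100,
ε = 10⁻³ and verifies the posterior mean lies within 3 posterior SDs of
the true k/N for ≥99% of sites **under a uniform grid prior** — the
calling priors put roughly half their mass on f = 0 by design and would
shrink extreme frequencies out of any tight band; the uniform prior
isolates the likelihood's calibration, which is what the check is about.

## Known limitations

* Strictly biallelic two-class model; tri-allelic sites fold into n_A.
* No modelling of unequal individual contributions inside the likelihood
  (no method can identify them from pool data without extra assumptions).
* Quality scores are taken at face value; no recalibration, no
  context/position-dependent error model.
* The folded priors discard the divergence parameter entirely.
* Power/FDR measured on the built-in simulator are upper bounds for real
  pipelines (see Simulator above).
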