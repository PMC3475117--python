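# poolmaf

Bayesian minor-allele-frequency estimation and SNP calling for **pooled
sequencing** (pool-seq), with a built-in pool-seq simulator and a
power/FDR/site-frequency-spectrum benchmark harness.

## The problem

Sequencing DNA pooled from many individuals is a cheap way to survey
genetic variation, but calling SNPs in pools is harder than in
individuals. A diploid heterozygote has allele frequency 0.5; in a pool of
*N* chromosomes the frequency can be any multiple of 1/*N*, and under the
standard neutral model rare alleles dominate (*P(f) ∝ 1/f*), so most true
variants are exactly the ones a minimum-reads-per-allele filter would
throw away. At the same time a single sequencing error is indistinguishable,
read-for-read, from a genuine rare allele.

## The model

For each pileup site, reduce the reads to two classes — matching the
reference (*R*) or not (*A*) — and let *C* be the used depth and *n_A* the
number of alternative reads. With *N* chromosomes in the pool and *f* the
population frequency of the alternative allele, the posterior is

```
P(f | n_A) ∝ P(n_A | f) · P(f)

P(n_A | f) = Σ_{k=0}^{N}  Binom(n_A; C, p̃_k) · Binom(k; N, f)
```

marginalizing over the unknown number *k* of alternative chromosomes that
made it into the pool. Sequencing errors enter through
`p̃_k = (1 − ρ)·k/N + α·(1 − k/N)`, where per-site class error rates
`ε_R, ε_A` (geometric means of the Phred-implied per-read error
probabilities) are turned into misread probabilities by Bayes inversion:

```
ρ = ε_R (1 − 2ε_A) / (1 − ε_A − ε_R)      α = ε_A (1 − 2ε_R) / (1 − ε_A − ε_R)
```

*f* is discretized on the grid 0, 0.01, …, 1. Four priors are available —
flat or informative (neutral 1/f spectrum), each folded (reference not
assumed ancestral) or unfolded — parameterized by the prior nucleotide
diversity θ (default 0.001) and the divergence *D* (default 0.1), with the
fixed classes *f* = 0 and *f* = 1 carrying the remaining mass. A site is
called segregating when the posterior mass on 0 < *f* < 1 exceeds a
threshold (default 0.9). The full 101-point posterior is available for
every site.

## Worked example

Simulate 50 kb of a pool of 50 chromosomes (θ = 0.0005, 20X depth), call
with the informative folded prior, and score against the simulated truth:

```sh
poolmaf simulate --length 50000 --n-chrom 50 --theta 0.0005 --depth 20 \
    --seed 7 --out-prefix demo
# poolmaf simulate: 102 segregating sites over 50000 bp (N=50, theta=0.0005),
#                   1002088 reads -> demo.pileup

poolmaf call --pileup demo.pileup --n-chrom 50 --prior informative \
    --spectrum folded --theta 0.001 --divergence 0.01 --out demo.calls.tsv
# poolmaf call: 49999 sites in depth window [5, 40], 46 called (threshold 0.9)

poolmaf evaluate --calls demo.calls.tsv --truth demo.truth.tsv \
    --out demo.metrics.tsv
# poolmaf evaluate: power=0.4412 fdr=0.0217 (eligible=102, called=46)
```

`demo.calls.tsv` holds one row per in-window site; a called row looks like

```
#chrom  pos  ref  alt  C   n_A  eps_R        eps_A        p_f0         p_f1         p_seg  mean_f    map_f  called
sim1    158  C    G    18  9    0.000316228  0.000359381  2.16874e-23  6.85548e-24  1      0.499976  0.5    1
sim1    2096 T    G    23  4    0.000402961  0.000133352  9.17295e-09  9.23853e-58  1      0.174025  0.13   1
```

— position 158 has 9 alternative reads out of 18, a posterior mean
frequency of 0.50 and essentially no mass on the fixed classes; position
2096 is a lower-frequency variant (posterior mean 0.17) still called with
certainty. `demo.metrics.tsv` contains the overall power (here 45 of the
102 true sites recovered, mostly missing singletons) and FDR (1 of 46
calls is a false positive), power by depth and by true minor-allele
frequency, and the true and read-frequency folded spectra. Add
`--full-posterior` to `poolmaf call` to append the 101 posterior masses
per row, and `--uneven` to `poolmaf simulate` to skew individual
contributions (half 1.5x, half 0.5x).

The same pipeline is available as a library (`poolmaf.run_replicate`,
`poolmaf.batch_call`, `poolmaf.score_calls`, …); see `docs/methods.md` for
the modelling details and design choices.

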