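# Methods

This note documents the statistical machinery, its assumptions, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not establish about real registry data.

## Nomenclature consolidation

Registry typing mixes resolutions (SSP/SSO intermediate calls, SBT
four-digit calls). All calls are consolidated to first-field allele groups,
with one deliberate exception: the B14, B15 and B40 families are kept at
the resolution of their serological splits (B64/B65; B62/B63/B70/B71/B72/
B75/B76/B77; B60/B61), because these groups lump antigens that matching
practice distinguishes. The split assignments are WHO reference knowledge,
not something this package derives; they ship as a versioned, user-extensible
table (`data/serology_map.tsv`). A B14/B15/B40 allele missing from the
table raises an error — silent truncation to the broad group would corrupt
every downstream frequency, so the failure is loud by design. Within those
three families a bare group code (`B*40`) and a redundant-looking split
(`B*40(40)`) are *distinct* categories (unresolved broad typing vs. a
split-typed antigen); outside them a redundant split such as the legacy
`B*51(51)` canonicalizes to `B*51`.

The literal category `Unknown` (one untypable allele in the reference
table, 0.002%) is retained as a first-class category, participates in
frequency sums and in the distance computation like any allele. Whether it
should instead be dropped is ambiguous in the source material; at 2·10⁻⁵
its influence is below every tolerance used here.

All frequencies are proportions in [0, 1] internally; percent appears only
in file readers/writers. This removes an entire class of double-scaling
bugs at the cost of one division on input.

## Allele frequencies and Hardy–Weinberg testing

Frequencies are direct counts over the 2N allele copies. The HWE test is
the classical multiallelic χ² on genotype classes: expected counts N·p_i²
(homozygote) and 2N·p_i·p_j (heterozygote), χ² summed over all k(k+1)/2
classes, df = k(k−1)/2. Categories carried by fewer than `min_expected`
allele copies (default 5, the textbook validity rule) are pooled into one
rare class, rarest first, before the genotype classes are formed. With
highly polymorphic loci the χ² approximation degrades when genotype-class
expectations are tiny even after allele-level pooling; for that regime a
Monte-Carlo exact variant is provided that keeps the same statistic but
references it against permutations of the observed 2N allele copies into
random pairs (seeded). The default remains the pooled χ².

Calibration: under the simulator (linkage-equilibrium truth with three
alleles per locus at 0.5/0.3/0.2, N = 500, 1000 replicates) the pooled χ²
rejects at 5.5% for a nominal α = 5%. This calibration is a property of the
moderate-frequency regime; it does not certify the χ² approximation for
loci with dozens of rare alleles, which is exactly why the exact variant
exists.

## EM haplotype frequencies

The model is random mating (Hardy–Weinberg at the haplotype level): an
individual's two haplotypes are independent draws from the population
frequency vector f. The likelihood of an unphased genotype g is
Σ over compatible diplotypes {h₁,h₂} of c·f(h₁)·f(h₂), c = 2 when h₁ ≠ h₂.
The E-step distributes each donor over its 2^(h−1) compatible diplotypes
proportionally to these terms; the M-step sets f(h) to h's expected share
of the 2N chromosomes. The log-likelihood is checked to be non-decreasing
on every run (a violated check raises — it would indicate a defect, not a
data problem).

Implementation choices:

- **Support restriction.** Only haplotypes compatible with at least one
  observed genotype are carried. Any haplotype outside this support has
  MLE frequency 0, so the restriction is exact, and it bounds the state
  space by 4N. Identical genotypes are grouped and weighted.
- **Initialization** defaults to the linkage-equilibrium product of
  single-locus frequencies over the support (the conventional default of
  EM haplotyping tools); `uniform` and `random` starts are available, and
  `restarts > 1` keeps the best final likelihood across one deterministic
  and several random starts. The likelihood surface for these data is in
  practice unimodal at registry sample sizes; restarts are a safeguard.
- **Convergence**: maximum absolute frequency change < `tol` (default
  1e-7), `max_iter` 1000. At desk scale the estimates stabilize to well
  below print precision in well under 100 iterations.
- Output tables are written rounded to 4 decimals (print convention);
  internal values are never rounded.

A fixed-point property links stages: summing fitted haplotype frequencies
over two loci reproduces the direct-counting allele frequencies of the
third locus to 1e-6, which also forces the complete-space LD sum to vanish
(the closure diagnostic in `linkage`).

Recovery behaviour: simulating N = 2000 diploids from the renormalized
top-20 reference haplotypes and refitting recovers the truth with a mean
total-variation distance of ≈ 0.026 over 20 seeds — statistically
indistinguishable (to ~1e-6) from what *phase-known* counting of the same
4000 chromosomes achieves, whose expectation is
0.5·Σ√(2p(1−p)/(π·4000)) ≈ 0.0259. In other words, at these sample sizes
and this level of linkage disequilibrium, discarding phase costs the
estimator essentially nothing; the residual error is sampling noise, and
pushing it below ~0.02 requires more donors, not a better optimizer.

## Linkage disequilibrium

Δ(h) = HF(h) − p(a)·p(b)·p(d): the raw global three-locus disequilibrium,
not a normalized D′. This form is what the reference report tabulates —
its printed LD column equals HF minus the triple product of its own allele
frequencies to print precision for 47 of its 50 rows (the other three rows
are internally inconsistent in the source at a level print rounding cannot
produce, and are treated as typos there, not reproduced here). Δ is bounded
by −min(p(a)p(b)p(d), 1−HF) ≤ Δ ≤ HF, far inside the nominal ±1 range
sometimes quoted for LD coefficients.

## Genetic distance and phylogeny

The distance is Nei's standard D = −ln I in the 1972 form: per-locus gene
identities j_X, j_Y, j_XY are averaged arithmetically across loci *before*
forming I. Among the candidate variants (1972 standard, 1978
sample-size-unbiased, DA 1983, minimum distance), only the 1972 form on
frequencies exactly as printed (percent/100, absent categories 0, no
renormalization) reproduces the reference distances; the unbiased form
overcorrects drastically for the smallest samples. `renormalize=True` is
available to rescale rounded columns to exact unit sums (it changes the
Han–Manchu distance by ~1e-6), and the DA distance sits behind
`variant="da"` for sensitivity analysis. One caveat is inherent to printed
inputs: distances computed from rounded tables can differ from those the
original full-precision frequencies would give by more than print rounding
of the *distance* suggests, and for the smallest sample (Xibe, 2N = 62)
the residual against the reference value is ≈ 0.003.

Neighbor joining follows Saitou–Nei exactly: join the pair minimizing
Q(i,j) = (n−2)d(i,j) − Σd(i,·) − Σd(j,·), branch lengths
b_i = d(i,j)/2 + (r_i−r_j)/(2(n−2)), distances to the join
d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2, and the final three clusters closed
with the exact three-point formulas. Ties in Q are broken on the
lexicographically smallest pair of cluster labels (a cluster is labelled by
its smallest leaf), making output independent of input order. Negative
branch lengths are kept as computed unless `clamp_negative` is set — both
conventions exist in the field; keeping them preserves additivity. NJ is
exact on additive matrices, which the tests exploit as an oracle: path
matrices of random trees with positive branch lengths are recovered to
1e-9 over 200 trials.

## Synthetic registries

`sample_genotypes` draws 2n haplotypes i.i.d. from a truth vector
(inverse-CDF over the canonically sorted haplotype list, so fixed seeds are
bit-stable across platforms) and discards phase. Defaults used throughout
the tests mirror the reference study's conditions: ground truth from the
renormalized top-20 (or top-50) published Han haplotypes; N = 2000 for
EM-recovery experiments (desk-scale stand-in for the 20,465-donor
registry); N = 500 with 1000 replicates for HWE calibration. The optional
`noise_floor` reassigns a small probability mass to a cloud of rare
haplotypes built by cyclically permuting alleles across loci of the truth
set — a stress test for frequency filters that invents no new alleles.

What the simulator deliberately does **not** model: typing ambiguity and
mistyping, partial (missing-locus) records, population substructure and
admixture, and within-individual departure from random mating. Passing
recovery tests therefore certify the estimator under its own model
assumptions — they do not certify robustness to typing error or
stratification in real registry data.

## Degenerate inputs and numerical conventions

Empty datasets, duplicate sample ids, empty genotype cells, negative
frequencies, unsorted band edges and sub-2-category HWE tables are all
hard errors with named exceptions. Frequency-table locus sums are
validated to 1 ± 0.005 (print rounding); unfiltered EM output to 1 ± 1e-9;
haplotype tables read from 4-decimal files get the looser print tolerance.
Packaged reference tables are SHA-256-checksummed at load. The package-wide
default seed is 20140401; every function that touches randomness takes an
explicit seed.
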