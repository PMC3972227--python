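# hla-popgen

Population-genetic analysis of HLA-A/-B/-DRB1 typing data from marrow-donor
registries. The package implements the standard analysis chain applied to
registry samples — such as the 21,918 volunteer donors typed in Liaoning
Province, China, whose published summary tables ship here as reference
fixtures — for immunogeneticists and population geneticists who need the
whole pipeline, from raw unphased genotype tables to a phylogeny of
populations, reproducible and scriptable:

1. **Nomenclature consolidation** — allele calls at any resolution are
   reduced to first-field allele groups (`A*02`, `DRB1*09`), except the B14,
   B15 and B40 families, which are kept at serological-split resolution
   (`B*15(62)`, `B*40(60)`, …) via a user-extensible equivalence table.
2. **Allele frequencies** by direct counting of the 2N allele copies.
3. **Hardy–Weinberg equilibrium** χ² tests on genotype classes
   (expected N·p_i² and 2N·p_i·p_j), with rare-allele pooling and an
   optional Monte-Carlo exact variant.
4. **Haplotype frequencies** by the expectation-maximization (EM) algorithm
   over the unobserved phase: a donor heterozygous at h loci is compatible
   with 2^(h−1) diplotypes; EM weights them by f(h₁)·f(h₂) (×2 for
   heterozygous pairs) and re-estimates until the maximum-likelihood
   frequencies converge.
5. **Linkage disequilibrium** of each three-locus haplotype,
   Δ = HF(a,b,d) − p(a)·p(b)·p(d).
6. **Nei standard genetic distance** between populations,
   D = −ln I with I = J_XY / √(J_X·J_Y) and locus-averaged identities,
   and **neighbor-joining** trees (Saitou–Nei), written as Newick.
7. A **synthetic registry generator** (random mating from a known haplotype
   frequency vector) so that every stage is testable against ground truth.

## Worked example

```python
import hla_popgen as hp

# ground truth: the 20 most frequent Han haplotypes, renormalized
truth = hp.han_truth_table(20)
ds = hp.sample_genotypes(hp.SimulationSpec(truth, 2000, population_label="Han", seed=1))

res = hp.HaplotypeFrequencyModel(ds, "Han").fit()
print(res.summary(top_n=5))
```

```
EM haplotype frequency estimate
  population:     Han
  individuals:    2000
  haplotypes:     352 in support
  iterations:     8 (converged)
  log-likelihood: -9809.201492

   A    B        DRB1  frequency
A*30 B*13     DRB1*07     0.2075
A*02 B*46     DRB1*09     0.1035
A*02 B*13     DRB1*12     0.0738
A*33 B*58 DRB1*03(17)     0.0582
A*02 B*46     DRB1*08     0.0532
```

The estimate of the leading haplotype (0.2075) sits within sampling error of
its generating frequency (0.0488/0.2274 ≈ 0.2146 after renormalization);
the log-likelihood trace in `res.log_likelihood_trace` is non-decreasing by
construction of EM, and `res.table.marginal(locus)` reproduces the
direct-counting allele frequencies — a fixed-point property of the M-step.

Working from the packaged reference tables instead:

```python
fx = hp.make_paper_fixtures()
hp.nei_standard_distance(fx.frequencies["Han"], fx.frequencies["Manchu"])
# 0.002095  — the Manchu are by far the closest group to the Han

recs = hp.three_locus_delta(fx.han_haplotypes, fx.frequencies["Han"])
recs[0].haplotype, recs[0].hf, recs[0].delta_percent
# (A*30-B*13-DRB1*07, 0.0488, 4.7783)  — strong positive disequilibrium
```

The same stages are available from the shell (`hla-popgen freq|hwe|em|ld|
dist|tree|simulate`), and `hla-popgen run --config config.yaml` executes
the whole chain per population and writes a machine-readable run report;
reruns with the same configuration and seed are byte-identical.

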