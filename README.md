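# strtrace

Forensic microsatellite (STR) statistics for livestock parentage testing and
breed traceability.

Herd books, PGI-label certification bodies and forensic laboratories need to
answer three questions from a panel of STR markers: *is this the animal it
claims to be* (identity), *are these its parents* (parentage), and *which
breed does it come from* (assignment). `strtrace` implements the statistics
behind all three for diploid multi-locus STR genotypes:

* **Per-locus diversity** — allele counts, observed heterozygosity,
  Nei's unbiased expected heterozygosity He = (2n/(2n−1))(1 − Σpᵢ²),
  polymorphic information content (PIC), and the Guo–Thompson Markov-chain
  exact test for Hardy–Weinberg proportions with Bonferroni correction.
* **Forensic power** — matching probability MP (observed or HWE-expected),
  and three exclusion powers computed exactly from allele frequencies:
  PE-1P (a random non-parent shares no allele with an offspring, second
  parent untyped), PE-2P (a random couple is Mendelian-incompatible with an
  offspring) and PE-SI (two full siblings differ in genotype). Panels
  combine as CMP = Π MPₗ and CPE = 1 − Π(1 − PEₗ), and a search returns the
  smallest marker panel reaching a target combined power (e.g. the
  conventional 99.99 % exclusion level).
* **Population structure** — Weir–Cockerham θ (F_ST, ratio-of-sums across
  loci), allele-size-based R_ST, Reynolds drift distance, and
  neighbor-joining trees (exact on additive distances) with Newick output.
* **Assignment** — frequency-based and Bayesian (Dirichlet 1/K
  posterior-predictive) genotype scores, leave-one-out self-assignment,
  Monte-Carlo exclusion tests (p = (1+x)/(N+1), default 1000 simulated
  genotypes, threshold 0.001), and Monte-Carlo cross-validated assignment
  accuracy over grids of training sizes and top-F_ST marker subsets.
* **Synthetic data** — a Balding–Nichols generator (K populations Dirichlet-
  diverged from ancestral frequencies at a target F_ST), HWE genotypes,
  Mendelian trios, full-sib pairs, and a stepwise-mutation size walk, so
  every statistic in the package has a simulation oracle.

The package ships the published per-locus summary of the Pirenaica cattle
reference sample (114 purebred animals, the 30-marker ISAG-FAO panel) as a
fixture, and named marker lists for the common commercial panels
(Stockmarks 11, ISAG core 12).

## Worked example

How strong are the commercial panels for Pirenaica, and how many markers
does a reliable parentage test actually need?

```python
import strtrace as st

table1 = st.load_pirenaica_table1()
curve = st.combine_panel(table1, st.NAMED_PANELS["isag12"])
print(f"CPE_1 (ISAG 12-marker core): {curve.cpe1[-1]:.4f}")
print(f"CPE_2 (ISAG 12-marker core): {curve.cpe2[-1]:.8f}")
print(f"CMP   (ISAG 12-marker core): {curve.cmp_scientific()}")
full = st.combine_panel(table1)
print(f"CPE_1 (all 30 markers):      {full.cpe1[-1]:.5f}")
design = st.minimal_panel_size(table1, "PE1P", 0.9999)
print(f"loci for CPE_1 >= 0.9999 (ranked by PE-1P): {design.minimal_size}")
design_si = st.minimal_panel_size(table1, "PESI", 0.9999)
print(f"loci for CPE_SI >= 0.9999 (ranked by PE-SI): {design_si.minimal_size}")
```

prints

```
CPE_1 (ISAG 12-marker core): 0.9947
CPE_2 (ISAG 12-marker core): 0.99999977
CMP   (ISAG 12-marker core): 2.262e-12
CPE_1 (all 30 markers):      0.99998
loci for CPE_1 >= 0.9999 (ranked by PE-1P): 20
loci for CPE_SI >= 0.9999 (ranked by PE-SI): 10
```

Reading: with only the 12-marker core panel, about 1 in 190 true
non-parents would *not* be excluded when one parent is untyped
(CPE₁ = 0.9947 < 0.9999), so single-parent cases need a larger panel — about
20 markers when chosen by exclusion power. Full-sib discrimination is easier:
10 well-chosen markers reach the 99.99 % level. Two random animals share a
full 12-marker profile with probability ≈ 2×10⁻¹², ample for identity.

The same operations are available from the shell:

```sh
strtrace simulate --pops 3 --fst 0.12 --loci 30 --n 114,13,21 --seed 1 --out herd.gen
strtrace summarize herd.gen --hwe --seed 1
strtrace panel - --fixture --metric pe1p --threshold 0.9999
strtrace dist herd.gen --stat fst
strtrace tree herd.gen --distance ashare
strtrace assign herd.gen --method freq
strtrace cv herd.gen --train 10 --loci 5,15,30 --iters 100 --seed 1
```

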