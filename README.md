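# minkpop

Population genetics of small, fragmented riparian populations — built around
the classic study design used for the critically endangered European mink
(*Mustela lutreola*): mtDNA control-region haplotypes plus a panel of diploid
microsatellite loci scored in a handful of regional populations, analysed for
diversity, neutrality, structure, and colonization history.

The package is aimed at conservation and population geneticists who want the
whole analysis chain of that study design as one tested, scriptable library
rather than a relay of desktop programs:

- **Coalescent scenario simulator** — backward-time n-coalescent over an
  explicit event schedule (population splits, admixture pulses, effective
  size changes), with generalized stepwise mutation (GSM) for
  microsatellites and infinite-sites mutation for mtDNA. It doubles as the
  reference simulator for ABC and as the synthetic-data generator behind
  every test in this repository.
- **Diversity & neutrality** — Nei's haplotype diversity
  *ĥ = n(1 − Σp²)/(n−1)*, per-site nucleotide diversity π, Tajima's *D*,
  Fu's *Fs* (via the Ewens sampling formula), Ramos-Onsins & Rozas *R2*;
  significance from 10⁴ coalescent simulations conditioned on the observed
  number of segregating sites.
- **Microsatellite statistics** — allele counts and private alleles, Nei's
  unbiased *He*, Weir–Cockerham *F_IS*, Monte-Carlo exact Hardy–Weinberg
  and linkage-disequilibrium tests, Bonferroni correction, and EM
  estimation of null-allele frequencies.
- **Differentiation** — pairwise Φ_ST / Weir–Cockerham θ (F_ST) / Slatkin
  R_ST with permutation significance; hierarchical AMOVA
  (σ²_a, σ²_b, σ²_c → Φ_CT, Φ_SC, Φ_ST); SAMOVA, a simulated-annealing
  search for the geographically contiguous k-group partition maximizing
  F_CT.
- **Median-joining haplotype networks** with quasi-median vectors and
  maximum-parsimony cleanup.
- **ABC model choice** — reference tables over candidate demographic
  scenarios (the study's fourteen colonization histories ship as
  `mink_scenarios()`), 1 % rejection on SD-normalized summary statistics,
  and polychotomous logistic regression on linear-discriminant projections,
  with bootstrap confidence intervals and a confusion-matrix calibration.

## Worked example

Simulate a dataset at the study layout (four regional populations NE/SE/FR/SP,
313 genotyped individuals at 11 loci, 157 mtDNA sequences) under the
admixture-origin scenario, then compute the mtDNA variability table:

```python
from minkpop import generate_mink_like, trim_gapped_columns
from minkpop.diversity import diversity_summary, neutrality_test

aln = trim_gapped_columns(generate_mink_like(2, seed=42).alignment)
for row in diversity_summary(aln):
    print(row.label, row.n, row.n_haplotypes, round(row.h, 3), round(row.pi, 5))
res = neutrality_test(aln, reps=2000, rng=1)
print(res.tajimas_d, res.p_tajimas_d)
```

prints (see `examples/02_diversity_neutrality.py` for the formatted version):

```
  pop    n  Nh  Ph       h        pi
  all  157  12  11   0.853   0.00683
   NE   54   4   4   0.691   0.00191
   SE   22   4   4   0.758   0.00528
   FR   36   2   1   0.437   0.00092
   SP   45   3   2   0.524   0.00222

S = 17 segregating sites over 157 sequences
Tajima's D = +0.204  (p = 0.692)
Fu's Fs    = +0.844  (p = 0.669)
R2         = 0.4996  (p = 0.393)
```

Each row gives the sample size *n*, observed haplotypes *N_h* with private
haplotypes *P_h*, haplotype diversity *h* and nucleotide diversity *π* for
one region; the neutrality block shows that none of the three tests rejects
a stable (non-expanding) population history for this draw (all *p* > 0.05),
the same qualitative outcome the real mink data gave.

The other capabilities have one narrative script each under `examples/`
(simulation ground truth, microsatellite variability, differentiation +
AMOVA/SAMOVA, haplotype network, ABC model choice). A thin CLI wraps the
pipeline: `minkpop simulate | run | fixtures`.

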