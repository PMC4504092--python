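"""Sequence diversity and neutrality tests on a synthetic dataset.

Prints a variability table (haplotype and nucleotide diversity per region)
and the three neutrality statistics with coalescent-simulated p-values.
A non-significant test (p > 0.05) is what stable, non-expanding populations
produce; strongly negative D/Fs with small p would signal expansion.
"""

from minkpop import generate_mink_like, trim_gapped_columns
from minkpop.diversity import diversity_summary, neutrality_test

aln = trim_gapped_columns(generate_mink_like(2, seed=42).alignment)

print(f"{'pop':>5} {'n':>4} {'Nh':>3} {'Ph':>3} {'h':>7} {'pi':>9}")
for row in diversity_summary(aln):
    print(f"{row.label:>5} {row.n:>4} {row.n_haplotypes:>3} "
          f"{row.private_haplotypes:>3} {row.h:7.3f} {row.pi:9.5f}")

res = neutrality_test(aln, reps=2000, rng=1)
print(f"\nS = {res.S} segregating sites over {res.n} sequences")
print(f"Tajima's D = {res.tajimas_d:+.3f}  (p = {res.p_tajimas_d:.3f})")
print(f"Fu's Fs    = {res.fus_fs:+.3f}  (p = {res.p_fus_fs:.3f})")
print(f"R2         = {res.r2:.4f}  (p = {res.p_r2:.3f})")
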