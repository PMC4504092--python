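"""Median-joining haplotype network with parsimony cleanup.

Collapses the mtDNA alignment into distinct haplotypes and links them with
mutation-step edges; inferred median (missing intermediate) haplotypes are
added only where they shorten the network, and pruned back to true branch
points.  A star-like topology around a frequent central haplotype is the
classic signature of expansion from a refuge.
"""

from minkpop import collapse_haplotypes, generate_mink_like, trim_gapped_columns
from minkpop.network import median_joining

aln = trim_gapped_columns(generate_mink_like(2, seed=42).alignment)
table = collapse_haplotypes(aln)
net = median_joining(table, epsilon=0)

names = {h: f"H{k + 1}" for k, h in enumerate(table.haplotypes)}
for m, h in enumerate(net.medians):
    names[h] = f"mv{m + 1}"

print(f"{len(table.haplotypes)} observed haplotypes, "
      f"{len(net.medians)} median vectors, total length {net.total_length:.0f} steps")
print("edges (steps):")
for u, v, w in sorted(net.export_edgelist(), key=lambda e: (names[e[0]], names[e[1]])):
    print(f"  {names[u]:>4} -- {names[v]:<4} {w}")
print("haplotype frequencies:",
      {names[h]: f for h, f in net.frequencies.items()})
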