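"""Pairwise fixation indices, hierarchical AMOVA and the SAMOVA search.

Phi_ST (mtDNA sequence distances) and F_ST/R_ST (microsatellites) measure
among-population differentiation; the AMOVA decomposes the variance into
among-group / among-population / within-population components, and SAMOVA
finds the geographic grouping of populations that maximizes the among-group
index F_CT.
"""

import numpy as np

from minkpop import generate_mink_like, trim_gapped_columns
from minkpop.differentiation import (
    amova,
    f_st_pairwise,
    genotype_distance_matrix,
    phi_st_pairwise,
    samova,
    sequence_distance_matrix,
)
from minkpop.pipeline import REGION_COORDS

ds = generate_mink_like(2, seed=42)
aln = trim_gapped_columns(ds.alignment)

pm = phi_st_pairwise(aln, permutations=199, rng=0)
off = pm.values[np.triu_indices_from(pm.values, k=1)]
print(f"pairwise Phi_ST over {pm.populations}: "
      f"{np.nanmin(off):.3f} .. {np.nanmax(off):.3f}")

fst = f_st_pairwise(ds.genotypes, permutations=199, rng=1)
print("pairwise F_ST matrix:")
for i, p in enumerate(fst.populations):
    row = " ".join(
        "  -  " if np.isnan(v) else f"{v:5.3f}" for v in fst.values[i]
    )
    print(f"  {p:>3} {row}")

labels = [ds.genotypes.pop_of[i] for i in ds.genotypes.individuals]
d2 = genotype_distance_matrix(ds.genotypes)
res = amova(d2, labels, {"NE": "East", "SE": "East", "FR": "West", "SP": "West"},
            permutations=199, rng=2)
print(f"\nAMOVA (East vs West, microsatellites): "
      f"F_CT = {res.phi_ct:.3f} (p = {res.p_ct:.3f}), "
      f"F_ST = {res.phi_st:.3f} (p = {res.p_st:.3f})")

d2s = sequence_distance_matrix(aln)
seq_labels = [aln.pop_of[i] for i in aln.ids]
best = max(
    (samova(d2s, seq_labels, REGION_COORDS, k, rng=3) for k in (2, 3, 4)),
    key=lambda r: r.f_ct,
)
print(f"SAMOVA best grouping: k = {best.k}, F_CT = {best.f_ct:.3f} "
      f"(p = {best.p_value:.3f}), assignment = {best.assignment}")
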