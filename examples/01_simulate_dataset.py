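"""Simulate a synthetic four-population dataset under an admixture scenario.

Generates the default study layout — 313 diploid individuals genotyped at 11
microsatellite loci in four regional populations (NE=107, SE=44, FR=73,
SP=89) plus 157 mtDNA control-region sequences — under scenario 2, in which
the western lineage is founded by an NE x SE admixture pulse.
"""

from minkpop import collapse_haplotypes, generate_mink_like

ds = generate_mink_like(scenario_id=2, seed=42)

print(f"scenario          : {ds.scenario}")
print(f"genotyped         : {ds.genotypes.n} individuals x {ds.genotypes.n_loci} loci")
print(f"sequenced         : {ds.alignment.n} mtDNA sequences of {ds.alignment.length} bp")
table = collapse_haplotypes(ds.alignment)
print(f"distinct haplotypes: {len(table.haplotypes)}")
print("drawn parameters   :")
for k, v in sorted(ds.params.items()):
    print(f"  {k:>6} = {v:,.4g}")
# The parameter draw is the embedded ground truth: effective sizes (diploid
# individuals), event times (generations) and the admixture proportion r.
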