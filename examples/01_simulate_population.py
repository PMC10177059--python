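"""Simulate the tetraploid half-diallel study population.

Builds 16 founders (8 frost-tolerant interspecific lines, 8 sensitive
cultivars), samples 23 viable crosses from the 136 half-diallel combinations
and generates 406 F1 progeny with three causal frost-tolerance loci on
chromosomes II, V and IX.
"""

from frostmas import simulate as sim

cfg = sim.SimulationConfig(seed=1)
pop = sim.simulate_population(cfg)

print(f"founders : {len(pop.founders)} "
      f"({sum(f.class_label == 'tolerant' for f in pop.founders)} tolerant)")
print(f"crosses  : {len({(p.mother_id, p.father_id) for p in pop.progeny})}")
print(f"progeny  : {len(pop.progeny)}")
print(f"variants : {len(pop.variants)} "
      f"({int(pop.variants['is_causal'].sum())} causal, "
      f"{(pop.variants['cluster'] >= 0).sum()} in linkage blocks)")
for locus in pop.causal_loci:
    print(f"  causal locus {locus.chromosome}:{locus.position:,} "
          f"effect {locus.effect} injury units")
# The dosage matrices hold 0-4 alternate-allele copies per individual and
# site; every downstream stage (phenotyping, pooling, sequencing) reads them.
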