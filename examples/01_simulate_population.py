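"""Simulate a small line-breeding population: genetic map, inbred founders,
a bi-parental DH family, an additive trait and noisy phenotype records."""

import famblup as fb

gmap = fb.generate_genetic_map(n_chromosomes=5, markers_per_chromosome=80,
                               chrom_length_cM=120.0, seed=1)
founders = fb.generate_founders(50, gmap, maf_range=(0.05, 0.5), seed=2)
print(f"map: {gmap.n_markers} markers on {len(gmap.chromosomes())} chromosomes")
print(f"founders: {founders.n_lines} fully homozygous lines")

# cross two founders and derive 30 doubled-haploid progeny
p1, p2 = founders.line_ids[:2]
progeny = fb.simulate_progeny(founders.calls.loc[p1], founders.calls.loc[p2],
                              gmap, n_progeny=30, progeny_type="DH", seed=3)
seg = (founders.calls.loc[p1] != founders.calls.loc[p2]).sum()
print(f"family {p1} x {p2}: 30 DH progeny, {seg} segregating loci")

# additive trait: 40 QTL with N(0,1) effects, 300 disjoint relationship SNPs
arch = fb.sample_trait_architecture(gmap.marker_ids, n_qtl=40, n_snp=300, seed=4)
tbv = fb.true_breeding_values(arch, progeny).tbv
noised = fb.add_phenotyping_noise(tbv, target_h2=0.5, seed=5)
print(f"progeny TBV range: {tbv.min():.2f} .. {tbv.max():.2f}")
print(f"records at h2=0.5: error variance {noised.error_variance:.2f} "
      f"(equals the TBV variance, by construction)")
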