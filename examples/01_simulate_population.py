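"""Simulate a biparental breeding population and look at its structure.

Builds one replicate of the canonical single-cross design: an outbred
parent A (an F1 of two inbred grandparents) crossed to an inbred mate B,
200 F2 descendants of which 10 are genotyped at high density (2,000
SNPs) and the rest at low density (50 SNPs), with parent A ungenotyped.
"""

import numpy as np

from bipimpute import MISSING, ScenarioSpec, build_scenario

spec = ScenarioSpec(
    parentA_inbred=False,
    parentA_genotyping="none",
    n_crosses=1,
    n_f2_per_cross=200,
    n_hd_descendants_per_cross=10,
    n_hd_snps=2000,
    n_ld_snps=50,
    n_base_sites=12000,
    seed=42,
)
sim = build_scenario(spec)

a = sim.true_genotype("A")
print(f"panel: {sim.panel.n_markers} Hd SNPs, "
      f"{len(sim.panel.ld_marker_ids)} Ld SNPs on a "
      f"{sim.panel.positions_cm[-1]:.0f} cM chromosome")
print(f"pedigree: {len(sim.pedigree.individuals)} individuals, "
      f"founders first: {sim.pedigree.topological_order()[:4]}")
print(f"parent A heterozygosity (true): {np.mean(a == 1):.3f}")
print(f"parent A observed markers (masked): "
      f"{np.sum(sim.genotypes_masked.row('A') != MISSING)}")
hd = sim.hd_descendants['B'][0]
focal = sim.focal_individuals['B'][0]
print(f"Hd descendant {hd}: "
      f"{np.sum(sim.genotypes_masked.row(hd) != MISSING)} observed markers")
print(f"focal individual {focal}: "
      f"{np.sum(sim.genotypes_masked.row(focal) != MISSING)} observed markers")

# The heterozygosity line shows parent A segregates at a sizeable share
# of the panel (it is an F1 of two inbred founders); the masked counts
# show the genotyping design: A fully missing, 10 descendants at full
# density, the focal F2 at the 50-SNP panel only.
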