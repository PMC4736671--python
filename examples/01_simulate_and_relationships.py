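"""Simulate a paternal half-sib population and build its G and D matrices.

Generates 10 sire families of 25 genotyped daughters at 800 SNPs, then
builds the additive and dominance genomic relationship matrices and
summarises their structure.  Paternal half-sibs share one parent, so
their expected additive relationship is 0.25 while unrelated pairs sit
near 0; dominance relationships between half-sibs without shared dams
are expected near 0.
"""

import numpy as np

from domgblup import (
    SimConfig,
    build_additive_grm,
    build_dominance_grm,
    estimate_allele_frequencies,
    simulate_dataset,
)

cfg = SimConfig(n_sires=10, daughters_per_sire=25, n_snps=800, seed=4)
genotypes, truth, records = simulate_dataset(cfg)
print(f"simulated {genotypes.n_animals} daughters x {genotypes.n_snps} SNPs, "
      f"{len(records)} phenotype records")

freqs = estimate_allele_frequencies(genotypes)
G = build_additive_grm(genotypes, freqs)
D = build_dominance_grm(genotypes, freqs)

sires = np.asarray(genotypes.sires)
same_family = np.equal.outer(sires, sires) & ~np.eye(len(sires), dtype=bool)
diff_family = ~np.equal.outer(sires, sires)

print(f"mean diagonal of G:                {np.diag(G.values).mean():.3f}  (~1)")
print(f"mean G within half-sib families:   {G.values[same_family].mean():.3f}  (~0.25)")
print(f"mean G between families:           {G.values[diff_family].mean():.3f}  (~0)")
print(f"mean D within half-sib families:   {D.values[same_family].mean():.3f}  (~0)")
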