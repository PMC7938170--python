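"""Senescence evolves even when mother and daughter cells are perfectly
symmetric.

Runs a desk-scale version of the high-D experiment (damage has almost no
direct survival effect; deaths come from damage-gated deleterious alleles)
and prints the allocation equilibrium, the deleterious-allele frequency
gradient across damage windows, and the age trend of mortality.

Takes ~10 s.  Larger populations sharpen every number.
"""

import numpy as np
from scipy.stats import spearmanr

import bicell

params = bicell.get_preset("fig1").with_overrides(n=5_000, cycles=1_000, seed=1)
result = bicell.run_simulation(params)
summary = bicell.equilibrium_summary(result.trajectory)

alloc = summary["mean_alloc"].mean(axis=0)
print(f"mean allocation (both types, final 10% of cycles):")
print(f"  foraging     p_x = {alloc[0]:.3f}")
print(f"  repair       p_y = {alloc[1]:.3f}")
print(f"  reproduction p_z = {alloc[2]:.3f}")
print(f"division-of-labour index: {summary['dol_index']:.3f} "
      "(0 = the two cell types allocate identically)")

freqs = summary["allele_freq"]
rho, pval = spearmanr(np.arange(freqs.size), freqs)
print(f"\ndeleterious-allele frequency per damage window (low -> high damage):")
print("  " + " ".join(f"{f:.2f}" for f in freqs))
print(f"Spearman rank correlation with window index: {rho:.2f} (p = {pval:.2g})")
print("  a positive gradient = mutation accumulation: selection is weak against")
print("  alleles expressed at damage levels few individuals reach")

mort = bicell.empirical_mortality_by_age(result.trajectory)
mort = mort[mort.exposures >= 1000]
print(f"\nage-specific mortality (deaths/exposures, final 10% of cycles):")
for _, row in mort.iterrows():
    print(f"  age {int(row.age):2d}: {row.mortality:.4f}")
print("rising mortality with age despite fully symmetric reproduction — the")
print("hallmark of senescence, with no germ-line/soma distinction at all")
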