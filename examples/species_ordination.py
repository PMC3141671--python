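"""Within-group correspondence analysis of codon usage across species.

Builds ten synthetic species spanning genome-wide GC3 from 0.30 to 0.90,
pools each species' coding sequences, and ordinates the species x 59
codon-count table by within-group CA - which removes amino-acid
composition effects so only synonymous codon choice is compared. The
first axis should recover the GC3 gradient.
"""

import numpy as np
from scipy.stats import spearmanr

import dupetime as dt

targets = np.linspace(0.30, 0.90, 10)
species = {
    f"sp{i:02d}": dt.generate_coding_set(15, 600, float(t), seed=500 + i)
    for i, t in enumerate(targets)
}

analysis = dt.composition(species, mode="wca")
coords = analysis.ordination.row_coords["axis1"]

print("species   GC3_target  GC3_realized  WCA_axis1")
for i, name in enumerate(species):
    print(f"{name}    {targets[i]:.2f}        {analysis.stats['GC3'].iloc[i]:.3f}"
          f"         {coords.iloc[i]: .4f}")

frac = analysis.ordination.inertia_fractions
rho = spearmanr(coords, targets)[0]
print(f"\naxis 1 carries {100 * frac[0]:.1f}% of within-group inertia")
print(f"Spearman rho(axis1, GC3 target) = {rho:+.3f}")
print(f"Pearson r^2(axis1, realized GC3) = {analysis.axis1_gc3_r2:.3f}")
print("\n|rho| near 1: synonymous usage varies across these species almost")
print("entirely along their GC3 gradient, as in real vertebrate comparisons.")
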