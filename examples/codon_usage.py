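"""Per-gene codon-usage bias against Wright's no-selection expectation.

Generates an in-frame coding-sequence set whose synonymous choices are
tilted toward GC3 = 0.75 (a lamprey-like high-GC3 regime) with no further
codon preference, then compares each gene's effective number of codons
(ENc) with the null curve ENc = 2 + s + 29/(s^2 + (1-s)^2).
"""

import dupetime as dt

cds = dt.generate_coding_set(
    n_genes=30, length=900, gc3_target=0.75, preference_strength=0.0, seed=7
)
stats = dt.enc_table(cds)
stats["ENc_expected"] = dt.expected_enc(stats["GC3"].to_numpy())
stats["deviation"] = stats["ENc"] - stats["ENc_expected"]

print(stats.head(8).round(3).to_string())
print(f"\nmean GC3      = {stats['GC3'].mean():.3f}  (target 0.75)")
print(f"mean ENc      = {stats['ENc'].mean():.2f}")
print(f"mean expected = {stats['ENc_expected'].mean():.2f}")
print("\nGenes generated with a pure GC3 tilt sit close to the null curve:")
print("codon bias here is explained by composition, not translational selection.")

rscu = dt.rscu(dt.codon_counts(cds, by="dataset")).iloc[0]
print("\nmost over-used codons (RSCU > 1 means above within-family average):")
print(rscu.sort_values(ascending=False).head(5).round(2).to_string())
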