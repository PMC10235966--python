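"""Score an actin gene set per cell and compare populations.

Generates a negative-binomial count matrix for four labeled populations with
a 2x actin-set effect planted in HF-SCs, normalizes, computes the bin-matched
module score, and compares populations nonparametrically.
"""

from follipulse import actin, synth

adata, gene_set = synth.gen_expression(synth.ExprSimParams(seed=3))
normed = actin.normalize_counts(adata)
result = actin.module_score(normed, gene_set, seed=3)

print(result.population_summary().round(3))
diff, comp = actin.compare_population_scores(result, "HF-SC", "HG")
print(f"\nHF-SC vs HG: mean-score difference {diff:.3f}, Mann-Whitney p = {comp.p_value:.2e}")
print(
    "The planted 2x actin-set expression puts HF-SCs on top, mirroring their\n"
    "strong actomyosin network; null populations score near zero."
)
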