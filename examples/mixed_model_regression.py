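"""Per-gene mixed-effect regression of regulatory percentiles.

Each comparison is one observation; fixed effects capture cell line,
platform, drug type, treatment duration and the drug x duration
interaction, with a random intercept shared by comparisons from the same
experimental batch.  The fitted drug-type coefficient measures how many
percentile points a gene's response differs between drug classes.
"""

from ermeta import synthetic as syn
from ermeta.meta_stats import fit_all_mixed_models, fit_gene_mixed_model

TERM = "C(drug_type)[T.SERM]"

# a gene with a planted +30-point SERD-specific response
y, metas, truth = syn.generate_regression_dataset(
    n_genes=6, n_comparisons=40, drug_effect=30.0, affected_frac=0.5, seed=22
)
affected = set(truth.roles["drug_affected"])
print("per-gene drug-type effects (SERM relative to SERD, percentile points):")
for gene in y.index:
    res = fit_gene_mixed_model(y.loc[gene], metas, gene)
    tag = "planted +30 on SERD" if gene in affected else "null"
    print(f"  {gene}: coef {res.coefficients[TERM]:+7.2f}  "
          f"p {res.pvalues[TERM]:.2e}  batch var {res.group_var:6.1f}  ({tag})")

print("\nplanted genes show coefficients near -30 (SERM lacks the SERD shift);")
print("null genes scatter near 0 with large p-values.")

out = fit_all_mixed_models(y, metas, adjust_term=TERM)
drug = out[out["term"] == TERM]
print(f"\nBH-adjusted drug-term p-values across all {len(drug)} genes:")
print(drug[["gene_id", "coefficient", "p", "padj"]].round(4).to_string(index=False))
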