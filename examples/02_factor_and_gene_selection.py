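"""Pick the singular-vector triple matching the study design, then select genes.

The replicate-mode vector should be flat (replicates measure the same thing),
the slice-mode vector opposite-signed (the two cell lines differ), and the
gene-mode vector is the one with the largest core weight for that pair. Genes
are then tested against a Gaussian null whose scale sigma is optimized so the
bulk of the p-value histogram is flat.
"""

from tdufe import (
    SyntheticSpec,
    choose_factors,
    evaluate_recovery,
    generate_tensor,
    hosvd,
    select_genes,
    standardize_tensor,
)

tensor, truth = generate_tensor(SyntheticSpec(seed=1))
tensor = standardize_tensor(tensor)
result = hosvd(tensor)

choice = choose_factors(result)
print(f"chosen components: l1={choice.l1} (genes), l2={choice.l2} (replicates), "
      f"l3={choice.l3} (cell lines)")
print(f"replicate-constancy score of l2: {choice.constancy_scores[choice.l2]:.4f} "
      "(sd/|mean|, 0 = perfectly flat)")

u = result.factors[0][:, choice.l1]
sel = select_genes(u, threshold=0.01)
print(f"optimized null sigma: {sel.sigma:.3e} (loadings are unit-norm, hence tiny)")
print(f"genes selected at BH-adjusted p < 0.01: {sel.n_selected}")

metrics = evaluate_recovery(sel.selected, truth)
print(f"against planted truth: precision={metrics.precision:.3f}, "
      f"recall={metrics.recall:.3f} (500 genes planted at 6 noise-sd)")
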