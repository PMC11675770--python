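# tdufe — tensor-decomposition unsupervised feature extraction

`tdufe` selects genes from multi-condition expression studies by decomposing a
genes × replicates × slices tensor with the higher-order SVD (HOSVD), instead
of fitting a per-gene regression. It is aimed at designs like "two cell lines,
several replicate samples each": the decomposition

    x_ijk = Σ G(l1, l2, l3) · u_l1(gene i) · u_l2(replicate j) · u_l3(slice k)

concentrates coordinated expression patterns into a few components, and the
study design says which component matters — the replicate-mode vector should
be **constant** (replicates measure the same thing) and the slice-mode vector
**opposite-signed** (the two lines differ). The gene-mode vector coupled most
strongly to that pair (largest `|G|`) carries per-gene loadings `u_i`, which
are tested against a Gaussian null

    P_i = P[χ²₁ > (u_i / σ)²],

with σ optimized so the p-value histogram's bulk is flat, BH-adjusted, and
thresholded (default adjusted p < 0.01). Selected genes can then be tested
for gene-set over-representation with exact hypergeometric tails against GMT
collections. A synthetic-data generator with planted ground truth makes every
stage testable end to end. See `docs/methods.md` for the full model.

## Worked example

```python
from tdufe import (SyntheticSpec, generate_tensor, standardize_tensor, hosvd,
                   choose_factors, select_genes, evaluate_recovery)

tensor, truth = generate_tensor(SyntheticSpec(seed=1))   # 10,000 × 8 × 2, 500 signal genes
tensor = standardize_tensor(tensor)                      # each sample column → mean 0, var 1
result = hosvd(tensor)
choice = choose_factors(result)                          # flat-in-j, opposed-in-k, max |G|
sel = select_genes(result.factors[0][:, choice.l1], threshold=0.01)
m = evaluate_recovery(sel.selected, truth)
print(choice.l1, choice.l2, choice.l3, sel.n_selected, round(m.precision, 3), round(m.recall, 3))
```

prints

```
0 0 0 503 0.994 1.0
```

i.e. the leading component of every mode carries the planted pattern, 503
genes pass the adjusted-p cutoff, and against the planted truth that selection
has precision 0.994 and recall 1.000. The scripts in `examples/` walk through
each capability (decomposition, factor and gene selection, enrichment, the
one-call pipeline) with commentary on the printed numbers.

A thin CLI mirrors the library for shell use:

```bash
tdufe simulate --out sim/ --seed 1
tdufe run-all --config examples/run.yaml --out run/
```

Real data enters as TSV/CSV expression matrices via
`read_expression_matrices(paths, layout)`, where `layout` maps each table
column to its (replicate, slice) cell; gene-set collections are standard GMT
files.

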