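# mdapred

Prediction of disease-associated microRNAs by graph-regularized
nonnegative matrix factorization.

Most human diseases are regulated by miRNAs, but experimentally testing
each miRNA-disease pair is slow and expensive. `mdapred` prioritises
candidate pairs computationally by integrating four kinds of evidence: the
known binary association matrix **A** (miRNA x disease), a miRNA
similarity matrix **M**, a disease similarity matrix **D**, and a sparse
binary node-attribute matrix **C** recording each miRNA's family and
genomic-cluster membership (miRNAs of one family share a seed region and
tend to regulate similar targets; clustered miRNAs are co-transcribed).
It is aimed at computational biologists who want a ranked candidate list
per disease plus the standard cross-validated evaluation of that ranking.

## Model

The association score matrix `U >= 0` (miRNA x disease) minimises

```
L(U, X, Y, Z) =  ||U - A||_F^2
              + a1 ||U - M X (D Y)^T||_F^2
              + a2 ||U - C Z (D Y)^T||_F^2
              + a3 Tr(U^T L U)
              + a4 ||U||_1         with U, X, Y, Z >= 0.
```

`X`, `Y`, `Z` project the miRNA similarities, disease similarities and
node attributes into a shared `c`-dimensional space, so a pair's score is
pulled toward the inner product of its miRNA and disease feature vectors.
`L = W - S` is the Laplacian of the k-nearest-neighbour graph over miRNA
similarities, smoothing scores across similar miRNAs, and the `l1` term
keeps the predicted association pattern sparse. The objective is solved by
cycling four multiplicative block updates (U -> X -> Y -> Z) that preserve
nonnegativity exactly; defaults are `a1 = a2 = a3 = a4 = 0.1`, `c = 15`,
`k = 5`, at most 100 cycles or an absolute objective change below `1e-6`.

Evaluation follows masked five-fold cross-validation: known positives are
split into five folds, each fold is hidden from training in turn, and each
evaluated disease's hidden positives are ranked against its
never-associated miRNAs (per-disease AUC, AUPR and top-k recall, plus a
paired t-test for comparing scorers).

## Worked example

`examples/02_cross_validation.py` generates a planted low-rank synthetic
network (200 miRNAs, 40 diseases, rank 6, 8% density, label noise),
cross-validates the model over the 15 best-annotated diseases, and fits an
ablation with `a1 = a2 = a3 = 0` that can only shrink the training matrix:

```
$ python examples/02_cross_validation.py
evaluated diseases: 15
mean AUC  0.963   (ablation without side information: 0.500)
mean AUPR 0.586
mean top-k recall: {30: 0.917, 60: 0.99, 90: 1.0}
```

Mean AUC 0.963 means a hidden true association outranks a random
never-associated candidate 96% of the time; the ablation's 0.500 shows
that all of this signal enters through the similarity, attribute and graph
terms, since hidden positives are zeros in the training matrix. The other
examples demonstrate candidate ranking for a single disease
(`01_fit_and_rank.py`), the functional-similarity/graph builders
(`03_similarity_graph.py`), and the paired significance test
(`04_compare_methods.py`).

A thin CLI wraps the same library calls:

```
mdapred synth --outdir fixtures/
mdapred fit --associations A.tsv --mirna-sim M.tsv --disease-sim D.tsv \
            --attributes C.tsv --out scores.tsv
mdapred evaluate --associations A.tsv --mirna-sim M.tsv --disease-sim D.tsv \
                 --attributes C.tsv --min-positives 80 --out report.json
```

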