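# Methods

## Model and assumptions

`mdapred` scores miRNA-disease pairs with a nonnegative score matrix
`U` (Nm x Nd) fitted to four evidence sources at once:

```
min_{U,X,Y,Z >= 0}  ||U - A||_F^2
                  + a1 ||U - M X (D Y)^T||_F^2
                  + a2 ||U - C Z (D Y)^T||_F^2
                  + a3 Tr(U^T L U)
                  + a4 ||U||_1
```

- `A` (binary, Nm x Nd): observed associations. Zeros mean *unobserved*,
  not negative — the fit term anchors U to the known positives while the
  remaining terms redistribute mass onto plausible unobserved pairs.
- `M` (Nm x Nm) and `D` (Nd x Nd): nonnegative similarity matrices.
  `X` (Nm x c) and `Y` (Nd x c) project them into a shared c-dimensional
  space; the similarity term pulls `U_ij` toward `(MX)_i (DY)_j^T`, i.e.
  toward the inner product of the two entities' low-dimensional features.
- `C` (binary, Nm x (Nf + Nc)): family and cluster membership. Because a
  miRNA typically belongs to at most one family and one cluster, `C` is
  extremely sparse; projecting it through `Z` lets miRNAs that share a
  family/cluster share association structure. When `C` has zero columns
  the a2 term and the `Z` block are dropped entirely (an empty projection
  would otherwise degenerate to an unintended `||U||^2` ridge penalty).
- `L = W - S`: combinatorial Laplacian of the miRNA kNN graph. Row i of
  `S` marks miRNA i's `min(k, #positive-similarity candidates)` nearest
  neighbours (ties broken by smaller index for determinism), so the
  degree `W_ii = sum_j S_ij` counts i's own neighbours; by default `S` is
  symmetrized by elementwise max with its transpose, which makes
  `Tr(U^T L U) = 1/2 sum_ij S_ij ||U_i - U_j||^2` the standard smoothness
  penalty. The raw directed graph is kept behind `symmetrize_neighbors`
  because the update rules use `S` and `W` directly and remain
  well-defined either way.
- `||U||_1`: most diseases have few associated miRNAs, so the score
  pattern itself should be sparse.

The underlying biological assumptions: functionally similar miRNAs (and
semantically similar diseases) share associations; family/cluster
membership predicts shared targets; and association evidence propagates
along the miRNA neighbour graph.

## Optimisation

The objective is non-convex jointly but is handled as four coordinate
blocks, each updated by a multiplicative rule that rescales every entry by
the ratio of the negative to the positive part of its block gradient, e.g.

```
U <- U * [2A + 2 a1 MX(DY)^T + 2 a2 CZ(DY)^T + 2 a3 S U]
       / [2U + 2 a1 U + 2 a2 U + 2 a3 W U + a4 B]        (B = all-ones)
```

and analogous rules for `X`, `Y`, `Z`. Because every factor starts
strictly positive and each rule multiplies by a nonnegative ratio,
nonnegativity holds exactly at every iteration with no projection step.
Correctness of each rule is verified in the test suite two independent
ways: direct elementwise substitution of the rule, and central finite
differences of the corresponding sub-objective against the gradient
implied by the rule's numerator/denominator split.

Numerical choices:

- **Initialisation** (seeded): `U0 = A + 0.1 * max(mean(A), 0.01) *
  Uniform(0,1)` — strictly positive so multiplicative updates can move
  every entry, warm-started at the data (`init_scheme =
  "warm_start_from_A"`); `X0, Y0, Z0 ~ 0.01 * Uniform(0,1)`. A plain
  `uniform_random` scheme for `U0` is available. The `mean(A)` floor keeps
  an all-zero `A` movable.
- **Denominator guard**: an additive floor of `1e-12` on every update
  denominator; the raw rules are undefined at zero, and the floor shifts
  interior fixed points by a negligible relative amount.
- **Update order** U -> X -> Y -> Z, each block seeing the freshest
  values; the objective is recorded once per full cycle.
- **Stopping**: absolute objective change between adjacent cycles below
  `epsilon = 1e-6`, or 100 cycles. Absolute thresholds are
  scale-dependent, so a relative mode (`convergence = "relative"`) is
  provided.
- **Degenerate inputs**: `max_iter = 0` returns the initial state;
  all-zero attribute rows contribute a zero feature vector and are
  harmless; `k = Nm - 1` yields the complete graph when all similarities
  are strictly positive; non-finite values in any factor abort with a
  diagnostic naming the block and iteration.

Multiplicative rules of this family are not guaranteed monotone, so the
suite *measures* monotonicity (objective non-increasing in >= 99% of
cycles over 20 seeded runs) rather than assuming it, and checks the
complementary-slackness (KKT) residual `|factor * gradient|` at
convergence. Doubling the sparsity weight `a4` is checked never to
increase `||U||_1` at convergence.

## Hyperparameters

| name | default | meaning |
|---|---|---|
| a1, a2, a3, a4 | 0.1 | weights of the similarity-projection, attribute-projection, graph and l1 terms (grid-searched over {0.01, 0.1, 1, 10} in the original study; 0.1 across the board performed best) |
| c | 15 | shared latent dimension; must satisfy `c < min(Nm, Nd, Nf+Nc)`; the suite also exercises c in {5, 10} at smaller problem sizes |
| k_neighbors | 5 | miRNA kNN graph size; the source study never reports it, 5 is this package's default |
| epsilon | 1e-6 | stopping tolerance on the objective change |
| max_iter | 100 | maximum full update cycles |

## Evaluation protocol

Positives are partitioned uniformly at random into five near-equal folds
(seeded). For each fold, its cells are zeroed in the training matrix, the
model is refit, and for each evaluated disease the held-out positives are
scored against the disease's never-associated miRNAs (training positives
are excluded from the candidate pool; positives of *other* diseases for
the same miRNA are not excluded). Per-disease AUC (rank statistic, ties
half-counted), AUPR (trapezoid over the threshold-sweep PR curve, with an
average-precision alternative) and top-k recall are averaged over folds,
then over diseases; ROC/PR curves are vertically averaged on a fixed
1000-point grid. Only well-annotated diseases are evaluated — the
`min_positives` predicate (default 80, matching databases with hundreds
of miRNAs per common disease) or the `most_annotated_diseases(A, n=15)`
helper at synthetic scale — because a disease whose few "positives" are
mostly label noise measures annotation noise, not ranking skill. Diseases
with no held-out positives in any fold are excluded with a warning.

When `M` is itself derived from associations (best-match-average
functional similarity), `similarity_source="functional"` recomputes it
from the training fold only, avoiding test-label leakage; the default
uses the supplied `M` unchanged, which also reproduces the naive variant.

Scorer comparison uses a two-sided paired t-test on per-disease metric
differences (n-1 df); a zero-variance difference vector returns p = 1
when the mean difference is 0 and the degenerate limit p = 0 (with a
warning) otherwise.

## Synthetic data generator

`generate(SyntheticConfig(...))` emulates the structure the model
assumes, so every code path is testable without any database download:

- each miRNA gets one family and one cluster; miRNA latent factors are
  `0.7 * family_prototype + 0.3 * cluster_prototype + |N(0, 0.05)|`, with
  prototypes drawn `Dirichlet(0.3)` (sparse loadings), so family and
  cluster membership genuinely predict association structure and the a2
  term has signal to exploit;
- disease factors are `Dirichlet(0.3)` rows; `truth = P Q^T` rescaled to
  `[0, 1]`; `A` marks the top `density` fraction of cells positive;
- label noise: each positive is dropped with probability `flip_prob` and
  never-positive cells are switched on at rate
  `flip_prob * density / (1 - density)`, so `flip_prob` is the corruption
  rate of the positive class while the expected density stays on target;
- `M`, `D` are cosine similarities of the factor rows plus symmetric
  `N(0, noise_sd)` noise, truncated at 0, unit diagonal (`D` additionally
  clipped to 1).

Defaults (`n_mirna=200, n_disease=40, n_family=20, n_cluster=30, rank=6,
density=0.08, noise_sd=0.1, flip_prob=0.02`) define the standard study
condition used by the recovery experiment. What the generator does *not*
emulate: the long-tailed degree distributions of curated association
databases, block-structured disease ontology similarity, multi-family
miRNAs, and annotation biases — so passing recovery tests demonstrate
correct mechanics and sensitivity to planted signal, not real-data
performance.

## Known limitations

- The solver finds local optima; different seeds give different factor
  sets (scores are typically stable, factors are not identifiable).
- Absolute-epsilon stopping is scale-dependent; use the relative mode for
  large or rescaled inputs.
- Disease similarity is consumed as a precomputed matrix; building it
  from ontology term graphs or phenotype data is out of scope.
- A disease with no training positives receives near-uniform low scores;
  the model cannot rank for entirely novel diseases.
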