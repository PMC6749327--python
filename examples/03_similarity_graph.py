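"""Build miRNA functional similarity and the neighbour graph from scratch.

Starting from a tiny hand-written association table and a disease
similarity matrix, computes best-match-average miRNA similarity, the
kNN graph and its Laplacian - the three ingredients of the model's
smoothness penalty.
"""

import numpy as np

from mdapred import (AssociationMatrix, SimilarityMatrix,
                     build_neighbor_graph, graph_laplacian,
                     mirna_functional_similarity)

# three miRNAs, three diseases; mir-a and mir-b share disease d1
A = AssociationMatrix([[1, 1, 0], [0, 1, 0], [0, 0, 1]],
                      ["mir-a", "mir-b", "mir-c"], ["d0", "d1", "d2"])
D = SimilarityMatrix([[1.0, 0.4, 0.1], [0.4, 1.0, 0.2], [0.1, 0.2, 1.0]],
                     ["d0", "d1", "d2"], "disease")

M = mirna_functional_similarity(A, D)
print("miRNA functional similarity (best-match average):")
print(np.round(M.values, 3))
# mir-a/mir-b share d1 -> high similarity; mir-c's disease set is
# disjoint with weak cross-similarity -> low scores

G = build_neighbor_graph(M, k=1, symmetrize=True)
print("\nk=1 neighbour graph (symmetrized):")
print(G.S.astype(int))

lap = graph_laplacian(G)
print("\nLaplacian L = W - S (row sums are zero for a symmetric graph):")
print(lap.L.astype(int))
print("\nquadratic form Tr(U^T L U) penalises score differences between "
      "linked miRNAs")
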