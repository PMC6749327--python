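"""Domain types, validation and TSV readers/writers.

The canonical on-disk format for every matrix is a dense tab-separated
table with a header row and an index column (UTF-8).  Association data may
alternatively be given as a two-column edge list, and miRNA node
attributes as a three-column annotation table
``(mirna_id, attribute_id, attribute_type)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("mdapred")

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "NodeAttributeMatrix",
    "Hyperparameters",
    "Dataset",
    "read_association_matrix",
    "read_similarity_matrix",
    "read_attribute_matrix",
    "read_annotation_table",
    "build_attribute_matrix",
    "write_association_matrix",
    "write_similarity_matrix",
    "write_attribute_matrix",
    "align_universe",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what} identifiers: {sorted(set(dups))}")


def _check_binary(values: np.ndarray, rows: Sequence[str], cols: Sequence[str],
                  what: str) -> None:
    bad = ~((values == 0) | (values == 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{what} must be binary; cell ({rows[i]}, {cols[j]}) = {values[i, j]!r}"
        )


@dataclass
class AssociationMatrix:
    """Binary miRNA x disease association matrix A.

    ``values[i, j] == 1`` records a known association between miRNA
    ``mirna_ids[i]`` and disease ``disease_ids[j]``; 0 means unobserved.
    """

    values: np.ndarray
    mirna_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mirna_ids = list(self.mirna_ids)
        self.disease_ids = list(self.disease_ids)
        if self.values.ndim != 2:
            raise ValueError("association matrix must be 2-D")
        if self.values.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.mirna_ids)} miRNA / {len(self.disease_ids)} disease ids"
            )
        _check_unique(self.mirna_ids, "miRNA")
        _check_unique(self.disease_ids, "disease")
        _check_binary(self.values, self.mirna_ids, self.disease_ids,
                      "association matrix")

    @property
    def n_mirna(self) -> int:
        return self.values.shape[0]

    @property
    def n_disease(self) -> int:
        return self.values.shape[1]

    @property
    def density(self) -> float:
        """Fraction of observed positives, (# of 1s) / (Nm * Nd)."""
        return float(self.values.sum() / self.values.size) if self.values.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.mirna_ids,
                            columns=self.disease_ids)


@dataclass
class SimilarityMatrix:
    """Nonnegative square similarity matrix over miRNAs (M) or diseases (D)."""

    values: np.ndarray
    ids: list[str]
    kind: str  # "mirna" | "disease"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = list(self.ids)
        if self.kind not in ("mirna", "disease"):
            raise ValueError(f"kind must be 'mirna' or 'disease', got {self.kind!r}")
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"similarity matrix must be square over {n} ids, got shape "
                f"{self.values.shape}"
            )
        _check_unique(self.ids, self.kind)
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative similarity at ({self.ids[i]}, {self.ids[j]}): "
                f"{self.values[i, j]}"
            )
        if self.kind == "disease" and (self.values > 1).any():
            i, j = np.argwhere(self.values > 1)[0]
            raise ValueError(
                f"disease similarity must lie in [0, 1]; "
                f"({self.ids[i]}, {self.ids[j]}) = {self.values[i, j]}"
            )
    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class NodeAttributeMatrix:
    """Binary miRNA x (family + cluster) membership matrix C.

    Family columns precede cluster columns.  Rows may be all zero: a miRNA
    that belongs to no annotated family or cluster simply contributes a
    zero feature vector.
    """

    values: np.ndarray
    mirna_ids: list[str]
    family_ids: list[str]
    cluster_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mirna_ids = list(self.mirna_ids)
        self.family_ids = list(self.family_ids)
        self.cluster_ids = list(self.cluster_ids)
        shape = (len(self.mirna_ids), len(self.family_ids) + len(self.cluster_ids))
        if self.values.shape != shape:
            raise ValueError(
                f"attribute matrix shape {self.values.shape} does not match "
                f"expected {shape}"
            )
        _check_unique(self.mirna_ids, "miRNA")
        _check_unique(self.family_ids + self.cluster_ids, "attribute")
        cols = self.family_ids + self.cluster_ids
        _check_binary(self.values, self.mirna_ids, cols, "attribute matrix")

    @property
    def n_family(self) -> int:
        return len(self.family_ids)

    @property
    def n_cluster(self) -> int:
        return len(self.cluster_ids)

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.mirna_ids,
                            columns=self.family_ids + self.cluster_ids)


@dataclass
class Hyperparameters:
    """Model hyperparameters.

    alpha1..alpha4 weight the similarity-projection, attribute-projection,
    graph-smoothness and l1-sparsity terms of the objective; c is the
    shared latent dimension; k_neighbors the miRNA kNN graph size.
    Optimisation stops when the objective changes by less than ``epsilon``
    between two full update cycles, or after ``max_iter`` cycles.
    """

    alpha1: float = 0.1
    alpha2: float = 0.1
    alpha3: float = 0.1
    alpha4: float = 0.1
    c: int = 15
    k_neighbors: int = 5
    epsilon: float = 1e-6
    max_iter: int = 100
    seed: int = 0
    init_scheme: str = "warm_start_from_A"  # or "uniform_random"
    symmetrize_neighbors: bool = True
    convergence: str = "absolute"  # or "relative"

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "alpha3", "alpha4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.c < 1:
            raise ValueError("latent dimension c must be a positive integer")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be a positive integer")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")
        if self.init_scheme not in ("warm_start_from_A", "uniform_random"):
            raise ValueError(f"unknown init_scheme {self.init_scheme!r}")
        if self.convergence not in ("absolute", "relative"):
            raise ValueError(f"unknown convergence mode {self.convergence!r}")

    def validate_dims(self, n_mirna: int, n_disease: int, n_attributes: int) -> None:
        """Check dimension-dependent invariants against a dataset."""
        bounds = [n_mirna, n_disease]
        if n_attributes > 0:  # attribute term dropped entirely when C has no columns
            bounds.append(n_attributes)
        if self.c >= min(bounds):
            raise ValueError(
                f"latent dimension c={self.c} must be < min{tuple(bounds)}"
            )
        if self.k_neighbors >= n_mirna:
            raise ValueError(
                f"k_neighbors={self.k_neighbors} must be < number of miRNAs "
                f"({n_mirna})"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Hyperparameters":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


@dataclass
class Dataset:
    """Aligned model inputs: associations A, similarities M and D, attributes C."""

    A: AssociationMatrix
    M: SimilarityMatrix
    D: SimilarityMatrix
    C: NodeAttributeMatrix

    def __post_init__(self) -> None:
        if self.M.ids != self.A.mirna_ids:
            raise ValueError("miRNA similarity ids differ from association rows; "
                             "run align_universe first")
        if self.D.ids != self.A.disease_ids:
            raise ValueError("disease similarity ids differ from association "
                             "columns; run align_universe first")
        if self.C.mirna_ids != self.A.mirna_ids:
            raise ValueError("attribute matrix rows differ from association rows; "
                             "run align_universe first")

    @classmethod
    def from_arrays(cls, A, M, D, C=None) -> "Dataset":
        """Build a dataset from bare arrays with generated identifiers."""
        A = np.asarray(A, dtype=float)
        nm, nd = A.shape
        mirnas = [f"m{i}" for i in range(nm)]
        diseases = [f"d{j}" for j in range(nd)]
        if C is None:
            C = np.zeros((nm, 0))
        C = np.asarray(C, dtype=float)
        return cls(
            A=AssociationMatrix(A, mirnas, diseases),
            M=SimilarityMatrix(np.asarray(M, dtype=float), mirnas, "mirna"),
            D=SimilarityMatrix(np.asarray(D, dtype=float), diseases, "disease"),
            C=NodeAttributeMatrix(C, mirnas,
                                  [f"fam{k}" for k in range(C.shape[1])], []),
        )


# ---------------------------------------------------------------------------
# readers


def _read_dense(path: str | Path) -> pd.DataFrame:
    # round_trip parser keeps written floats bit-exact
    return pd.read_csv(path, sep="\t", index_col=0,
                       float_precision="round_trip")


def read_association_matrix(path: str | Path,
                            format: str = "dense_tsv") -> AssociationMatrix:
    """Read an association matrix from a dense TSV or a two-column edge list.

    Dense input uses header order; edge lists use first-appearance order of
    identifiers.  Duplicate edges are deduplicated with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "dense_tsv":
        frame = _read_dense(path)
        am = AssociationMatrix(frame.to_numpy(dtype=float),
                               [str(i) for i in frame.index],
                               [str(c) for c in frame.columns])
    elif format == "edge_list":
        edges = pd.read_csv(path, sep="\t", header=None, dtype=str,
                            usecols=[0, 1], comment="#")
        pairs = list(edges.itertuples(index=False, name=None))
        seen: set[tuple[str, str]] = set()
        mirnas: list[str] = []
        diseases: list[str] = []
        uniq: list[tuple[str, str]] = []
        n_dup = 0
        for m, d in pairs:
            if (m, d) in seen:
                n_dup += 1
                continue
            seen.add((m, d))
            uniq.append((m, d))
            if m not in mirnas:
                mirnas.append(m)
            if d not in diseases:
                diseases.append(d)
        if n_dup:
            log.warning("edge list %s: %d duplicate edge(s) deduplicated",
                        path, n_dup)
        values = np.zeros((len(mirnas), len(diseases)))
        mi = {m: i for i, m in enumerate(mirnas)}
        di = {d: j for j, d in enumerate(diseases)}
        for m, d in uniq:
            values[mi[m], di[d]] = 1.0
        am = AssociationMatrix(values, mirnas, diseases)
    else:
        raise ValueError(f"unknown format {format!r}")
    log.info("loaded association matrix %s: %d miRNAs x %d diseases, "
             "density %.4f", path, am.n_mirna, am.n_disease, am.density)
    return am


def read_similarity_matrix(path: str | Path, kind: str) -> SimilarityMatrix:
    """Read and validate a dense similarity TSV with matching header/index."""
    frame = _read_dense(path)
    rows = [str(i) for i in frame.index]
    cols = [str(c) for c in frame.columns]
    if rows != cols:
        raise ValueError(
            f"similarity table {path}: header labels differ from index labels"
        )
    sm = SimilarityMatrix(frame.to_numpy(dtype=float), rows, kind)
    # self-similarity dominance is expected of curated inputs but advisory
    if sm.n and (sm.values.diagonal() < sm.values.max(axis=1) - 1e-12).any():
        log.warning("%s similarity %s: some diagonal entries are not the row "
                    "maximum (self-similarity not dominant)", kind, path)
    return sm


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read a (mirna_id, attribute_id, attribute_type) annotation TSV."""
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#",
                        names=["mirna_id", "attribute_id", "attribute_type"])
    return frame


def build_attribute_matrix(annotations, mirna_ids: Sequence[str]) -> NodeAttributeMatrix:
    """Build the binary family/cluster matrix C from an annotation table.

    ``annotations`` is a DataFrame with columns (mirna_id, attribute_id,
    attribute_type) or an iterable of such triples; attribute_type is
    ``family`` or ``cluster``.  Family columns precede cluster columns, each
    block in first-appearance order.  miRNAs without annotations get
    all-zero rows.
    """
    if isinstance(annotations, pd.DataFrame):
        triples = list(annotations.itertuples(index=False, name=None))
    else:
        triples = [tuple(t) for t in annotations]
    mirna_ids = list(mirna_ids)
    known = set(mirna_ids)
    offenders = sorted({m for m, _, _ in triples if m not in known})
    if offenders:
        raise ValueError(f"annotated miRNAs missing from mirna_ids: {offenders}")
    bad_types = sorted({t for _, _, t in triples if t not in ("family", "cluster")})
    if bad_types:
        raise ValueError(f"unknown attribute_type values: {bad_types}")
    family_ids: list[str] = []
    cluster_ids: list[str] = []
    for _, attr, typ in triples:
        target = family_ids if typ == "family" else cluster_ids
        if attr not in target:
            target.append(attr)
    values = np.zeros((len(mirna_ids), len(family_ids) + len(cluster_ids)))
    mi = {m: i for i, m in enumerate(mirna_ids)}
    fi = {f: j for j, f in enumerate(family_ids)}
    ci = {c: len(family_ids) + j for j, c in enumerate(cluster_ids)}
    for m, attr, typ in triples:
        values[mi[m], fi[attr] if typ == "family" else ci[attr]] = 1.0
    return NodeAttributeMatrix(values, mirna_ids, family_ids, cluster_ids)


def read_attribute_matrix(path: str | Path, n_family: int | None = None
                          ) -> NodeAttributeMatrix:
    """Read a dense attribute TSV.

    Family columns are those whose label starts with ``fam`` unless
    ``n_family`` gives the explicit size of the leading family block.
    """
    frame = _read_dense(path)
    cols = [str(c) for c in frame.columns]
    if n_family is None:
        n_family = sum(1 for c in cols if c.startswith("fam"))
    return NodeAttributeMatrix(frame.to_numpy(dtype=float),
                               [str(i) for i in frame.index],
                               cols[:n_family], cols[n_family:])


# ---------------------------------------------------------------------------
# writers


def _write_frame(frame: pd.DataFrame, path: str | Path) -> None:
    # %.17g guarantees bit-exact float round-trips through TSV
    frame.to_csv(path, sep="\t", float_format="%.17g")


def write_association_matrix(am: AssociationMatrix, path: str | Path) -> None:
    _write_frame(am.to_frame(), path)


def write_similarity_matrix(sm: SimilarityMatrix, path: str | Path) -> None:
    _write_frame(sm.to_frame(), path)


def write_attribute_matrix(cm: NodeAttributeMatrix, path: str | Path) -> None:
    _write_frame(cm.to_frame(), path)


# ---------------------------------------------------------------------------
# alignment


def _subset_similarity(sm: SimilarityMatrix, ids: list[str]) -> SimilarityMatrix:
    idx = [sm.ids.index(i) for i in ids]
    return SimilarityMatrix(sm.values[np.ix_(idx, idx)], ids, sm.kind)


def align_universe(A: AssociationMatrix, M: SimilarityMatrix,
                   D: SimilarityMatrix,
                   C: NodeAttributeMatrix | None = None) -> Dataset:
    """Intersect and reorder all inputs onto a shared identifier universe.

    The miRNA order is A's row order restricted to miRNAs present in M
    (and in C when given); the disease order is A's column order restricted
    to diseases present in D.  Errors on an empty intersection.
    """
    m_ids = [m for m in A.mirna_ids if m in set(M.ids)]
    if C is not None:
        c_set = set(C.mirna_ids)
        m_ids = [m for m in m_ids if m in c_set]
    d_ids = [d for d in A.disease_ids if d in set(D.ids)]
    if not m_ids:
        raise ValueError("no miRNAs shared between association, similarity "
                         "and attribute inputs")
    if not d_ids:
        raise ValueError("no diseases shared between association and disease "
                         "similarity inputs")
    ri = [A.mirna_ids.index(m) for m in m_ids]
    cj = [A.disease_ids.index(d) for d in d_ids]
    A2 = AssociationMatrix(A.values[np.ix_(ri, cj)], m_ids, d_ids)
    M2 = _subset_similarity(M, m_ids)
    D2 = _subset_similarity(D, d_ids)
    if C is None:
        C2 = NodeAttributeMatrix(np.zeros((len(m_ids), 0)), m_ids, [], [])
    else:
        idx = [C.mirna_ids.index(m) for m in m_ids]
        C2 = NodeAttributeMatrix(C.values[idx], m_ids, C.family_ids,
                                 C.cluster_ids)
    return Dataset(A=A2, M=M2, D=D2, C=C2)
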