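"""Seeded generator of synthetic association/similarity/attribute fixtures.

Emulates the statistical structure the model assumes: a planted low-rank
bipartite association matrix whose miRNA factors are organised by family
and cluster membership (so the node-attribute matrix is genuinely
predictive), similarity matrices consistent with those factors, and
one-hot family/cluster attribute rows.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .io import (AssociationMatrix, Dataset, NodeAttributeMatrix,
                 SimilarityMatrix, write_association_matrix,
                 write_attribute_matrix, write_similarity_matrix)

__all__ = ["SyntheticConfig", "SyntheticData", "generate", "write_fixture_dir"]

# internal generator constants (see docs/methods.md): prototype sharpness,
# family/cluster mixing weights and latent factor noise
_PROTO_ALPHA = 0.3
_FAMILY_WEIGHT = 0.7
_CLUSTER_WEIGHT = 0.3
_FACTOR_NOISE_SD = 0.05


@dataclass
class SyntheticConfig:
    """Generation parameters; defaults are the standard study condition."""

    n_mirna: int = 200
    n_disease: int = 40
    n_family: int = 20
    n_cluster: int = 30
    rank: int = 6
    density: float = 0.08
    noise_sd: float = 0.1
    flip_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mirna", "n_disease", "n_family", "n_cluster", "rank"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.rank >= min(self.n_mirna, self.n_disease):
            raise ValueError("rank must be < min(n_mirna, n_disease)")
        if not 0.0 < self.density < 1.0:
            raise ValueError("density must lie strictly between 0 and 1")
        if not 0.0 <= self.flip_prob < 0.5:
            raise ValueError("flip_prob must lie in [0, 0.5)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_family < self.rank:
            raise ValueError(
                "degenerate config: n_family must be >= rank so that family "
                "prototypes can span the planted latent space")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class SyntheticData:
    A: AssociationMatrix
    M: SimilarityMatrix
    D: SimilarityMatrix
    C: NodeAttributeMatrix
    truth: np.ndarray  # full planted probability matrix in [0, 1]
    config: SyntheticConfig

    def dataset(self) -> Dataset:
        return Dataset(A=self.A, M=self.M, D=self.D, C=self.C)


def _cosine(rows: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(rows, axis=1)
    norms = np.where(norms > 0, norms, 1.0)
    return (rows / norms[:, None]) @ (rows / norms[:, None]).T


def _noisy_similarity(base: np.ndarray, noise_sd: float,
                      rng: np.random.Generator, clip_high: bool) -> np.ndarray:
    n = base.shape[0]
    noise = rng.normal(0.0, noise_sd, size=(n, n))
    noise = np.triu(noise, 1)
    sim = base + noise + noise.T
    sim = np.clip(sim, 0.0, 1.0 if clip_high else None)
    np.fill_diagonal(sim, 1.0)
    return sim


def generate(config: SyntheticConfig) -> SyntheticData:
    """Draw one synthetic dataset.

    MiRNA latent factors mix a shared family prototype, a shared cluster
    prototype and small nonnegative noise, so miRNAs of one family (or
    cluster) have correlated association profiles.  truth = P Q^T rescaled
    to [0, 1]; A marks the ``density`` fraction of cells with the largest
    truth values as positive, then applies density-balanced label noise:
    each positive is dropped with probability ``flip_prob`` and never-
    positive cells are flipped on at the rate that keeps the expected
    density at target.  M and D are cosine similarities of the miRNA and
    disease factors with symmetric Gaussian perturbation (sd ``noise_sd``),
    truncated at 0 and given a unit diagonal.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    fam = rng.integers(0, cfg.n_family, size=cfg.n_mirna)
    clu = rng.integers(0, cfg.n_cluster, size=cfg.n_mirna)
    fam_proto = rng.dirichlet(np.full(cfg.rank, _PROTO_ALPHA), size=cfg.n_family)
    clu_proto = rng.dirichlet(np.full(cfg.rank, _PROTO_ALPHA), size=cfg.n_cluster)
    P = (_FAMILY_WEIGHT * fam_proto[fam] + _CLUSTER_WEIGHT * clu_proto[clu]
         + np.abs(rng.normal(0.0, _FACTOR_NOISE_SD,
                             size=(cfg.n_mirna, cfg.rank))))
    Q = rng.dirichlet(np.full(cfg.rank, _PROTO_ALPHA), size=cfg.n_disease)
    truth = P @ Q.T
    truth = truth / truth.max()

    n_cells = truth.size
    n_pos = max(1, int(round(cfg.density * n_cells)))
    flat = truth.ravel()
    top = np.argsort(-flat, kind="stable")[:n_pos]
    A = np.zeros(n_cells)
    A[top] = 1.0
    if cfg.flip_prob > 0:
        pos_idx = np.flatnonzero(A == 1.0)
        neg_idx = np.flatnonzero(A == 0.0)
        drop = rng.uniform(size=pos_idx.size) < cfg.flip_prob
        on_rate = cfg.flip_prob * cfg.density / (1.0 - cfg.density)
        add = rng.uniform(size=neg_idx.size) < on_rate
        A[pos_idx[drop]] = 0.0
        A[neg_idx[add]] = 1.0
    A = A.reshape(truth.shape)

    M = _noisy_similarity(_cosine(P), cfg.noise_sd, rng, clip_high=False)
    D = _noisy_similarity(_cosine(Q), cfg.noise_sd, rng, clip_high=True)

    C = np.zeros((cfg.n_mirna, cfg.n_family + cfg.n_cluster))
    C[np.arange(cfg.n_mirna), fam] = 1.0
    C[np.arange(cfg.n_mirna), cfg.n_family + clu] = 1.0

    mirnas = [f"mir-{i:04d}" for i in range(cfg.n_mirna)]
    diseases = [f"disease-{j:03d}" for j in range(cfg.n_disease)]
    families = [f"fam-{k:03d}" for k in range(cfg.n_family)]
    clusters = [f"clu-{k:03d}" for k in range(cfg.n_cluster)]
    return SyntheticData(
        A=AssociationMatrix(A, mirnas, diseases),
        M=SimilarityMatrix(M, mirnas, "mirna"),
        D=SimilarityMatrix(D, diseases, "disease"),
        C=NodeAttributeMatrix(C, mirnas, families, clusters),
        truth=truth,
        config=cfg,
    )


def write_fixture_dir(data: SyntheticData, outdir) -> None:
    """Write A/M/D/C/truth as TSV plus a manifest recording the config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_association_matrix(data.A, outdir / "A.tsv")
    write_similarity_matrix(data.M, outdir / "M.tsv")
    write_similarity_matrix(data.D, outdir / "D.tsv")
    write_attribute_matrix(data.C, outdir / "C.tsv")
    np.savetxt(outdir / "truth.tsv", data.truth, delimiter="\t")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(asdict(data.config), fh, indent=2)
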