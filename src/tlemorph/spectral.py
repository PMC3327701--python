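"""Spectral features from pairwise subject similarity.

For each selected structure, subjects' z-scored volumes define a complete
weighted graph with Gaussian ("heat kernel") similarity

    W_ij = exp(-(z_i - z_j)^2 / c),    c = 2 by default.

Eigenvectors of the graph Laplacian of W embed the subjects; taking the k
eigenvectors of the smallest eigenvalues per structure and concatenating
across the D selected structures yields an N x kD feature matrix to which a
linear classifier is applied.

By default the embedding is transductive — computed over all subjects in an
experiment, training and test together, mirroring per-cohort construction of
the Laplacians. A train-only mode with Nystrom out-of-sample extension is
available for honest generalization estimates (see the classification
module).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .selection import StructureRanking
from .volumetry import CohortTable

__all__ = [
    "zscore",
    "similarity_matrix",
    "graph_laplacian",
    "spectral_embed",
    "nystrom_embedding",
    "build_feature_matrix",
    "SpectralFeatures",
]

VARIANTS = ("unnormalized", "symmetric", "random_walk")


def zscore(values, name: str | None = None) -> np.ndarray:
    """Population z-scores (divisor N). Errors on constant input."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D array of at least two values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    sd = x.std()
    if sd == 0:
        label = f" for structure {name!r}" if name else ""
        raise ValueError(f"zero standard deviation{label}: cannot z-score")
    return (x - x.mean()) / sd


def similarity_matrix(z, c: float = 2.0) -> np.ndarray:
    """Gaussian similarity W_ij = exp(-(z_i - z_j)^2 / c); diagonal 1."""
    if c <= 0:
        raise ValueError("similarity constant c must be positive")
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z-scores must be finite")
    d2 = (z[:, None] - z[None, :]) ** 2
    return np.exp(-d2 / c)


def graph_laplacian(W, variant: str = "unnormalized") -> np.ndarray:
    """Graph Laplacian of a symmetric non-negative weight matrix.

    unnormalized: L = Deg - W; symmetric: I - Deg^(-1/2) W Deg^(-1/2);
    random_walk: I - Deg^(-1) W (not symmetric — embed via the generalized
    problem, see :func:`build_feature_matrix`).
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("W must be symmetric")
    if W.min() < 0:
        raise ValueError("W must be non-negative")
    deg = W.sum(axis=1)
    if variant == "unnormalized":
        return np.diag(deg) - W
    if variant == "symmetric":
        with np.errstate(divide="ignore"):
            dinv = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
        return np.eye(len(W)) - dinv[:, None] * W * dinv[None, :]
    if variant == "random_walk":
        with np.errstate(divide="ignore"):
            dinv = np.where(deg > 0, 1.0 / deg, 0.0)
        return np.eye(len(W)) - dinv[:, None] * W
    raise ValueError(f"unknown Laplacian variant {variant!r}")


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude entry positive.

    np.argmax takes the first maximum, which breaks magnitude ties by
    ascending entry index.
    """
    V = V.copy()
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return V


def spectral_embed(L, k: int) -> np.ndarray:
    """Unit-norm eigenvectors of the k smallest eigenvalues, sign-fixed."""
    L = np.asarray(L, dtype=float)
    n = L.shape[0]
    if k >= n:
        raise ValueError(f"k must be < number of subjects ({k} >= {n})")
    if not np.allclose(L, L.T, atol=1e-8):
        raise ValueError("L must be symmetric")
    _, V = linalg.eigh(L, subset_by_index=(0, k - 1))
    V = V / np.linalg.norm(V, axis=0, keepdims=True)
    return _fix_signs(V)


def _embed_generalized(L: np.ndarray, B: np.ndarray, k: int) -> np.ndarray:
    # random-walk eigenvectors via the generalized symmetric problem L v = λ B v
    _, V = linalg.eigh(L, B, subset_by_index=(0, k - 1))
    V = V / np.linalg.norm(V, axis=0, keepdims=True)
    return _fix_signs(V)


def nystrom_embedding(
    z_train: np.ndarray, z_all: np.ndarray, k: int, c: float = 2.0
) -> np.ndarray:
    """Out-of-sample extension of the unnormalized-Laplacian embedding.

    Eigenpairs (lambda, v) are computed on the training subjects; each
    subject x (training or not) is embedded via the eigen-identity of
    L = Deg - W:

        v(x) = sum_j w(x, j) v_j / (d(x) - lambda)

    which reproduces v exactly at training points with distinct degrees and
    extends it smoothly elsewhere. Columns are renormalized and sign-fixed.
    """
    z_train = np.asarray(z_train, dtype=float)
    z_all = np.asarray(z_all, dtype=float)
    if k >= len(z_train):
        raise ValueError("k must be smaller than the training set")
    W = similarity_matrix(z_train, c)
    L = graph_laplacian(W, "unnormalized")
    lam, V = linalg.eigh(L, subset_by_index=(0, k - 1))
    Wx = np.exp(-((z_all[:, None] - z_train[None, :]) ** 2) / c)
    dx = Wx.sum(axis=1)
    out = np.empty((len(z_all), k))
    for j in range(k):
        denom = dx - lam[j]
        # guard near-singular denominators (e.g. the constant eigenvector of
        # an isolated degree); fall back to the mean training value there
        safe = np.abs(denom) > 1e-9
        vals = np.full(len(z_all), float(V[:, j].mean()))
        vals[safe] = (Wx[safe] @ V[:, j]) / denom[safe]
        out[:, j] = vals
    norms = np.linalg.norm(out, axis=0, keepdims=True)
    norms[norms == 0] = 1.0
    return _fix_signs(out / norms)


@dataclass(frozen=True)
class SpectralFeatures:
    """N x kD spectral feature matrix, structure-major, eigenvector-minor."""

    structures: tuple[str, ...]
    k: int
    c: float
    laplacian_variant: str
    matrix: np.ndarray
    subject_ids: tuple[str, ...]

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(
            f"{s}.ev{j + 1}" for s in self.structures for j in range(self.k)
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=list(self.column_names))
        df.insert(0, "subject_id", list(self.subject_ids))
        return df


def build_feature_matrix(
    cohort: CohortTable,
    selected,
    k: int = 2,
    c: float = 2.0,
    variant: str = "unnormalized",
    skip_trivial: bool = False,
) -> SpectralFeatures:
    """Per-structure z-score -> similarity -> Laplacian -> embedding, concatenated.

    ``selected`` is a :class:`StructureRanking` (its selected prefix is used)
    or an explicit sequence of structure names. With ``skip_trivial`` the
    near-constant leading eigenvector of each connected similarity graph is
    dropped and eigenvectors 2..k+1 are used instead.
    """
    if not cohort.normalized:
        raise ValueError("cohort must be ICV-normalized")
    if variant not in VARIANTS:
        raise ValueError(f"unknown Laplacian variant {variant!r}")
    if isinstance(selected, StructureRanking):
        names = selected.selected
    else:
        names = tuple(selected)
    if not names:
        raise ValueError("no structures selected")
    n = len(cohort)
    n_eig = k + 1 if skip_trivial else k
    if n_eig >= n:
        raise ValueError(f"need more subjects than eigenvectors ({n_eig} >= {n})")
    blocks = []
    for name in names:
        z = zscore(cohort.data[name].to_numpy(dtype=float), name=name)
        W = similarity_matrix(z, c)
        if variant == "random_walk":
            L = graph_laplacian(W, "unnormalized")
            V = _embed_generalized(L, np.diag(W.sum(axis=1)), n_eig)
        else:
            V = spectral_embed(graph_laplacian(W, variant), n_eig)
        blocks.append(V[:, 1:] if skip_trivial else V)
    matrix = np.hstack(blocks)
    return SpectralFeatures(
        structures=names,
        k=k,
        c=c,
        laplacian_variant=variant,
        matrix=matrix,
        subject_ids=tuple(cohort.data["subject_id"].astype(str)),
    )
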