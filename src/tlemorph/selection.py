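"""Univariate structure selection by a kernel class-separability criterion.

Each structure's ICV-normalized volume is treated as a scalar feature. For a
two-class labelling, the criterion J is the squared distance between the two
class means in the kernel-induced feature space, divided by the summed
within-class scatter in that space:

    between = A + B - 2C,   A/B = mean kernel value over same-class pairs,
                            C   = mean kernel value over cross-class pairs
    within  = sum over classes of (mean k(x_i, x_i) - mean same-class kernel)
    J       = between / (within + epsilon)

With a linear kernel this reduces exactly to the classical Fisher ratio
(difference of class means squared over summed within-class variances, biased
variance convention), which serves as an independent oracle in the tests.
Best Individual N (BIN) applies J to each structure independently and keeps
the top D.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .volumetry import CohortTable

__all__ = [
    "SeparabilityParams",
    "StructureRanking",
    "kernel_separability",
    "rank_structures_bin",
    "SeparabilityEngine",
]

#: floor for the median-heuristic bandwidth, guards near-degenerate features
_SIGMA_FLOOR = 1e-3


@dataclass(frozen=True)
class SeparabilityParams:
    """Criterion configuration.

    ``sigma=None`` selects the median heuristic: the bandwidth is the median
    pairwise absolute difference of the (z-scored) feature, floored at 1e-3,
    which makes J invariant under common affine rescaling of the feature.
    """

    kernel: str = "gaussian"
    sigma: float | None = None
    epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if self.kernel not in ("gaussian", "linear"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must be in (0, 1)")


@dataclass(frozen=True)
class StructureRanking:
    """Structures ordered by non-increasing criterion value J."""

    entries: tuple[tuple[str, float], ...]
    n_selected: int

    def __post_init__(self) -> None:
        js = [j for _, j in self.entries]
        if any(b > a + 1e-12 for a, b in zip(js, js[1:])):
            raise ValueError("ranking entries must be sorted non-increasing by J")
        if not 0 <= self.n_selected <= len(self.entries):
            raise ValueError("n_selected must be within the number of entries")

    @property
    def selected(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.entries[: self.n_selected])

    def top(self, d: int) -> tuple[str, ...]:
        if d > len(self.entries):
            raise ValueError(f"cannot take top {d} of {len(self.entries)} entries")
        return tuple(name for name, _ in self.entries[:d])

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_selected": self.n_selected,
                "entries": [{"structure": n, "J": j} for n, j in self.entries],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "StructureRanking":
        obj = json.loads(text)
        return cls(
            entries=tuple((e["structure"], float(e["J"])) for e in obj["entries"]),
            n_selected=int(obj["n_selected"]),
        )


def _median_bandwidth(x: np.ndarray) -> float:
    d = np.abs(x[:, None] - x[None, :])
    iu = np.triu_indices(len(x), k=1)
    return max(float(np.median(d[iu])), _SIGMA_FLOOR)


def _kernel_matrix(x: np.ndarray, params: SeparabilityParams) -> np.ndarray:
    if params.kernel == "linear":
        return np.outer(x, x)
    sigma = params.sigma if params.sigma is not None else _median_bandwidth(x)
    d2 = (x[:, None] - x[None, :]) ** 2
    return np.exp(-d2 / (2.0 * sigma**2))


def _j_from_kernel(
    K: np.ndarray, m1: np.ndarray, m2: np.ndarray, epsilon: float
) -> float:
    A = float(K[np.ix_(m1, m1)].mean())
    B = float(K[np.ix_(m2, m2)].mean())
    C = float(K[np.ix_(m1, m2)].mean())
    between = A + B - 2.0 * C
    diag = np.diag(K)
    within = (float(diag[m1].mean()) - A) + (float(diag[m2].mean()) - B)
    if between <= 0:
        return 0.0
    return between / (max(within, 0.0) + epsilon)


def kernel_separability(
    values, labels, params: SeparabilityParams | None = None
) -> float:
    """Class-separability criterion J >= 0 for one scalar feature.

    ``labels`` must contain exactly two classes with at least two members
    each; ``values`` must be finite.
    """
    params = params or SeparabilityParams()
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("values and labels must be 1-D and aligned")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    m1 = y == classes[0]
    m2 = ~m1
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each class needs at least two members")
    K = _kernel_matrix(x, params)
    return _j_from_kernel(K, m1, m2, params.epsilon)


def _zscore_columns(X: np.ndarray) -> np.ndarray:
    """Population z-score per column; zero-variance columns become all-zero."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    z = np.zeros_like(X)
    ok = sd > 0
    z[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
    return z


def rank_structures_bin(
    cohort: CohortTable,
    labels=None,
    params: SeparabilityParams | None = None,
    D: int | None = None,
) -> StructureRanking:
    """Best Individual N: rank all structures by J, flag the top D selected.

    Each structure column is z-scored before the criterion is applied so that
    J is comparable across structures of different absolute magnitude. Ties
    are broken by canonical catalog order. Constant (zero-variance) columns
    receive J = 0.
    """
    if not cohort.normalized:
        raise ValueError("cohort must be ICV-normalized before ranking")
    params = params or SeparabilityParams()
    y = np.asarray(labels if labels is not None else cohort.labels())
    names = cohort.structures
    if D is None:
        D = len(names)
    if not 0 < D <= len(names):
        raise ValueError(f"D must be in 1..{len(names)}, got {D}")
    Z = _zscore_columns(cohort.volume_matrix())
    js = np.array(
        [
            kernel_separability(Z[:, m], y, params) if Z[:, m].std() > 0 else 0.0
            for m in range(Z.shape[1])
        ]
    )
    order = np.argsort(-js, kind="stable")  # stable: ties keep catalog order
    entries = tuple((names[i], float(js[i])) for i in order)
    return StructureRanking(entries=entries, n_selected=D)


class SeparabilityEngine:
    """Precomputed per-structure kernel matrices for repeated subset ranking.

    Cross-validation and permutation testing rank structures many times on
    overlapping subject subsets. Kernel matrices depend only on the volumes
    (never on labels), so they are computed once over the full cohort —
    z-scores and the median-heuristic bandwidth included — and rankings for a
    subject subset are then cheap sub-matrix reductions. Labels enter only
    through the subset ranking call, so selection sees training labels only.
    """

    def __init__(self, cohort: CohortTable, params: SeparabilityParams | None = None):
        if not cohort.normalized:
            raise ValueError("cohort must be ICV-normalized")
        self.params = params or SeparabilityParams()
        self.names = cohort.structures
        Z = _zscore_columns(cohort.volume_matrix())
        n = Z.shape[0]
        M = Z.shape[1]
        self.kernels = np.empty((M, n, n))
        for m in range(M):
            self.kernels[m] = _kernel_matrix(Z[:, m], self.params)

    def criterion_values(self, subject_idx, labels_subset) -> np.ndarray:
        """J per structure, computed on the given subject subset only."""
        idx = np.asarray(subject_idx)
        y = np.asarray(labels_subset)
        if len(idx) != len(y):
            raise ValueError("subject_idx and labels_subset must align")
        classes = np.unique(y)
        if len(classes) != 2 or (y == classes[0]).sum() < 2 or (y == classes[1]).sum() < 2:
            raise ValueError("need two classes with >= 2 members each")
        K = self.kernels[np.ix_(np.arange(len(self.names)), idx, idx)]
        m1 = y == classes[0]
        m2 = ~m1
        A = K[:, m1][:, :, m1].mean(axis=(1, 2))
        B = K[:, m2][:, :, m2].mean(axis=(1, 2))
        C = K[:, m1][:, :, m2].mean(axis=(1, 2))
        between = A + B - 2.0 * C
        diag = np.diagonal(K, axis1=1, axis2=2)
        within = (diag[:, m1].mean(axis=1) - A) + (diag[:, m2].mean(axis=1) - B)
        js = np.where(
            between > 0,
            between / (np.maximum(within, 0.0) + self.params.epsilon),
            0.0,
        )
        return js

    def rank(self, subject_idx, labels_subset) -> np.ndarray:
        """Structure indices ordered by decreasing J (catalog order on ties)."""
        js = self.criterion_values(subject_idx, labels_subset)
        return np.argsort(-js, kind="stable")

    def criterion_values_loo(self, labels) -> np.ndarray:
        """J per structure for every leave-one-out training split at once.

        Row i holds the criterion values computed on all subjects except i —
        exactly ``criterion_values(all-but-i, labels[all-but-i])``, obtained
        by rank-one updates of the class pair-sums instead of re-slicing the
        kernel matrices. Labels of the held-out subject never enter row i.
        """
        y = np.asarray(labels)
        n = self.kernels.shape[1]
        if len(y) != n:
            raise ValueError("labels must cover the full cohort")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2 or counts.min() < 3:
            raise ValueError("need two classes with >= 3 members each")
        m1 = (y == classes[0]).astype(float)
        m2 = 1.0 - m1
        K = self.kernels  # (M, n, n)
        R1 = K @ m1  # (M, n): row sums over class-1 columns
        R2 = K @ m2
        diag = np.diagonal(K, axis1=1, axis2=2)  # (M, n)
        S11 = (R1 * m1).sum(axis=1)  # (M,)
        S22 = (R2 * m2).sum(axis=1)
        S12 = (R2 * m1).sum(axis=1)
        T1 = (diag * m1).sum(axis=1)
        T2 = (diag * m2).sum(axis=1)
        n1, n2 = m1.sum(), m2.sum()
        in1 = m1.astype(bool)

        # per held-out subject i, updated pair sums (vectorized over folds)
        S11i = S11[:, None] - (2.0 * R1 - diag) * m1[None, :]
        S22i = S22[:, None] - (2.0 * R2 - diag) * m2[None, :]
        S12i = S12[:, None] - np.where(in1[None, :], R2, R1)
        T1i = T1[:, None] - diag * m1[None, :]
        T2i = T2[:, None] - diag * m2[None, :]
        n1i = np.where(in1, n1 - 1, n1)
        n2i = np.where(in1, n2, n2 - 1)

        A = S11i / n1i**2
        B = S22i / n2i**2
        C = S12i / (n1i * n2i)
        between = A + B - 2.0 * C
        within = (T1i / n1i - A) + (T2i / n2i - B)
        J = np.where(
            between > 0,
            between / (np.maximum(within, 0.0) + self.params.epsilon),
            0.0,
        )
        return J.T  # (n, M)
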