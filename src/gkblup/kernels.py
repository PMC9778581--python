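"""Line-similarity kernels built from molecular marker data.

Genomic prediction treats the genetic merit of a line as a random effect
whose covariance across lines is a kernel computed from marker genotypes.
Two kernels are provided:

* the Gaussian kernel ``K(x_i, x_j) = rho ** d2_ij`` on normalized squared
  Euclidean marker distances, parameterized by a bandwidth ``rho`` in (0, 1)
  (equivalently ``exp(-gamma * d2)`` with ``gamma = -log(rho)``), and
* the VanRaden genomic relationship matrix (the "linear kernel"), the
  standard additive GBLUP covariance.

Squared distances are divided by their off-diagonal mean before entering the
Gaussian kernel, so the bandwidth acts on an O(1) quantity regardless of the
number of markers; without this, any fixed bandwidth grid degenerates as the
marker count grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MarkerMatrix",
    "DistanceMatrix",
    "KernelMatrix",
    "squared_distance_matrix",
    "gaussian_kernel",
    "linear_grm",
    "PSD_TOL",
]

#: Tolerance on the smallest eigenvalue of a kernel before it is rejected.
PSD_TOL = 1e-8


@dataclass(frozen=True)
class MarkerMatrix:
    """Genotypes for ``J`` lines at ``p`` biallelic markers.

    Parameters
    ----------
    line_ids : sequence of str
        Unique line identifiers, one per row of ``G``.
    G : ndarray of shape (J, p)
        Numeric genotype codes, per-marker coding in {0, 1, 2} or {-1, 0, 1}.
        Missing values are not allowed here; loaders impute or reject.
    """

    line_ids: tuple
    G: np.ndarray

    def __post_init__(self):
        G = np.asarray(self.G, dtype=float)
        ids = tuple(str(l) for l in self.line_ids)
        if G.ndim != 2:
            raise ValueError("marker matrix G must be 2-dimensional")
        J, p = G.shape
        if J < 2:
            raise ValueError(f"need at least 2 lines, got {J}")
        if p < 1:
            raise ValueError("need at least 1 marker")
        if len(ids) != J:
            raise ValueError(f"{len(ids)} line ids for {J} genotype rows")
        if len(set(ids)) != J:
            raise ValueError("line ids must be unique")
        if np.isnan(G).any():
            raise ValueError(
                "marker matrix contains missing genotypes; impute before "
                "constructing MarkerMatrix"
            )
        object.__setattr__(self, "G", G)
        object.__setattr__(self, "line_ids", ids)

    @property
    def n_lines(self) -> int:
        return self.G.shape[0]

    @property
    def n_markers(self) -> int:
        return self.G.shape[1]


@dataclass(frozen=True)
class DistanceMatrix:
    """Normalized squared Euclidean distances between lines.

    ``D2`` has zero diagonal and, by construction, off-diagonal mean 1; the
    positive scalar ``normalizer`` is the mean off-diagonal raw squared
    distance that was divided out.
    """

    D2: np.ndarray
    normalizer: float
    line_ids: tuple

    def __post_init__(self):
        object.__setattr__(self, "D2", np.asarray(self.D2, dtype=float))
        object.__setattr__(self, "line_ids", tuple(self.line_ids))


@dataclass(frozen=True)
class KernelMatrix:
    """A symmetric PSD line-similarity matrix.

    ``rho`` records the Gaussian bandwidth that produced ``K`` (``None`` for
    the linear genomic relationship matrix).
    """

    K: np.ndarray
    line_ids: tuple
    rho: float | None = None
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self):
        K = np.asarray(self.K, dtype=float)
        ids = tuple(str(l) for l in self.line_ids)
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "line_ids", ids)
        if self.validate:
            if K.ndim != 2 or K.shape[0] != K.shape[1]:
                raise ValueError("kernel must be square")
            if K.shape[0] != len(ids):
                raise ValueError("kernel size does not match line ids")
            if not np.allclose(K, K.T, atol=1e-10):
                raise ValueError("kernel must be symmetric")
            evals = np.linalg.eigvalsh(K)
            tol = PSD_TOL * max(1.0, float(evals[-1]))
            if evals[0] < -tol:
                raise ValueError(
                    f"kernel is not positive semidefinite: smallest "
                    f"eigenvalue {evals[0]:.3e} below tolerance {-tol:.1e}"
                )

    @property
    def n_lines(self) -> int:
        return self.K.shape[0]

    def index_of(self, lines) -> np.ndarray:
        """Positions of ``lines`` within this kernel, erroring on strangers."""
        pos = {l: i for i, l in enumerate(self.line_ids)}
        idx = []
        for l in lines:
            l = str(l)
            if l not in pos:
                raise KeyError(f"line {l!r} absent from kernel")
            idx.append(pos[l])
        return np.asarray(idx, dtype=int)

    def subset(self, lines) -> "KernelMatrix":
        """Principal submatrix for ``lines`` (stays PSD; no re-validation)."""
        idx = self.index_of(lines)
        return KernelMatrix(
            K=self.K[np.ix_(idx, idx)],
            line_ids=[self.line_ids[i] for i in idx],
            rho=self.rho,
            validate=False,
        )


def squared_distance_matrix(markers: MarkerMatrix) -> DistanceMatrix:
    """Normalized pairwise squared Euclidean distances between lines.

    Marker columns are mean-centered, raw squared distances are computed and
    then divided by their off-diagonal mean, so the result is dimensionless
    with off-diagonal mean exactly 1.

    Raises
    ------
    ValueError
        If there are fewer than 2 lines, or if all lines are identical
        (the normalizer would be zero).
    """
    G = markers.G
    J = G.shape[0]
    if J < 2:
        raise ValueError("distance normalizer undefined for fewer than 2 lines")
    Gc = G - G.mean(axis=0)
    sq = np.einsum("ij,ij->i", Gc, Gc)
    raw = sq[:, None] + sq[None, :] - 2.0 * (Gc @ Gc.T)
    raw = np.maximum(raw, 0.0)
    raw = 0.5 * (raw + raw.T)
    np.fill_diagonal(raw, 0.0)
    total = float(raw.sum())
    normalizer = total / (J * (J - 1))
    scale = float(sq.max())
    if normalizer <= max(scale, 1.0) * 1e-12:
        raise ValueError(
            "degenerate marker matrix: all lines are identical, so the mean "
            "off-diagonal squared distance is zero and no normalizer exists"
        )
    return DistanceMatrix(D2=raw / normalizer, normalizer=normalizer,
                          line_ids=markers.line_ids)


def gaussian_kernel(dist: DistanceMatrix, rho: float) -> KernelMatrix:
    """Gaussian kernel ``K_ij = rho ** D2_ij`` for bandwidth ``rho`` in (0, 1).

    Equivalent to ``exp(-gamma * D2)`` under ``rho = exp(-gamma)``. The
    diagonal is exactly 1 and, distances being Euclidean, the result is
    positive semidefinite up to round-off.
    """
    rho = float(rho)
    if not 0.0 < rho < 1.0:
        raise ValueError(f"bandwidth rho must lie in (0, 1), got {rho}")
    K = np.power(rho, dist.D2)
    np.fill_diagonal(K, 1.0)
    K = 0.5 * (K + K.T)
    return KernelMatrix(K=K, line_ids=dist.line_ids, rho=rho)


def linear_grm(markers: MarkerMatrix) -> KernelMatrix:
    """VanRaden genomic relationship matrix (the linear kernel).

    Genotypes are centered by twice the observed allele frequency and the
    cross-product is scaled by ``2 * sum(p_k * (1 - p_k))``. Row sums are zero
    by construction; the diagonal is not 1 (unlike the Gaussian kernel).
    """
    G = markers.G
    if G.min() < 0:  # {-1,0,1} coding -> shift to {0,1,2}
        G = G + 1.0
    p = G.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 1e-12:
        raise ValueError(
            "all markers are monomorphic: VanRaden scaling denominator "
            "2*sum(p(1-p)) is zero"
        )
    W = G - 2.0 * p
    K = (W @ W.T) / denom
    K = 0.5 * (K + K.T)
    return KernelMatrix(K=K, line_ids=markers.line_ids, rho=None)
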