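"""Genomic covariance kernels from marker matrices.

Two covariance functions are provided: the linear genomic relationship
matrix (GB, the VanRaden ``XX'/p`` kernel used by GBLUP) and the Gaussian
kernel (GK, ``exp(-h d²/q)``) built from squared Euclidean marker
distances normalised by a quantile ``q`` of those distances with
bandwidth ``h``.  Both produce a :class:`Kernel` — a labelled symmetric
positive semi-definite matrix — the common currency of the package.
Externally supplied relationship matrices (pedigree, dominance, ...)
enter through :func:`validate_kernel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._exceptions import DegenerateDataError, InputError, NotPSDError, NumericalError

__all__ = [
    "MarkerMatrix",
    "Kernel",
    "gb_kernel",
    "squared_distance_matrix",
    "gk_kernel",
    "validate_kernel",
]

#: relative asymmetry below which a matrix is silently symmetrised
SYMMETRY_RTOL = 1e-10
#: eigenvalues are accepted down to -PSD_RTOL * max(eigenvalue)
PSD_RTOL = 1e-8


@dataclass(frozen=True)
class MarkerMatrix:
    """Genotypes x markers matrix of biallelic marker codes (e.g. 0/1/2).

    Parameters
    ----------
    values
        Real matrix of shape ``(n_gen, p)`` with no missing entries.
    genotype_ids
        Unique identifiers for the ``n_gen`` genotypes (rows).
    marker_ids
        Identifiers for the ``p`` markers (columns).
    """

    values: np.ndarray
    genotype_ids: tuple[str, ...]
    marker_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "genotype_ids", tuple(str(g) for g in self.genotype_ids))
        object.__setattr__(self, "marker_ids", tuple(str(m) for m in self.marker_ids))
        if values.ndim != 2:
            raise InputError("marker matrix must be two-dimensional")
        n_gen, p = values.shape
        if n_gen < 2:
            raise InputError(f"need at least 2 genotypes, got {n_gen}")
        if p < 1:
            raise InputError("marker matrix has zero markers")
        if len(self.genotype_ids) != n_gen:
            raise InputError(
                f"{len(self.genotype_ids)} genotype ids for {n_gen} rows"
            )
        if len(self.marker_ids) != p:
            raise InputError(f"{len(self.marker_ids)} marker ids for {p} columns")
        if len(set(self.genotype_ids)) != n_gen:
            raise InputError("genotype ids must be unique")
        if not np.isfinite(values).all():
            raise InputError("marker matrix contains missing/non-finite entries")

    @property
    def n_genotypes(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Kernel:
    """Labelled symmetric PSD covariance matrix.

    ``structure`` is ``"dense"`` or ``"block_diagonal"``; for the latter,
    ``block_sizes`` lists the diagonal block dimensions in order and all
    entries outside those blocks are exactly zero.  Block structure is what
    lets the sampler eigen-decompose per block instead of on the full
    matrix.
    """

    values: np.ndarray
    labels: tuple[str, ...]
    structure: str = "dense"
    block_sizes: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise InputError("kernel matrix must be square")
        n = values.shape[0]
        if len(self.labels) != n:
            raise InputError(f"{len(self.labels)} labels for a {n}x{n} kernel")
        if self.structure not in ("dense", "block_diagonal"):
            raise InputError(f"unknown kernel structure {self.structure!r}")
        if not self.block_sizes:
            object.__setattr__(self, "block_sizes", (n,))
        else:
            object.__setattr__(self, "block_sizes", tuple(int(b) for b in self.block_sizes))
        if sum(self.block_sizes) != n:
            raise InputError("block sizes must sum to the kernel dimension")
        if self.structure == "dense" and len(self.block_sizes) != 1:
            raise InputError("a dense kernel has a single block")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def block_offsets(self) -> tuple[int, ...]:
        """Start index of each diagonal block."""
        return tuple(int(x) for x in np.cumsum((0,) + self.block_sizes[:-1]))

    def label_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}


def gb_kernel(X: MarkerMatrix, rescale: bool = True) -> Kernel:
    """Linear genomic relationship kernel ``XX'/p`` (GBLUP / VanRaden).

    Parameters
    ----------
    X
        Marker matrix; the kernel is computed on the supplied coding as is
        (no implicit centering — center columns beforehand if desired).
    rescale
        Divide by the mean diagonal so the average self-relationship is 1,
        which keeps kernels from different sources on a common scale.
        Default on.
    """
    G = X.values @ X.values.T / X.n_markers
    G = (G + G.T) / 2.0  # exact symmetry despite float round-off
    if rescale:
        mean_diag = float(np.mean(np.diag(G)))
        if mean_diag <= 0:
            raise DegenerateDataError(
                "cannot rescale: mean diagonal of XX'/p is not positive"
            )
        G = G / mean_diag
    return Kernel(G, X.genotype_ids, structure="dense")


def squared_distance_matrix(X: MarkerMatrix) -> np.ndarray:
    """Pairwise squared Euclidean distances ``d²_ij = Σ_k (x_ik − x_jk)²``."""
    return squareform(pdist(X.values, metric="sqeuclidean"))


def gk_kernel(
    X: MarkerMatrix, bandwidth: float = 1.0, quantile: float = 0.5
) -> Kernel:
    """Gaussian kernel ``exp(−h · d²_ij / q)``.

    ``q`` is the given quantile of the off-diagonal squared-distance values
    (upper triangle only — including the structural zeros on the diagonal
    would bias ``q`` downward), computed with linear interpolation.  The
    bandwidth ``h`` controls the rate of decay of covariance with genetic
    distance.

    Raises
    ------
    DegenerateDataError
        If the distance quantile is zero (all genotypes identical).
    InputError
        If ``bandwidth`` is not positive or ``quantile`` outside (0, 1).
    """
    if bandwidth <= 0:
        raise InputError(f"bandwidth must be positive, got {bandwidth}")
    if not 0 < quantile < 1:
        raise InputError(f"quantile must be in (0, 1), got {quantile}")
    d2_condensed = pdist(X.values, metric="sqeuclidean")
    q = float(np.quantile(d2_condensed, quantile))
    if q <= 0:
        raise DegenerateDataError(
            "distance quantile is zero — all genotypes identical at this quantile"
        )
    K = np.exp(-bandwidth * squareform(d2_condensed) / q)
    # d_ii = 0 so the diagonal is exp(0) = 1 exactly already
    return Kernel(K, X.genotype_ids, structure="dense")


def validate_kernel(
    M: np.ndarray,
    labels: Sequence[str],
    structure: str = "dense",
    block_sizes: Sequence[int] | None = None,
) -> Kernel:
    """Validate a user-supplied covariance matrix and wrap it as a Kernel.

    Checks squareness, label agreement, symmetry and positive
    semi-definiteness.  Asymmetry below ``1e-10`` relative is repaired as
    ``(M + M')/2``; larger asymmetry is an error.  The smallest eigenvalue
    must be ``≥ −1e−8 ×`` the largest.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise InputError("kernel matrix must be square")
    if len(labels) != M.shape[0]:
        raise InputError(
            f"{len(labels)} labels for a {M.shape[0]}x{M.shape[1]} matrix"
        )
    scale = float(np.max(np.abs(M))) or 1.0
    asym = float(np.max(np.abs(M - M.T)))
    if asym > SYMMETRY_RTOL * scale:
        raise NumericalError(
            f"matrix is asymmetric (relative asymmetry {asym / scale:.3g})"
        )
    M = (M + M.T) / 2.0
    w = np.linalg.eigvalsh(M)
    w_max = float(w[-1])
    if w_max < 0 or float(w[0]) < -PSD_RTOL * max(w_max, 1e-300):
        raise NotPSDError(
            f"matrix is not positive semi-definite "
            f"(eigenvalues in [{w[0]:.3g}, {w_max:.3g}])"
        )
    return Kernel(M, tuple(labels), structure=structure,
                  block_sizes=tuple(block_sizes) if block_sizes else ())
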