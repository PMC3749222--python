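"""Individual-by-individual genetic distances and Principal Coordinates
Analysis.

The default metric between two multi-locus STR haplotypes is the squared
repeat-count difference summed over loci,

    d(i, j) = sum_l (a_il - a_jl)^2,

the standard microsatellite individual distance; since it is the squared
Euclidean distance of the repeat-count vectors, the distance matrix is fed
to Gower double-centering as-is (as squared distances).  A simple mismatch
count (number of differing loci) is available as an alternative metric.

PCoA eigendecomposes B = -1/2 J D J (J the centering matrix, D the squared
distances); coordinates are eigenvectors scaled by the square root of their
eigenvalues.  Negative eigenvalues — possible for non-Euclidean inputs such
as the mismatch metric — are reported, never silently dropped, and excluded
from the explained-variance denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .profiles import StrProfile

Metric = Literal["squared", "mismatch"]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with a zero diagonal."""

    ids: tuple[str, ...]
    d: np.ndarray
    metric: str = "squared"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.ids), columns=list(self.ids))


@dataclass
class PcoaResult:
    """Sample coordinates plus the eigenvalue spectrum.

    ``pct_variance`` is computed over positive eigenvalues only and sums to
    100; ``negative_eigenvalues`` lists any negative part of the spectrum.
    """

    ids: tuple[str, ...]
    coordinates: np.ndarray          # samples x axes
    eigenvalues: np.ndarray          # all eigenvalues, descending
    pct_variance: np.ndarray         # per returned axis, %
    negative_eigenvalues: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=list(self.ids), columns=cols)


def pairwise_distances(
    profiles: Sequence[StrProfile],
    loci: Sequence[str],
    metric: Metric = "squared",
) -> DistanceMatrix:
    """Pairwise distances over the given single-copy loci.

    Every profile must carry exactly one allele at each locus; fractional
    micro-variant alleles are used numerically (subtraction is well defined
    for decimal repeat counts).
    """
    values = np.empty((len(profiles), len(loci)), dtype=float)
    for i, p in enumerate(profiles):
        for j, locus in enumerate(loci):
            if not p.has_locus(locus):
                raise ValueError(f"{p.sample_id}: missing locus {locus}")
            values[i, j] = float(p.single_allele(locus))
    diff = values[:, None, :] - values[None, :, :]
    if metric == "squared":
        d = np.sum(diff**2, axis=-1)
    elif metric == "mismatch":
        d = np.sum(diff != 0, axis=-1).astype(float)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    ids = tuple(p.sample_id for p in profiles)
    return DistanceMatrix(ids=ids, d=d, metric=metric)


def pcoa(dm: DistanceMatrix, axes: int = 2) -> PcoaResult:
    """Classical (metric) MDS of a squared-distance matrix.

    Deterministic up to per-axis sign.  An all-zero matrix yields all-zero
    coordinates with a warning.
    """
    if axes < 1:
        raise ValueError("axes must be >= 1")
    D = dm.d
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(1e-10, 1e-12 * max(abs(eigval.max(initial=0.0)), 1.0))
    positive = eigval > tol
    if not positive.any():
        import warnings

        warnings.warn("degenerate distance matrix: all coordinates are zero")
        k = min(axes, n)
        return PcoaResult(
            ids=dm.ids,
            coordinates=np.zeros((n, k)),
            eigenvalues=eigval,
            pct_variance=np.zeros(k),
            negative_eigenvalues=eigval[eigval < -tol],
        )

    k = min(axes, int(positive.sum()))
    lam = eigval[:k]
    coords = eigvec[:, :k] * np.sqrt(lam)
    pct = 100.0 * lam / eigval[positive].sum()
    return PcoaResult(
        ids=dm.ids,
        coordinates=coords,
        eigenvalues=eigval,
        pct_variance=pct,
        negative_eigenvalues=eigval[eigval < -tol],
    )


def reconstructed_distances(result: PcoaResult, n_axes: int | None = None) -> np.ndarray:
    """Squared Euclidean distances implied by the PCoA coordinates."""
    X = result.coordinates if n_axes is None else result.coordinates[:, :n_axes]
    diff = X[:, None, :] - X[None, :, :]
    return np.sum(diff**2, axis=-1)
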