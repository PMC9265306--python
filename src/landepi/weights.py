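"""Spatial neighbourhood weights W shared by Moran's I, LM tests, and the
spatial regression models.

Default scheme: k-nearest neighbours (k = 8) on unit centroids,
row-standardised; a symmetric distance band is available.  Eigenvalues of
the (standardised) matrix are cached — they bound the stationary interval
for the spatial parameters and supply the log-determinant term of the ML
estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["SpatialWeights"]


@dataclass
class SpatialWeights:
    W: np.ndarray
    scheme: str
    row_standardised: bool = True
    _eigs: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be square")
        if np.any(np.diag(W) != 0):
            raise ValueError("W must have a zero diagonal")
        self.W = W

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @classmethod
    def from_knn(cls, coords: np.ndarray, k: int = 8,
                 row_standardise: bool = True) -> "SpatialWeights":
        """Binary k-nearest-neighbour weights; distance ties broken by index."""
        coords = np.asarray(coords, dtype=float)
        n = len(coords)
        if n < 2:
            raise ValueError("need at least 2 units")
        if not 1 <= k < n:
            raise ValueError("need 1 <= k < n")
        tree = cKDTree(coords)
        # query k+1 because each point finds itself first; cKDTree breaks
        # exact-distance ties by index order, matching the stated tie rule
        _, idx = tree.query(coords, k=k + 1)
        W = np.zeros((n, n))
        for i in range(n):
            neigh = [j for j in idx[i] if j != i][:k]
            W[i, neigh] = 1.0
        out = cls(W, scheme=f"knn_{k}", row_standardised=False)
        if row_standardise:
            out = out.standardised()
        return out

    @classmethod
    def from_distance_band(cls, coords: np.ndarray, threshold: float,
                           row_standardise: bool = True) -> "SpatialWeights":
        """Symmetric binary weights: neighbours within ``threshold`` metres."""
        coords = np.asarray(coords, dtype=float)
        n = len(coords)
        d = np.hypot(coords[:, None, 0] - coords[None, :, 0],
                     coords[:, None, 1] - coords[None, :, 1])
        W = ((d > 0) & (d <= threshold)).astype(float)
        islands = np.flatnonzero(W.sum(axis=1) == 0)
        if islands.size:
            raise ValueError(f"islands (no neighbours) under distance band: "
                             f"units {islands.tolist()}")
        out = cls(W, scheme=f"distance_band_{threshold:g}", row_standardised=False)
        if row_standardise:
            out = out.standardised()
        return out

    def standardised(self) -> "SpatialWeights":
        rs = self.W.sum(axis=1, keepdims=True)
        if np.any(rs == 0):
            raise ValueError("cannot row-standardise: empty row(s)")
        return SpatialWeights(self.W / rs, scheme=self.scheme, row_standardised=True)

    @property
    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues of W (possibly complex for asymmetric schemes); cached."""
        if self._eigs is None:
            self._eigs = np.linalg.eigvals(self.W)
        return self._eigs

    @property
    def param_interval(self) -> tuple[float, float]:
        """Open stationary interval for the spatial parameter, from the real
        eigenvalues: (1/min Re(lambda), 1/max Re(lambda))."""
        re = self.eigenvalues.real
        lo = re.min()
        hi = re.max()
        if lo >= 0 or hi <= 0:
            raise ValueError("degenerate eigenvalue range for W")
        return 1.0 / lo, 1.0 / hi

    def logdet(self, param: float) -> float:
        """ln |I - param * W| via the cached eigenvalues."""
        vals = 1.0 - param * self.eigenvalues
        return float(np.sum(np.log(np.abs(vals))))

    @property
    def s0(self) -> float:
        return float(self.W.sum())

    def lag(self, y: np.ndarray) -> np.ndarray:
        return self.W @ np.asarray(y, dtype=float)
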