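"""Individual metabolic network construction by Jensen-Shannon
divergence similarity estimation (JSSE).

Each region's voxel-intensity distribution is summarized by a
Gaussian-kernel density estimate evaluated on a shared grid; for every
region pair the Jensen-Shannon divergence (log base 2, hence bounded by
1) between the two discretized PDFs measures how dissimilar the regional
metabolic distributions are, and the connection weight stored in the
individual 90 x 90 adjacency matrix is the similarity 1 - D_JS.

The JS divergence uses the mixture M = (P + Q)/2:

    D_JS(P || Q) = [D_KL(P || M) + D_KL(Q || M)] / 2

which is symmetric, finite, and zero iff P = Q.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .aal import default_region_names
from .parcellation import ROISampleSet

__all__ = [
    "DiscretePDF",
    "MetabolicNetwork",
    "silverman_bandwidth",
    "estimate_pdf",
    "kl_divergence",
    "js_divergence",
    "build_connectome",
]

#: Grid points used for each pair-specific evaluation grid.
DEFAULT_GRID_POINTS = 256

#: Grid extends this many bandwidths beyond the pooled sample range.
GRID_PAD_BANDWIDTHS = 3.0

#: Bandwidth floor for zero-variance samples (relative to the mean scale).
ZERO_VARIANCE_BANDWIDTH = 1e-6


@dataclass
class DiscretePDF:
    """A probability mass vector on a strictly increasing grid."""

    grid: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.mass = np.asarray(self.mass, dtype=np.float64)
        if self.grid.shape != self.mass.shape or self.grid.ndim != 1:
            raise ValueError("grid and mass must be 1D vectors of equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.mass < 0):
            raise ValueError("mass must be non-negative")
        total = self.mass.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass must sum to 1, got {total}")


@dataclass
class MetabolicNetwork:
    """Symmetric, zero-diagonal similarity matrix: the individual connectome."""

    weights: np.ndarray
    region_names: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        n = len(self.region_names)
        if self.weights.shape != (n, n):
            raise ValueError(
                f"weights must be {n}x{n}, got {self.weights.shape}"
            )
        if np.abs(self.weights - self.weights.T).max() > 1e-12:
            raise ValueError("weights must be symmetric")
        if np.abs(np.diag(self.weights)).max() > 0:
            raise ValueError("diagonal must be zero")
        off = self.weights[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < -1e-12 or off.max() > 1 + 1e-12):
            raise ValueError("weights must lie in [0, 1]")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def upper_triangle(self) -> np.ndarray:
        """Connection weights of the n(n-1)/2 unordered pairs, row-major."""
        iu = np.triu_indices(self.n_regions, k=1)
        return self.weights[iu]

    def to_csv(self, path: str | os.PathLike) -> None:
        pd.DataFrame(
            self.weights, index=self.region_names, columns=self.region_names
        ).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "MetabolicNetwork":
        frame = pd.read_csv(path, index_col=0)
        return cls(weights=frame.to_numpy(dtype=np.float64),
                   region_names=[str(c) for c in frame.columns])

    def to_edge_list(self) -> pd.DataFrame:
        iu = np.triu_indices(self.n_regions, k=1)
        names = np.asarray(self.region_names)
        return pd.DataFrame(
            {
                "region_i": names[iu[0]],
                "region_j": names[iu[1]],
                "weight": self.weights[iu],
            }
        )


def silverman_bandwidth(samples: np.ndarray) -> float:
    """Silverman's rule-of-thumb KDE bandwidth.

    h = 0.9 * min(sd, IQR/1.34) * n^(-1/5); degenerate (zero-spread)
    samples fall back to a small floor so the density remains well
    defined as a near-point mass.
    """
    x = np.asarray(samples, dtype=np.float64)
    n = x.size
    if n < 2:
        raise ValueError("at least 2 samples required")
    sd = float(x.std(ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    spread_candidates = [s for s in (sd, iqr / 1.34) if s > 0]
    if not spread_candidates:
        return ZERO_VARIANCE_BANDWIDTH * max(1.0, abs(float(x.mean())))
    return 0.9 * min(spread_candidates) * n ** (-0.2)


def estimate_pdf(
    samples: np.ndarray,
    grid: np.ndarray,
    bandwidth: Optional[float] = None,
) -> DiscretePDF:
    """Gaussian-kernel density of ``samples`` discretized on ``grid``.

    The evaluated density is renormalized to sum to 1, making it a
    probability mass vector on the grid (the unit the divergences
    consume). Deterministic for fixed inputs.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 2:
        raise ValueError("at least 2 samples required")
    grid = np.asarray(grid, dtype=np.float64)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    h = silverman_bandwidth(x) if bandwidth is None else float(bandwidth)
    z = (grid[None, :] - x[:, None]) / h
    density = np.exp(-0.5 * z * z).sum(axis=0)  # normalization cancels below
    total = density.sum()
    if total <= 0 or not np.isfinite(total):
        # all mass fell off the grid; put it on the nearest grid point
        density = np.zeros_like(grid)
        density[np.abs(grid - x.mean()).argmin()] = 1.0
        total = 1.0
    return DiscretePDF(grid=grid, mass=density / total)


def _check_shared_grid(P: DiscretePDF, Q: DiscretePDF) -> None:
    if P.grid.shape != Q.grid.shape or not np.array_equal(P.grid, Q.grid):
        raise ValueError("P and Q must share the same evaluation grid")


def kl_divergence(P: DiscretePDF, Q: DiscretePDF) -> float:
    """Kullback-Leibler divergence D_KL(P || Q) in bits.

    Terms with P(i) = 0 contribute nothing; any point with P(i) > 0 and
    Q(i) = 0 makes the divergence +inf (measure-theoretic convention).
    """
    _check_shared_grid(P, Q)
    p, q = P.mass, Q.mass
    support = p > 0
    if np.any(q[support] == 0):
        return float("inf")
    ps, qs = p[support], q[support]
    return float(np.sum(ps * np.log2(ps / qs)))


def js_divergence(P: DiscretePDF, Q: DiscretePDF) -> float:
    """Jensen-Shannon divergence in bits; symmetric and bounded in [0, 1]."""
    _check_shared_grid(P, Q)
    m = DiscretePDF(grid=P.grid, mass=(P.mass + Q.mass) / 2.0)
    d = 0.5 * (kl_divergence(P, m) + kl_divergence(Q, m))
    # clip tiny negative rounding; the mathematical value is in [0, 1]
    return float(min(max(d, 0.0), 1.0))


def _pair_grid(
    xi: np.ndarray, xj: np.ndarray, hi: float, hj: float, n_points: int
) -> np.ndarray:
    h = max(hi, hj)
    lo = min(xi.min(), xj.min()) - GRID_PAD_BANDWIDTHS * h
    hi_ = max(xi.max(), xj.max()) + GRID_PAD_BANDWIDTHS * h
    if hi_ <= lo:  # identical point masses
        half = max(abs(lo) * 1e-6, 1e-9)
        lo, hi_ = lo - half, hi_ + half
    return np.linspace(lo, hi_, n_points)


def build_connectome(
    roi_samples: ROISampleSet,
    grid_points: int = DEFAULT_GRID_POINTS,
    edge_weight: str = "similarity",
) -> MetabolicNetwork:
    """Build the individual JSSE metabolic network.

    For each unordered region pair the two PDFs are estimated on a
    common pair-specific grid (spanning the pooled sample range padded
    by three bandwidths) and the edge carries 1 - D_JS (``similarity``,
    default) or D_JS itself (``divergence``).
    """
    if edge_weight not in ("similarity", "divergence"):
        raise ValueError("edge_weight must be 'similarity' or 'divergence'")
    n = roi_samples.n_regions
    samples = roi_samples.samples
    bandwidths = [silverman_bandwidth(s) for s in samples]
    weights = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            grid = _pair_grid(
                samples[i], samples[j], bandwidths[i], bandwidths[j], grid_points
            )
            Pi = estimate_pdf(samples[i], grid, bandwidth=bandwidths[i])
            Pj = estimate_pdf(samples[j], grid, bandwidth=bandwidths[j])
            d = js_divergence(Pi, Pj)
            w = 1.0 - d if edge_weight == "similarity" else d
            weights[i, j] = weights[j, i] = w
    names = roi_samples.region_names or default_region_names(n)
    return MetabolicNetwork(weights=weights, region_names=list(names))
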