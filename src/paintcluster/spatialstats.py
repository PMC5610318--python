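"""Ripley's K / L(r)-r statistics with minus-sampling edge handling.

For a spatial scale r, only points at distance >= r from the ROI boundary
("interior points") serve as circle centres, so no circle leaks outside the
ROI.  With N points in the ROI, n(r) interior points and ROI area A,

    K_hat(r) = A / (n(r) * N) * sum_{i interior} sum_{j != i} I(d_ij < r)
    L(r)     = sqrt(K_hat(r) / pi)

Under complete spatial randomness E[L(r) - r] = 0 at every r; positive
values indicate clustering at scale r.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .locdata import PolygonROI


@dataclasses.dataclass
class RipleyCurve:
    """K, L and L(r)-r over an r grid for one ROI (NaN where undefined)."""

    r_values: np.ndarray  # nm
    K: np.ndarray  # nm^2
    L: np.ndarray  # nm
    L_minus_r: np.ndarray  # nm
    n_interior: np.ndarray  # interior point count per r
    area: float  # ROI area, nm^2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_nm": self.r_values,
                "K": self.K,
                "L": self.L,
                "L_minus_r": self.L_minus_r,
                "n_interior": self.n_interior,
            }
        )


def ripley_curve(points: np.ndarray, roi: PolygonROI, r_values: np.ndarray) -> RipleyCurve:
    """Minus-sampling Ripley estimate for one point pattern in one ROI.

    ``points`` outside the ROI are ignored.  Grid entries where no interior
    point exists are flagged NaN rather than raising.
    """
    r_values = np.asarray(r_values, float)
    if len(r_values) == 0 or (r_values <= 0).any() or (np.diff(r_values) <= 0).any():
        raise ValueError("r_values must be positive and strictly increasing")
    points = np.asarray(points, float)
    inside = roi.contains(points[:, 0], points[:, 1]) if len(points) else np.zeros(0, bool)
    pts = points[inside]
    N = len(pts)
    if N < 2:
        raise ValueError("Ripley estimation needs at least 2 points inside the ROI")
    area = roi.area
    edge = roi.edge_distance(pts[:, 0], pts[:, 1])  # >= 0 inside

    r_max = float(r_values[-1])
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r_max, output_type="ndarray")
    # directed pair (i -> j) contributes to scales r with d_ij < r <= edge_i
    if len(pairs):
        src = np.concatenate([pairs[:, 0], pairs[:, 1]])
        dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
        d = np.hypot(*(pts[src] - pts[dst]).T)
        lo = np.searchsorted(r_values, d, side="right")  # first grid index with r > d
        hi = np.searchsorted(r_values, edge[src], side="right")  # first index with r > edge
        ok = hi > lo  # pair visible on at least one grid scale
        delta = np.zeros(len(r_values) + 1)
        np.add.at(delta, lo[ok], 1.0)
        np.add.at(delta, hi[ok], -1.0)
        counts = np.cumsum(delta[:-1])
    else:
        counts = np.zeros(len(r_values))

    edge_sorted = np.sort(edge)
    n_interior = N - np.searchsorted(edge_sorted, r_values, side="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(n_interior > 0, area * counts / (n_interior * N), np.nan)
    L = np.sqrt(K / np.pi)
    return RipleyCurve(r_values, K, L, L - r_values, n_interior.astype(int), area)


def mean_ripley(curves: list[RipleyCurve]) -> tuple[np.ndarray, np.ndarray]:
    """Per-r mean and SD of L(r)-r over curves, ignoring undefined entries."""
    if not curves:
        raise ValueError("mean_ripley needs at least one curve")
    grid = curves[0].r_values
    for c in curves[1:]:
        if len(c.r_values) != len(grid) or not np.array_equal(c.r_values, grid):
            raise ValueError("all curves must share the same r grid")
    stack = np.vstack([c.L_minus_r for c in curves])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=0)
    return mean, sd
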