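"""Mean-shift clustering of merged localizations and the cluster filters.

The mean-shift variant used here is the flat square-window one: a box of
width twice the bandwidth is centred on each localization, the mean of all
localizations in the box is computed, the box is shifted to that mean, and
the process repeats until the shift is below tolerance.  Localizations
whose trajectories converge to the same point form a cluster.

The bandwidth is not free: it is derived from the physical geometry of the
labelling stack.  Two antibodies bound to a dimer can sit ~8 nm apart at the
receptors, and each antibody adds its own arm length, streptavidin biotin-
site offset, single-stranded DNA length and dye-fit uncertainty, so two
localizations from one dimer can appear up to
2*(arm + biotin + ssDNA + dye) + separation apart — 48 nm with the default
budget.  Clusters are then filtered: a real cluster contains at least one
antibody, whose expected localization yield is lambda = per-strand rate x
strands (7.2 x 6 = 43.2), so observing fewer than 12 localizations from a
real antibody has Poisson probability ~2e-8 and such clusters are discarded
as noise, as are clusters with degenerate (zero-area) convex hulls or ones
within 100 nm of the cell or image boundary.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numba
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.special import gammaln, logsumexp

from .locdata import LocalizationTable, PolygonROI

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# bandwidth


@dataclasses.dataclass(frozen=True)
class BandwidthDerivation:
    """Component distances (nm) that bound two same-dimer localizations.

    Per antibody: arm length, streptavidin biotin-site offset, ssDNA docking
    strand length, dye fit uncertainty.  Once: receptor separation across
    the dimer interface.
    """

    antibody_arm: float = 10.0
    biotin_site_offset: float = 3.0
    ssdna_length: float = 3.0
    dye_fit_uncertainty: float = 4.0
    receptor_separation: float = 8.0

    @property
    def per_antibody(self) -> float:
        return (
            self.antibody_arm
            + self.biotin_site_offset
            + self.ssdna_length
            + self.dye_fit_uncertainty
        )

    @property
    def total(self) -> float:
        return 2.0 * self.per_antibody + self.receptor_separation


def derive_bandwidth(derivation: BandwidthDerivation = BandwidthDerivation()) -> float:
    """Worst-case same-dimer localization separation; the mean-shift bandwidth."""
    for f in dataclasses.fields(derivation):
        if getattr(derivation, f.name) < 0:
            raise ValueError(f"bandwidth component {f.name} must be non-negative")
    return derivation.total


# ---------------------------------------------------------------------------
# mean shift


@numba.njit(cache=True)
def _grid_window_means(qx, qy, half, cell, min0, min1, nrows, ncols, cell_start, pts_sorted):
    """Count and mean of indexed points within Chebyshev distance ``half``."""
    m = len(qx)
    counts = np.zeros(m, np.int64)
    means = np.empty((m, 2))
    for i in range(m):
        x = qx[i]
        y = qy[i]
        i0 = np.int64(np.floor((x - half) / cell)) - min0
        i1 = np.int64(np.floor((x + half) / cell)) - min0
        j0 = np.int64(np.floor((y - half) / cell)) - min1
        j1 = np.int64(np.floor((y + half) / cell)) - min1
        if i0 < 0:
            i0 = 0
        if j0 < 0:
            j0 = 0
        if i1 >= nrows:
            i1 = nrows - 1
        if j1 >= ncols:
            j1 = ncols - 1
        sx = 0.0
        sy = 0.0
        c = 0
        for ci in range(i0, i1 + 1):
            base = ci * ncols
            for cj in range(j0, j1 + 1):
                for k in range(cell_start[base + cj], cell_start[base + cj + 1]):
                    px = pts_sorted[k, 0]
                    py = pts_sorted[k, 1]
                    if -half <= px - x <= half and -half <= py - y <= half:
                        sx += px
                        sy += py
                        c += 1
        counts[i] = c
        if c > 0:
            means[i, 0] = sx / c
            means[i, 1] = sy / c
        else:  # empty window: stay put
            means[i, 0] = x
            means[i, 1] = y
    return counts, means


class _GridIndex:
    """Uniform-grid spatial index keyed by the bandwidth.

    Data points are bucketed into square cells of side ``cell`` and sorted
    by flattened cell id; a Chebyshev window query scans the touched cells.
    """

    def __init__(self, points: np.ndarray, cell: float):
        self.cell = float(cell)
        self.pts = np.ascontiguousarray(points, float)
        ij = np.floor(self.pts / self.cell).astype(np.int64)
        self.mins = ij.min(axis=0)
        ij -= self.mins
        self.nrows = int(ij[:, 0].max()) + 1
        self.ncols = int(ij[:, 1].max()) + 1
        key = ij[:, 0] * self.ncols + ij[:, 1]
        order = np.argsort(key, kind="stable")
        self.pts_sorted = np.ascontiguousarray(self.pts[order])
        self.cell_start = np.zeros(self.nrows * self.ncols + 1, np.int64)
        np.cumsum(np.bincount(key, minlength=self.nrows * self.ncols), out=self.cell_start[1:])

    def window_mean(self, q: np.ndarray, half: float) -> tuple[np.ndarray, np.ndarray]:
        """Count and mean of data points with Chebyshev distance <= half of q."""
        q = np.ascontiguousarray(q, float)
        return _grid_window_means(
            q[:, 0],
            q[:, 1],
            float(half),
            self.cell,
            self.mins[0],
            self.mins[1],
            self.nrows,
            self.ncols,
            self.cell_start,
            self.pts_sorted,
        )


@dataclasses.dataclass
class MeanShiftResult:
    """Converged mode per point and the induced cluster assignment."""

    modes: np.ndarray  # (n, 2) final trajectory positions
    labels: np.ndarray  # (n,) cluster index, canonical (by first member)
    converged: np.ndarray  # (n,) bool, False where max_iter was exhausted
    n_clusters: int

    def cluster_modes(self) -> np.ndarray:
        """(n_clusters, 2) mean of member modes per cluster."""
        out = np.zeros((self.n_clusters, 2))
        counts = np.bincount(self.labels, minlength=self.n_clusters)
        np.add.at(out, self.labels, self.modes)
        return out / counts[:, None]


def _canonical_labels(raw: np.ndarray) -> tuple[np.ndarray, int]:
    """Relabel clusters by order of first appearance (point order independent
    given a fixed point set, since components are set-determined)."""
    _, first_pos, inverse = np.unique(raw, return_index=True, return_inverse=True)
    rank = np.argsort(np.argsort(first_pos, kind="stable"), kind="stable")
    return rank[inverse], len(first_pos)


def mean_shift(
    points: np.ndarray,
    bandwidth: float,
    conv_tol: float = 0.01,
    merge_tol: float = 1.0,
    max_iter: int = 500,
    chunk: int = 200_000,
) -> MeanShiftResult:
    """Flat square-window mean shift over a fixed data set.

    The window always averages over the *original* points; only the query
    positions move.  Points whose final positions lie within ``merge_tol``
    (Euclidean, single linkage) are grouped into one cluster.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    points = np.asarray(points, float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) == 0:
        raise ValueError("points must be a non-empty (n, 2) array")
    n = len(points)
    grid = _GridIndex(points, bandwidth)
    pos = points.copy()
    active = np.arange(n)
    converged = np.zeros(n, bool)
    for _ in range(max_iter):
        if len(active) == 0:
            break
        # trajectories that have reached bitwise-equal positions stay equal
        # forever (the window mean depends only on the position), so only
        # unique active positions need a window query
        uniq, inv = np.unique(pos[active], axis=0, return_inverse=True)
        means = np.empty_like(uniq)
        for start in range(0, len(uniq), chunk):
            _, means[start : start + chunk] = grid.window_mean(
                uniq[start : start + chunk], bandwidth
            )
        new = means[inv]
        shift = np.hypot(new[:, 0] - pos[active, 0], new[:, 1] - pos[active, 1])
        pos[active] = new
        done = shift < conv_tol
        converged[active[done]] = True
        active = active[~done]

    # group trajectories that converged to the same point: collapse bitwise
    # duplicates first, then single-link the unique modes within merge_tol
    uniq_modes, inv = np.unique(pos, axis=0, return_inverse=True)
    tree = cKDTree(uniq_modes)
    pairs = tree.query_pairs(merge_tol, output_type="ndarray")
    if len(pairs):
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
            shape=(len(uniq_modes), len(uniq_modes)),
        )
        _, raw_u = connected_components(adj, directed=False)
    else:
        raw_u = np.arange(len(uniq_modes))
    raw = raw_u[inv]
    labels, n_clusters = _canonical_labels(raw)
    return MeanShiftResult(pos, labels, converged, n_clusters)


# ---------------------------------------------------------------------------
# hull geometry


def convex_hull_area(points: np.ndarray) -> tuple[float, np.ndarray]:
    """Convex hull area (nm^2) and hull vertices; 0 for < 3 or collinear points."""
    points = np.asarray(points, float)
    if len(points) == 0:
        raise ValueError("convex hull of an empty point set is undefined")
    if len(points) < 3:
        return 0.0, points.copy()
    try:
        hull = ConvexHull(points)
    except QhullError:  # collinear / duplicate degenerate input
        return 0.0, points.copy()
    return float(hull.volume), points[hull.vertices]  # 2-D "volume" is area


# ---------------------------------------------------------------------------
# cluster tables


DISCARD_NONE = ""
DISCARD_TOO_FEW = "too_few"
DISCARD_DEGENERATE = "degenerate_hull"
DISCARD_BOUNDARY = "near_boundary"


@dataclasses.dataclass
class ClusterTable:
    """Per-cluster records for one cell.

    ``df`` columns: cluster_id, n_total, n_<channel>..., area_nm2,
    d_<channel>... (localizations per nm^2, NaN for zero-area hulls),
    mode_x_nm, mode_y_nm, boundary_dist_nm, retained, discard_reason.
    ``members`` maps cluster_id -> record-id array of member localizations.
    """

    df: pd.DataFrame
    members: dict[int, np.ndarray]
    channels: tuple[str, ...]
    cell_id: str = ""
    condition: int | None = None

    def __len__(self) -> int:
        return len(self.df)

    def retained(self) -> pd.DataFrame:
        return self.df[self.df["retained"]]

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, float_format="%.10g")


def build_cluster_table(
    table: LocalizationTable,
    assignments: MeanShiftResult | np.ndarray,
    cell_mask: PolygonROI | None = None,
    cell_id: str = "",
    condition: int | None = None,
) -> ClusterTable:
    """Summarize a mean-shift assignment into per-cluster records.

    Per cluster: per-channel localization counts ("composition"), convex-
    hull area, per-channel densities (count / area), mode position, and the
    minimum distance from any member localization to the cell-mask boundary
    or the field-of-view rectangle edge.  When no cell mask is given the
    field-of-view rectangle alone bounds the clusters (logged as a fallback,
    since real cells rarely fill the image).
    """
    if isinstance(assignments, MeanShiftResult):
        labels = assignments.labels
        modes = assignments.modes
    else:
        labels = np.asarray(assignments)
        modes = None
    if len(labels) != len(table):
        raise ValueError("assignment length does not match the localization table")
    if cell_mask is None:
        logger.warning(
            "no cell mask supplied; using the field-of-view rectangle as the boundary"
        )

    df = table.df
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    if len(labels):
        if labels.min() < 0:
            raise ValueError("assignments must be non-negative cluster indices")
        n_clusters = int(labels.max()) + 1
    else:
        n_clusters = 0

    fov_dist = np.minimum.reduce([x, table.fov_width - x, y, table.fov_height - y]) if len(df) else np.zeros(0)
    bdist = fov_dist
    if cell_mask is not None and len(df):
        bdist = np.minimum(fov_dist, cell_mask.edge_distance(x, y))

    channels = tuple(c for c in table.channels)
    chan_codes = pd.Categorical(df["channel"], categories=channels).codes

    rows = []
    members: dict[int, np.ndarray] = {}
    ids = df["id"].to_numpy()
    order = np.argsort(labels, kind="stable")
    bounds = np.searchsorted(labels[order], np.arange(n_clusters + 1))
    for k in range(n_clusters):
        sel = order[bounds[k] : bounds[k + 1]]
        members[k] = ids[sel]
        pts = np.column_stack([x[sel], y[sel]])
        area, _ = convex_hull_area(pts)
        counts = np.bincount(chan_codes[sel][chan_codes[sel] >= 0], minlength=len(channels))
        if modes is not None:
            mode = modes[sel].mean(axis=0)
        else:
            mode = pts.mean(axis=0)
        row = {
            "cluster_id": k,
            "n_total": len(sel),
            "area_nm2": area,
            "mode_x_nm": mode[0],
            "mode_y_nm": mode[1],
            "boundary_dist_nm": float(bdist[sel].min()) if len(sel) else np.nan,
        }
        for ci, ch in enumerate(channels):
            row[f"n_{ch}"] = int(counts[ci])
            row[f"d_{ch}"] = counts[ci] / area if area > 0 else np.nan
        rows.append(row)

    cols = (
        ["cluster_id", "n_total", "area_nm2", "mode_x_nm", "mode_y_nm", "boundary_dist_nm"]
        + [f"n_{ch}" for ch in channels]
        + [f"d_{ch}" for ch in channels]
    )
    out = pd.DataFrame(rows, columns=cols)
    out["retained"] = True
    out["discard_reason"] = DISCARD_NONE
    return ClusterTable(out, members, channels, cell_id=cell_id, condition=condition)


def min_count_poisson(lambda_rate: float, k: int) -> tuple[float, float]:
    """Poisson pmf at k and CDF up to k (log-space), for the noise cutoff.

    With lambda = per-strand rate x strands per conjugate (7.2 x 6 = 43.2
    localizations per imaging round for one antibody), the probability of a
    real antibody yielding <= 12 localizations is ~2e-8, which justifies
    discarding clusters with fewer than 12 localizations as noise.
    """
    if lambda_rate <= 0:
        raise ValueError("lambda_rate must be positive")
    if k < 0 or int(k) != k:
        raise ValueError("k must be a non-negative integer")
    ks = np.arange(k + 1)
    logpmf = ks * np.log(lambda_rate) - lambda_rate - gammaln(ks + 1)
    return float(np.exp(logpmf[-1])), float(np.exp(logsumexp(logpmf)))


def filter_clusters(
    clusters: ClusterTable,
    min_count: int = 12,
    boundary_margin: float = 100.0,
) -> ClusterTable:
    """Apply the noise and boundary filters; discarded rows keep a reason.

    Reasons, in precedence order: ``too_few`` (fewer than ``min_count``
    localizations), ``degenerate_hull`` (zero hull area), ``near_boundary``
    (any member localization closer than ``boundary_margin`` to the cell or
    image boundary, including outside the cell mask).
    """
    df = clusters.df.copy()
    reason = np.full(len(df), DISCARD_NONE, dtype=object)
    near = (df["boundary_dist_nm"] < boundary_margin).to_numpy()
    degenerate = (df["area_nm2"] <= 0).to_numpy()
    too_few = (df["n_total"] < min_count).to_numpy()
    reason[near] = DISCARD_BOUNDARY
    reason[degenerate] = DISCARD_DEGENERATE
    reason[too_few] = DISCARD_TOO_FEW
    df["discard_reason"] = reason
    df["retained"] = reason == DISCARD_NONE
    return ClusterTable(
        df, clusters.members, clusters.channels, clusters.cell_id, clusters.condition
    )
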