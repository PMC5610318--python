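"""Fiducial-based drift correction, channel alignment and precision QC.

Gold-nanoparticle fiducials are visible in every frame; their apparent
motion is the stage drift.  Tracks are linked greedily frame-to-frame,
averaged into a single drift trace, and subtracted from all localizations.
Channel-to-channel registration solves for the x-y translation that best
aligns each channel's fiducial centroids to a reference channel.  The
localization precision is checked with the distance between neighbouring-
frame localizations (DNFL): for a static emitter observed with per-axis
Gaussian error sigma, the distance between two adjacent-frame localizations
is Rayleigh with scale sigma*sqrt(2) and mean sigma*sqrt(pi).
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.spatial import cKDTree

from .locdata import FIDUCIAL_CHANNEL, LocalizationTable

_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclasses.dataclass
class FiducialTrack:
    """One drift marker's per-frame observed positions (NaN where absent)."""

    marker_id: int
    positions: np.ndarray  # (n_frames, 2), NaN where not observed
    present: np.ndarray  # (n_frames,) bool

    @property
    def presence_fraction(self) -> float:
        return float(self.present.mean()) if len(self.present) else 0.0

    @property
    def mean_position(self) -> np.ndarray:
        return np.nanmean(self.positions, axis=0)


@dataclasses.dataclass
class DriftTrace:
    """Per-frame (dx, dy) displacement in nm relative to frame 0."""

    displacement: np.ndarray  # (n_frames, 2)

    def __len__(self) -> int:
        return len(self.displacement)

    def negated(self) -> "DriftTrace":
        return DriftTrace(-self.displacement)


def detect_fiducials(
    table: LocalizationTable,
    min_presence_fraction: float = 0.8,
    radius: float = 100.0,
) -> list[FiducialTrack]:
    """Link localizations across frames into candidate fiducial tracks.

    Greedy nearest-neighbour linking: localizations within ``radius`` nm of
    an existing track's last position extend that track; the rest seed new
    tracks.  Only tracks present in at least ``min_presence_fraction`` of
    frames are returned — transiently binding imagers never qualify.
    """
    if len(table) == 0:
        raise ValueError("cannot detect fiducials in an empty table")
    n_frames = table.n_frames
    df = table.df
    frames = df["frame"].to_numpy()
    xy = table.xy

    last_pos: list[np.ndarray] = []  # per-track last observed position
    track_rows: list[list[tuple[int, float, float]]] = []
    order = np.argsort(frames, kind="stable")
    frames_sorted = frames[order]
    bounds = np.searchsorted(frames_sorted, np.arange(n_frames + 1))
    for f in range(n_frames):
        rows = order[bounds[f] : bounds[f + 1]]
        if len(rows) == 0:
            continue
        pts = xy[rows]
        assigned = np.full(len(rows), -1)
        if last_pos:
            tree = cKDTree(np.asarray(last_pos))
            dist, idx = tree.query(pts, k=1)
            # greedy: closest pairs claim tracks first, one hit per track/frame
            claimed: set[int] = set()
            for j in np.argsort(dist, kind="stable"):
                if dist[j] <= radius and idx[j] not in claimed:
                    assigned[j] = idx[j]
                    claimed.add(int(idx[j]))
        for j, row in enumerate(rows):
            t = assigned[j]
            if t < 0:
                t = len(last_pos)
                last_pos.append(pts[j].copy())
                track_rows.append([])
            else:
                last_pos[t] = pts[j].copy()
            track_rows[t].append((f, pts[j][0], pts[j][1]))

    tracks = []
    for tid, rows_t in enumerate(track_rows):
        present = np.zeros(n_frames, bool)
        pos = np.full((n_frames, 2), np.nan)
        for f, px, py in rows_t:
            present[f] = True
            pos[f] = (px, py)
        if present.mean() >= min_presence_fraction:
            tracks.append(FiducialTrack(tid, pos, present))
    return tracks


def estimate_drift(tracks: list[FiducialTrack], smoothing_window: int = 100) -> DriftTrace:
    """Average per-track displacements into one global drift trace.

    Each track contributes its displacement relative to its first observed
    position; per-frame values are averaged over tracks, gaps are linearly
    interpolated, and the result is smoothed with a centred moving average.
    """
    if not tracks:
        raise ValueError("drift estimation requires at least one fiducial track")
    n_frames = len(tracks[0].positions)
    disp = np.full((len(tracks), n_frames, 2), np.nan)
    for i, tr in enumerate(tracks):
        first = np.flatnonzero(tr.present)
        if len(first) == 0:
            continue
        disp[i] = tr.positions - tr.positions[first[0]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_disp = np.nanmean(disp, axis=0)
    # linear interpolation across frames where no track was observed
    t = np.arange(n_frames)
    for ax in range(2):
        good = np.isfinite(mean_disp[:, ax])
        if not good.any():
            raise ValueError("no frame has an observed fiducial")
        mean_disp[:, ax] = np.interp(t, t[good], mean_disp[good, ax])
    if smoothing_window > 1:
        mean_disp = uniform_filter1d(mean_disp, smoothing_window, axis=0, mode="nearest")
    return DriftTrace(mean_disp)


def apply_drift_correction(table: LocalizationTable, trace: DriftTrace) -> LocalizationTable:
    """Subtract the drift trace value at each record's frame."""
    frames = table.df["frame"].to_numpy()
    if len(table) and (frames.min() < 0 or frames.max() >= len(trace)):
        raise ValueError("drift trace does not cover all frames in the table")
    df = table.df.copy()
    if len(table):
        df["x"] = df["x"].to_numpy() - trace.displacement[frames, 0]
        df["y"] = df["y"].to_numpy() - trace.displacement[frames, 1]
    return LocalizationTable(df, table.fov_width, table.fov_height, table.n_frames, table.channels)


def align_channels(
    tables: dict[str, LocalizationTable],
    reference_channel: str,
    min_presence_fraction: float = 0.8,
    radius: float = 100.0,
    match_radius: float = 250.0,
) -> tuple[dict[str, tuple[float, float]], dict[str, LocalizationTable]]:
    """Translate each channel so its fiducial markers overlay the reference.

    Marker position = mean of that marker's localizations (the localization-
    table equivalent of fitting a Gaussian to the rendered marker).  Markers
    are matched to the reference by nearest neighbour within ``match_radius``
    and the translation is the least-squares (mean) displacement over
    matched pairs.  The reference channel receives (0, 0).
    """
    if reference_channel not in tables:
        raise ValueError(f"reference channel {reference_channel!r} not among tables")

    def marker_centroids(tab: LocalizationTable) -> np.ndarray:
        tracks = detect_fiducials(tab, min_presence_fraction, radius)
        if not tracks:
            raise ValueError("no fiducial markers detected in a channel")
        return np.asarray([tr.mean_position for tr in tracks])

    ref = marker_centroids(tables[reference_channel])
    tree = cKDTree(ref)
    shifts: dict[str, tuple[float, float]] = {}
    aligned: dict[str, LocalizationTable] = {}
    for ch, tab in tables.items():
        if ch == reference_channel:
            shifts[ch] = (0.0, 0.0)
            aligned[ch] = tab
            continue
        mk = marker_centroids(tab)
        dist, idx = tree.query(mk, k=1)
        ok = dist <= match_radius
        if not ok.any():
            raise ValueError(f"no matched marker pair between {ch!r} and the reference")
        delta = ref[idx[ok]] - mk[ok]
        shift = delta.mean(axis=0)
        shifts[ch] = (float(shift[0]), float(shift[1]))
        df = tab.df.copy()
        df["x"] = df["x"] + shift[0]
        df["y"] = df["y"] + shift[1]
        aligned[ch] = LocalizationTable(df, tab.fov_width, tab.fov_height, tab.n_frames, tab.channels)
    return shifts, aligned


def dnfl_precision(
    table: LocalizationTable, pairing_radius: float = 50.0
) -> tuple[np.ndarray, float]:
    """Distance between neighbouring-frame localizations and the implied sigma.

    Each localization in frame t is paired with its nearest neighbour in
    frame t+1 within ``pairing_radius``.  Under the Rayleigh model the mean
    pair distance is sigma*sqrt(pi), so sigma_hat = mean(d)/sqrt(pi).
    """
    frames = table.df["frame"].to_numpy()
    if len(table) == 0 or table.n_frames < 2:
        raise ValueError("DNFL needs localizations spanning at least 2 frames")
    xy = table.xy
    order = np.argsort(frames, kind="stable")
    fs = frames[order]
    bounds = np.searchsorted(fs, np.arange(table.n_frames + 1))
    dists = []
    for f in range(table.n_frames - 1):
        a = order[bounds[f] : bounds[f + 1]]
        b = order[bounds[f + 1] : bounds[f + 2]]
        if len(a) == 0 or len(b) == 0:
            continue
        tree = cKDTree(xy[b])
        d, _ = tree.query(xy[a], k=1, distance_upper_bound=pairing_radius)
        dists.append(d[np.isfinite(d)])
    sample = np.concatenate(dists) if dists else np.zeros(0)
    if len(sample) == 0:
        warnings.warn("no neighbouring-frame pairs found within the pairing radius")
        return sample, float("nan")
    return sample, float(sample.mean() / np.sqrt(np.pi))


def fwhm_from_sigma(sigma: float) -> float:
    """Full width at half maximum of a Gaussian: 2*sqrt(2*ln 2)*sigma."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return _FWHM_FACTOR * sigma
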