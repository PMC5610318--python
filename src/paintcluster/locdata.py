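"""Localization tables, polygon ROIs, and their CSV dialects.

Coordinates are stored in nanometres with the origin at the top-left corner
of the field of view, x increasing rightward and y downward.  A camera pixel
size (e.g. 160 nm) enters only as the dialect scale factor applied on read.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

#: reserved channel label for fiducial (drift marker) localizations
FIDUCIAL_CHANNEL = "fiducial"

_COLUMNS = ["id", "frame", "x", "y", "channel", "sigma", "intensity"]


@dataclasses.dataclass(frozen=True)
class Dialect:
    """Column-name mapping (and unit scale) for localization CSV files.

    ``scale`` multiplies file coordinates to obtain nanometres; it is 1.0
    for files already in nm and e.g. 160.0 for files in camera pixels.
    """

    frame: str = "frame"
    x: str = "x_nm"
    y: str = "y_nm"
    channel: str = "channel"
    sigma: str = "sigma_nm"
    intensity: str = "intensity"
    scale: float = 1.0


#: dialect matching a ThunderSTORM-style export (coordinates already in nm)
THUNDERSTORM = Dialect(
    frame="frame",
    x="x [nm]",
    y="y [nm]",
    channel="channel",
    sigma="uncertainty [nm]",
    intensity="intensity [photon]",
)


class FormatError(ValueError):
    """Raised when a localization or ROI file does not match its dialect."""


@dataclasses.dataclass
class LocalizationTable:
    """Ordered collection of super-localized emission events.

    ``df`` holds columns ``id, frame, x, y, channel, sigma, intensity``
    (x/y/sigma in nm; sigma and intensity may be NaN).  ``fov_width`` and
    ``fov_height`` are the nominal field-of-view extents in nm.
    """

    df: pd.DataFrame
    fov_width: float
    fov_height: float
    n_frames: int
    channels: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.df)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) float array of coordinates in nm."""
        return self.df[["x", "y"]].to_numpy(float)

    @classmethod
    def from_arrays(
        cls,
        frame: np.ndarray,
        x: np.ndarray,
        y: np.ndarray,
        channel: Iterable[str],
        sigma: np.ndarray | None = None,
        intensity: np.ndarray | None = None,
        fov: tuple[float, float] | None = None,
        n_frames: int | None = None,
    ) -> "LocalizationTable":
        frame = np.asarray(frame, dtype=np.int64)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(x)
        df = pd.DataFrame(
            {
                "id": np.arange(n, dtype=np.int64),
                "frame": frame,
                "x": x,
                "y": y,
                "channel": pd.Series(list(channel), dtype=object),
                "sigma": np.full(n, np.nan) if sigma is None else np.asarray(sigma, float),
                "intensity": np.full(n, np.nan) if intensity is None else np.asarray(intensity, float),
            }
        )
        if fov is None:
            fov = (float(x.max()) if n else 0.0, float(y.max()) if n else 0.0)
        if n_frames is None:
            n_frames = int(frame.max()) + 1 if n else 0
        channels = tuple(dict.fromkeys(df["channel"].tolist()))
        return cls(df, float(fov[0]), float(fov[1]), int(n_frames), channels)

    def validate(self) -> None:
        df = self.df
        if not df["id"].is_unique:
            raise ValueError("record ids are not unique")
        if len(df) and not np.isfinite(df[["x", "y"]].to_numpy(float)).all():
            raise ValueError("non-finite coordinates present")
        if len(df) and (df["frame"] < 0).any():
            raise ValueError("negative frame index present")

    def _replace(self, df: pd.DataFrame) -> "LocalizationTable":
        channels = tuple(c for c in self.channels if c in set(df["channel"]))
        return LocalizationTable(
            df.reset_index(drop=True), self.fov_width, self.fov_height, self.n_frames, channels
        )

    def subset(self, mask: np.ndarray) -> "LocalizationTable":
        """Row-subset by boolean mask, preserving metadata and record ids."""
        return self._replace(self.df.loc[np.asarray(mask, bool)])

    def per_channel(self, include_fiducials: bool = False) -> dict[str, "LocalizationTable"]:
        out = {}
        for ch in self.channels:
            if ch == FIDUCIAL_CHANNEL and not include_fiducials:
                continue
            out[ch] = self.subset((self.df["channel"] == ch).to_numpy())
        return out

    def without_fiducials(self) -> "LocalizationTable":
        return self.subset((self.df["channel"] != FIDUCIAL_CHANNEL).to_numpy())


@dataclasses.dataclass(frozen=True)
class PolygonROI:
    """Simple (non-self-intersecting) closed polygon in nm coordinates."""

    vertices: np.ndarray  # (k, 2)

    def __post_init__(self):
        v = np.asarray(self.vertices, float)
        object.__setattr__(self, "vertices", v)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
            raise ValueError("a polygon ROI needs at least 3 (x, y) vertices")
        poly = Polygon(v)
        if not poly.is_valid:
            raise ValueError("polygon ROI is self-intersecting or otherwise invalid")
        if poly.area <= 0:
            raise ValueError("polygon ROI has zero enclosed area")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return float(self.polygon.area)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Strict interior test; points exactly on an edge are excluded."""
        return shapely.contains_xy(self.polygon, np.asarray(x, float), np.asarray(y, float))

    def edge_distance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Distance to the polygon boundary; negative for exterior points."""
        pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
        d = shapely.distance(pts, self.polygon.boundary)
        inside = self.contains(x, y)
        return np.where(inside, d, -d)

    @classmethod
    def rectangle(cls, x0: float, y0: float, x1: float, y1: float) -> "PolygonROI":
        return cls(np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], float))


def read_localizations(
    path, dialect: Dialect = Dialect(), fov: tuple[float, float] | None = None
) -> LocalizationTable:
    """Read a localization CSV into a :class:`LocalizationTable`.

    Mandatory columns (via the dialect): frame, x, y, channel.  Coordinates
    are multiplied by ``dialect.scale`` to obtain nm.  The field of view is
    inferred from the data extent when ``fov`` is not given.
    """
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    for attr in ("frame", "x", "y", "channel"):
        col = getattr(dialect, attr)
        if col not in raw.columns:
            raise FormatError(f"missing mandatory column {col!r} for field {attr!r}")

    def numeric(col: str, what: str) -> np.ndarray:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise FormatError(f"non-numeric {what} value {raw[col][bad.idxmax()]!r} at line {line}")
        return vals.to_numpy(float)

    frame = numeric(dialect.frame, "frame")
    x = numeric(dialect.x, "x") * dialect.scale
    y = numeric(dialect.y, "y") * dialect.scale
    sigma = None
    if dialect.sigma in raw.columns:
        sigma = numeric(dialect.sigma, "sigma") * dialect.scale
    intensity = None
    if dialect.intensity in raw.columns:
        intensity = numeric(dialect.intensity, "intensity")
    table = LocalizationTable.from_arrays(
        frame.astype(np.int64), x, y, raw[dialect.channel].astype(str), sigma, intensity, fov=fov
    )
    table.validate()
    return table


def write_localizations(table: LocalizationTable, path) -> None:
    """Write the table as CSV: frame,x_nm,y_nm,channel,sigma_nm,intensity."""
    out = pd.DataFrame(
        {
            "frame": table.df["frame"],
            "x_nm": table.df["x"],
            "y_nm": table.df["y"],
            "channel": table.df["channel"],
            "sigma_nm": table.df["sigma"],
            "intensity": table.df["intensity"],
        }
    )
    out.to_csv(path, index=False, float_format="%.10g")


def read_roi(path) -> PolygonROI:
    """Read one polygon from a vertex-list CSV with columns x_nm, y_nm."""
    df = pd.read_csv(path)
    for col in ("x_nm", "y_nm"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory ROI column {col!r}")
    return PolygonROI(df[["x_nm", "y_nm"]].to_numpy(float))


def write_roi(roi: PolygonROI, path) -> None:
    pd.DataFrame({"x_nm": roi.vertices[:, 0], "y_nm": roi.vertices[:, 1]}).to_csv(
        path, index=False, float_format="%.10g"
    )


def crop_to_roi(table: LocalizationTable, roi: PolygonROI) -> LocalizationTable:
    """Keep only records strictly inside the polygon (boundary excluded)."""
    mask = roi.contains(table.df["x"].to_numpy(float), table.df["y"].to_numpy(float))
    return table.subset(mask)
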