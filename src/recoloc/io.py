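"""Reading, writing and validation of localization tables and ROIs.

The canonical coordinate unit throughout the package is the nanometre; every
reader converts on ingest via ``unit_scale``. Localization tables are plain
delimited text (comma or tab, auto-detected) with a header row containing at
least ``x`` and ``y`` columns and optionally ``z``; extra columns (frame,
intensity, ...) are ignored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import shapely

from .errors import DimensionalityError, EmptyInputError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "LocalizationSet",
    "RegionOfInterest",
    "read_localizations",
    "write_localizations",
    "read_roi",
    "clip_to_roi",
]


@dataclass
class LocalizationSet:
    """A single channel's molecular localizations.

    Parameters
    ----------
    coords
        ``(n, d)`` array of positions in nm with ``d`` equal to 2 or 3.
    channel_label
        Name of the molecular species / colour channel.
    image_id
        Identifier of the source image (used for per-image statistics).
    n_dropped
        Number of rows rejected on ingest for non-finite coordinates.
    """

    coords: np.ndarray
    channel_label: str = ""
    image_id: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise DimensionalityError(
                f"coords must be (n, 2) or (n, 3); got shape {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise EmptyInputError("localization set contains no points")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    def __len__(self) -> int:
        return self.n


@dataclass
class RegionOfInterest:
    """Analysis region: a simple polygon (2D) or an axis-aligned box (3D).

    ``polygon`` is an ``(m, 2)`` vertex array in nm; ``box`` is a
    ``(2, 3)`` array of (min, max) corners in nm. Exactly one is set.
    """

    polygon: np.ndarray | None = None
    box: np.ndarray | None = None
    _shape: shapely.Polygon | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if (self.polygon is None) == (self.box is None):
            raise ValueError("exactly one of polygon or box must be given")
        if self.polygon is not None:
            self.polygon = np.asarray(self.polygon, dtype=float)
            if self.polygon.ndim != 2 or self.polygon.shape[1] != 2:
                raise DimensionalityError("polygon vertices must be (m, 2)")
            poly = shapely.Polygon(self.polygon)
            if not poly.is_valid:
                raise ValueError("ROI polygon is not simple (self-intersecting)")
            if poly.area <= 0:
                raise ValueError("ROI polygon has non-positive area")
            self._shape = poly
        else:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (2, 3):
                raise DimensionalityError("box must be a (2, 3) (min, max) array")
            if np.any(self.box[1] <= self.box[0]):
                raise ValueError("box must have positive extent on every axis")

    @property
    def dim(self) -> int:
        return 2 if self.polygon is not None else 3

    @property
    def measure(self) -> float:
        """Area in nm^2 (2D) or volume in nm^3 (3D)."""
        if self.polygon is not None:
            return float(self._shape.area)
        return float(np.prod(self.box[1] - self.box[0]))

    def contains(self, coords: np.ndarray) -> np.ndarray:
        """Boundary-inclusive membership mask for an (n, d) coordinate array."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape[1] != self.dim:
            raise DimensionalityError(
                f"ROI is {self.dim}D but points are {coords.shape[1]}D"
            )
        if self.polygon is not None:
            pts = shapely.points(coords)
            return shapely.covers(self._shape, pts)
        lo, hi = self.box
        return np.all((coords >= lo) & (coords <= hi), axis=1)


def read_localizations(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    unit_scale: float = 1.0,
    channel_label: str = "",
    image_id: str = "",
) -> LocalizationSet:
    """Read a localization table from delimited text.

    Parameters
    ----------
    path
        CSV/TSV file with a header row.
    columns
        Optional mapping from the roles ``x``, ``y``, ``z`` to column names in
        the file. Defaults to the identically named columns; ``z`` is used
        when present.
    unit_scale
        Multiplicative factor converting file units to nm (e.g. 1000 for µm).

    Rows with non-finite coordinates are dropped; the drop count is logged and
    recorded on the returned set.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    colmap = dict(columns) if columns else {}
    names = {role: colmap.get(role, role) for role in ("x", "y", "z")}
    for role in ("x", "y"):
        if names[role] not in df.columns:
            raise SchemaError(f"required column {names[role]!r} missing from {path}")
    use = [names["x"], names["y"]]
    if names["z"] in df.columns:
        use.append(names["z"])
    raw = df[use].to_numpy(dtype=float)
    ok = np.all(np.isfinite(raw), axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%s: dropped %d rows with non-finite coordinates", path, n_dropped)
    raw = raw[ok]
    if raw.shape[0] == 0:
        raise EmptyInputError(f"{path}: no rows with finite coordinates")
    return LocalizationSet(
        raw * float(unit_scale),
        channel_label=channel_label or str(Path(path).stem),
        image_id=image_id,
        n_dropped=n_dropped,
    )


def write_localizations(path: str | Path, locs: LocalizationSet) -> None:
    """Write a localization set as CSV with x,y(,z) columns in nm."""
    cols = ["x", "y", "z"][: locs.dim]
    pd.DataFrame(locs.coords, columns=cols).to_csv(path, index=False, float_format="%.6g")


def read_roi(path: str | Path) -> RegionOfInterest:
    """Read an ROI: a CSV of 2D polygon vertices, or a JSON 3D box spec.

    The JSON form is ``{"box": {"min": [x,y,z], "max": [x,y,z]}}``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        spec = json.loads(path.read_text())
        if "box" not in spec:
            raise SchemaError(f"{path}: JSON ROI must contain a 'box' object")
        return RegionOfInterest(box=np.array([spec["box"]["min"], spec["box"]["max"]]))
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("x", "y"):
        if col not in df.columns:
            raise SchemaError(f"{path}: polygon ROI needs x and y columns")
    return RegionOfInterest(polygon=df[["x", "y"]].to_numpy(dtype=float))


def clip_to_roi(points: LocalizationSet, roi: RegionOfInterest) -> LocalizationSet:
    """Retain points inside the ROI; boundary points count as inside."""
    mask = roi.contains(points.coords)
    if not mask.any():
        raise EmptyInputError("no localizations inside the ROI")
    return LocalizationSet(
        points.coords[mask],
        channel_label=points.channel_label,
        image_id=points.image_id,
    )
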