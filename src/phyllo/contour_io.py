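"""Reading, validation, normalization, and rasterization of leaf outlines.

A leaf outline is an ordered, closed sequence of planar points, the layout
used by large leaf-shape repositories that distribute per-leaf plain-text
files with two numeric columns (x and y).  The functions here bring such
outlines onto a common footing for density-based shape analysis:

* :func:`read_contour_file` parses one outline file (whitespace- or
  comma-delimited),
* :func:`normalize_contour` resamples to equal arc-length spacing, centers
  the centroid at the origin, and scales the maximum radius to 1,
* :func:`rasterize_contour` traces the outline onto a square pixel grid
  covering ``[-1.1, 1.1]^2``,
* :func:`read_manifest` loads the sample-id -> family label table.

Raster conventions: indices are 0-based, row = y, column = x; the grid
origin is the lower-left corner of the window in contour units.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.draw import line as _draw_line

from .errors import (
    DegenerateContourError,
    ConfigurationError,
    ParseError,
    ValidationError,
)

#: Half-width of the raster window in normalized contour units.  A
#: normalized contour has maximum centroid distance 1, so the extra 10%
#: keeps boundary kernels away from the grid edge.
WINDOW = 1.1

DEFAULT_N_RESAMPLE = 2000
DEFAULT_RESOLUTION = 512


@dataclasses.dataclass(frozen=True)
class Contour:
    """An ordered closed leaf outline.

    The last point implicitly connects back to the first; the closing
    vertex is never stored.

    Attributes
    ----------
    points : ndarray, shape (n, 2)
        Ordered (x, y) coordinates, arbitrary units.
    id : str
        Sample identifier.
    family : str or None
        Optional taxon label.
    """

    points: np.ndarray
    id: str = ""
    family: str | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError(
                f"contour {self.id!r}: points must be an (n, 2) array, "
                f"got shape {pts.shape}"
            )
        if pts.shape[0] < 3:
            raise ValidationError(
                f"contour {self.id!r}: needs at least 3 points, got {pts.shape[0]}"
            )
        if not np.all(np.isfinite(pts)):
            raise ValidationError(f"contour {self.id!r}: non-finite coordinates")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def closed_points(self) -> np.ndarray:
        """Vertices with the first point appended, closing the polygon."""
        return np.vstack([self.points, self.points[:1]])

    def perimeter(self) -> float:
        closed = self.closed_points()
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())


@dataclasses.dataclass(frozen=True)
class RasterMask:
    """A binary raster trace of a contour.

    Attributes
    ----------
    grid : ndarray of bool, shape (resolution, resolution)
        Foreground pixels of the traced outline; row = y, column = x.
    origin : (float, float)
        (x, y) of the grid's lower-left corner in contour units.
    pixel_size : float
        Side length of one pixel in contour units.
    """

    grid: np.ndarray
    origin: tuple[float, float]
    pixel_size: float

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=bool)
        if grid.size == 0:
            raise ValidationError("raster grid is empty")
        if not self.pixel_size > 0:
            raise ValidationError("pixel_size must be positive")
        object.__setattr__(self, "grid", grid)

    @property
    def resolution(self) -> tuple[int, int]:
        return self.grid.shape

    def foreground(self) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of foreground pixels."""
        rows, cols = np.nonzero(self.grid)
        return rows, cols

    def pixel_centers(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(x, y) coordinates of pixel centers, shape (n, 2)."""
        x = self.origin[0] + (np.asarray(cols) + 0.5) * self.pixel_size
        y = self.origin[1] + (np.asarray(rows) + 0.5) * self.pixel_size
        return np.column_stack([x, y])


def read_contour_file(path: str | Path, id: str | None = None) -> Contour:
    """Read one outline file: two numeric columns, whitespace- or comma-delimited.

    Blank lines are skipped.  Points are kept in file order.

    Raises
    ------
    ParseError
        If a non-empty line does not hold exactly two numeric fields; the
        message names the 1-based line number.
    ValidationError
        If fewer than 3 points remain.
    """
    path = Path(path)
    sample_id = id if id is not None else path.stem
    rows: list[tuple[float, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            stripped = raw.strip()
            if not stripped:
                continue
            fields = stripped.replace(",", " ").split()
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected two numeric fields, "
                    f"got {stripped!r}"
                )
            try:
                rows.append((float(fields[0]), float(fields[1])))
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric field in {stripped!r}"
                ) from exc
    if len(rows) < 3:
        raise ValidationError(
            f"{path}: contour needs at least 3 points, got {len(rows)}"
        )
    return Contour(points=np.asarray(rows, dtype=float), id=sample_id)


def write_contour_file(contour: Contour, path: str | Path) -> None:
    """Write an outline as two whitespace-separated columns (x y per line)."""
    buf = io.StringIO()
    for x, y in contour.points:
        buf.write(f"{x:.8f} {y:.8f}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def normalize_contour(c: Contour, n_resample: int = DEFAULT_N_RESAMPLE) -> Contour:
    """Resample to equal arc-length spacing, center, and scale.

    The closed polygon is resampled to ``n_resample`` points equally spaced
    by arc length (starting at the first input vertex), translated so the
    centroid (mean of resampled points) sits at the origin, and scaled so
    the maximum distance from the origin to any point is 1.

    Resampling before density estimation makes pixel density reflect the
    geometry of the outline rather than the digitization density of the
    source file.

    Raises
    ------
    DegenerateContourError
        If the total perimeter is zero (all points identical) or the
        resampled points collapse onto the centroid.
    """
    if n_resample < 3:
        raise ConfigurationError(f"n_resample must be >= 3, got {n_resample}")
    closed = c.closed_points()
    # pre-center on the vertex mean so the arithmetic below is independent
    # of the input's absolute position (translation invariance)
    closed = closed - closed[:-1].mean(axis=0)
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    total = float(seg.sum())
    if total <= 0.0:
        raise DegenerateContourError(
            f"contour {c.id!r}: zero perimeter (all points identical)"
        )
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.arange(n_resample) * (total / n_resample)
    x = np.interp(t, s, closed[:, 0])
    y = np.interp(t, s, closed[:, 1])
    pts = np.column_stack([x, y])
    # Iterate the resampling to its fixed point (a polygon whose own chords
    # are equal length), so normalizing twice changes nothing: one pass
    # leaves residual spacing variation where the new chords cut corners of
    # the input polyline.
    for _ in range(20):
        closed = np.vstack([pts, pts[:1]])
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        total = float(seg.sum())
        if total <= 0.0:
            raise DegenerateContourError(f"contour {c.id!r}: resampling collapsed")
        s = np.concatenate([[0.0], np.cumsum(seg)])
        t = np.arange(n_resample) * (total / n_resample)
        new = np.column_stack(
            [np.interp(t, s, closed[:, 0]), np.interp(t, s, closed[:, 1])]
        )
        moved = float(np.abs(new - pts).max())
        pts = new
        if moved < 1e-13 * max(total, 1.0):
            break
    pts -= pts.mean(axis=0)
    rmax = float(np.linalg.norm(pts, axis=1).max())
    if rmax <= 0.0:
        raise DegenerateContourError(f"contour {c.id!r}: degenerate after centering")
    pts /= rmax
    return Contour(points=pts, id=c.id, family=c.family)


def rasterize_contour(c: Contour, resolution: int = DEFAULT_RESOLUTION) -> RasterMask:
    """Trace a normalized contour onto a square binary grid.

    The grid covers ``[-WINDOW, WINDOW]^2``.  A pixel is foreground if a
    contour point falls in it or a polygon edge crosses it (Bresenham line
    rasterization between consecutive point pixels), so the traced outline
    is an 8-connected closed curve.

    Raises
    ------
    ConfigurationError
        If ``resolution < 16``.
    ValidationError
        If any point lies outside the grid window (contour not normalized).
    """
    if resolution < 16:
        raise ConfigurationError(f"resolution must be >= 16, got {resolution}")
    pts = c.points
    if np.abs(pts).max() > WINDOW:
        raise ValidationError(
            f"contour {c.id!r}: points outside [-{WINDOW}, {WINDOW}]^2; "
            "normalize_contour first"
        )
    pixel_size = 2.0 * WINDOW / resolution
    origin = (-WINDOW, -WINDOW)
    cols = np.floor((pts[:, 0] - origin[0]) / pixel_size).astype(int)
    rows = np.floor((pts[:, 1] - origin[1]) / pixel_size).astype(int)
    cols = np.clip(cols, 0, resolution - 1)
    rows = np.clip(rows, 0, resolution - 1)
    grid = np.zeros((resolution, resolution), dtype=bool)
    grid[rows, cols] = True
    # connect consecutive point pixels (including the closing edge)
    r_next = np.roll(rows, -1)
    c_next = np.roll(cols, -1)
    for r0, c0, r1, c1 in zip(rows, cols, r_next, c_next):
        if abs(int(r1) - int(r0)) > 1 or abs(int(c1) - int(c0)) > 1:
            rr, cc = _draw_line(int(r0), int(c0), int(r1), int(c1))
            grid[rr, cc] = True
    return RasterMask(grid=grid, origin=origin, pixel_size=pixel_size)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest: delimited table with columns id, family[, group].

    Returns a DataFrame indexed by ``id`` with column ``family`` and, when
    present, ``group``.

    Raises
    ------
    ParseError
        On a missing required column or duplicated ids.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=None, engine="python", comment="#")
    table.columns = [str(col).strip() for col in table.columns]
    for required in ("id", "family"):
        if required not in table.columns:
            raise ParseError(f"{path}: manifest missing required column {required!r}")
    table["id"] = table["id"].astype(str)
    dupes = table["id"][table["id"].duplicated()].unique()
    if len(dupes):
        raise ParseError(f"{path}: duplicate sample ids: {', '.join(dupes[:5])}")
    keep = ["id", "family"] + (["group"] if "group" in table.columns else [])
    return table[keep].set_index("id")


def load_contour_dir(
    directory: str | Path, pattern: str = "*.txt"
) -> list[Contour]:
    """Read every contour file matching ``pattern`` under ``directory``.

    Subdirectories (the directory-per-group layout of public leaf-outline
    deposits) are searched recursively; ids are file stems.
    """
    directory = Path(directory)
    paths = sorted(directory.rglob(pattern))
    if not paths:
        raise ValidationError(f"no contour files matching {pattern!r} in {directory}")
    return [read_contour_file(p) for p in paths]


def save_mask_pgm(mask: RasterMask, path: str | Path) -> None:
    """Dump a RasterMask as a plain-text PGM image (debugging aid)."""
    grid = np.flipud(mask.grid.astype(int)) * 255  # row 0 at the top of the image
    h, w = grid.shape
    lines = [f"P2\n{w} {h}\n255\n"]
    for row in grid:
        lines.append(" ".join(str(v) for v in row) + "\n")
    Path(path).write_text("".join(lines), encoding="utf-8")
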