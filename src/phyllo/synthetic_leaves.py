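"""Parametric synthetic leaf outlines with known class structure.

Blades are polar modulations of a circle,

    r(theta) = 1 + A*cos(k*theta) + a_s*cos(f_s*theta),

anisotropically stretched by ``base_aspect`` along the y axis, so lobe
count/depth, serration frequency/amplitude, and elongation are controlled
in closed form and descriptor expectations (solidity falls with lobe depth,
aspect ratio tracks the stretch) are analytic.  Compound leaves are traced
as the union outline of leaflet blades arranged palmately (fanning from one
point) or pinnately (along a rachis), built with exact polygon boolean
operations so the emitted contour files contain true vertices rather than
raster traces.  An optional internal ring emulates the enclosed background
hole left where overlapping leaflets occlude one another.

Per-vertex Gaussian coordinate noise emulates digitization jitter; the
default magnitudes used by the bundled presets keep outlines simple
(self-intersecting draws are rejected and re-drawn).  All randomness is
seeded: a dataset's master seed streams per-instance seeds as
``seed + instance_index`` (instances numbered consecutively across
classes), so regeneration is byte-identical.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

from .contour_io import Contour, write_contour_file
from .errors import ConfigurationError, GenerationError

__all__ = [
    "LeafParams",
    "generate_blade",
    "generate_compound",
    "generate_leaf",
    "generate_dataset",
    "PRESETS",
]

BLADE_VERTICES = 720
#: Angular gap between neighboring leaflets of a palmate fan (degrees).
PALMATE_GAP_DEG = 30.0
#: Leaflet ellipse semi-axes (radial, lateral) before placement.
LEAFLET_AXES = (0.55, 0.10)


@dataclasses.dataclass(frozen=True)
class LeafParams:
    """Knobs of one synthetic leaf class (see module docstring).

    ``leaflet_count == 1`` gives a simple blade; ``>= 2`` a compound leaf,
    palmate when ``petiole_length == 0`` and pinnate otherwise.
    """

    base_aspect: float = 1.0
    lobe_count: int = 0
    lobe_depth: float = 0.0
    serration_freq: int = 0
    serration_amp: float = 0.0
    leaflet_count: int = 1
    petiole_length: float = 0.0
    noise_sd: float = 0.0
    hole: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_aspect < 1.0:
            raise ConfigurationError("base_aspect must be >= 1")
        if self.lobe_count < 0 or self.serration_freq < 0:
            raise ConfigurationError("lobe_count and serration_freq must be >= 0")
        if not 0.0 <= self.lobe_depth < 0.9:
            raise ConfigurationError("lobe_depth must lie in [0, 0.9)")
        if not 0.0 <= self.serration_amp < 0.2:
            raise ConfigurationError("serration_amp must lie in [0, 0.2)")
        if self.leaflet_count < 1:
            raise ConfigurationError("leaflet_count must be >= 1")
        if self.petiole_length < 0 or self.noise_sd < 0:
            raise ConfigurationError("petiole_length and noise_sd must be >= 0")


def _is_simple(points: np.ndarray) -> bool:
    return bool(shapely.LinearRing(points).is_simple)


def _with_noise(
    points: np.ndarray, noise_sd: float, rng: np.random.Generator, what: str
) -> np.ndarray:
    """Add seeded coordinate noise, re-drawing if the outline self-intersects."""
    if noise_sd == 0.0:
        if not _is_simple(points):
            raise GenerationError(f"{what}: outline self-intersects")
        return points
    for _ in range(10):
        noisy = points + rng.normal(0.0, noise_sd, size=points.shape)
        if _is_simple(noisy):
            return noisy
    raise GenerationError(
        f"{what}: no simple outline after 10 noise draws (noise_sd too large?)"
    )


def _blade_polygon(p: LeafParams) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * np.pi, BLADE_VERTICES, endpoint=False)
    r = (
        1.0
        + p.lobe_depth * np.cos(p.lobe_count * theta)
        + p.serration_amp * np.cos(p.serration_freq * theta)
    )
    if (r <= 0.0).any():
        raise GenerationError(
            "radial profile non-positive: lobe_depth + serration_amp too large"
        )
    x = r * np.cos(theta)
    y = r * np.sin(theta) * p.base_aspect
    return np.column_stack([x, y])


def _exterior(geom) -> np.ndarray:
    if geom.geom_type != "Polygon":
        raise GenerationError(f"union outline is a {geom.geom_type}, not a polygon")
    coords = np.asarray(geom.exterior.coords)[:-1]  # drop closing duplicate
    return coords


def _resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Equal arc-length resampling of a closed polyline (keeps union outlines
    free of the near-duplicate vertices boolean operations introduce)."""
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.arange(n) * (s[-1] / n)
    return np.column_stack(
        [np.interp(t, s, closed[:, 0]), np.interp(t, s, closed[:, 1])]
    )


def generate_blade(p: LeafParams, rng: np.random.Generator | None = None) -> Contour:
    """A simple (single-blade) leaf outline, optionally with a petiole."""
    rng = rng if rng is not None else np.random.default_rng(p.seed)
    pts = _blade_polygon(p)
    if p.petiole_length > 0.0:
        blade = Polygon(pts)
        y_min = pts[:, 1].min()
        petiole = shapely.box(-0.025, y_min - p.petiole_length, 0.025, y_min + 0.05)
        pts = _resample_closed(_exterior(blade.union(petiole)), BLADE_VERTICES)
    pts = _with_noise(pts, p.noise_sd, rng, "blade")
    return Contour(points=pts, id="blade")


def _leaflet(angle_deg: float, offset: np.ndarray | None = None) -> Polygon:
    """One leaflet ellipse pointing outward along ``angle_deg`` from its base."""
    a, b = LEAFLET_AXES
    t = np.linspace(0.0, 2.0 * np.pi, 120, endpoint=False)
    ellipse = np.column_stack([a * np.cos(t), b * np.sin(t)])
    ellipse[:, 0] += a - 0.07  # base slightly behind the attachment point
    phi = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    placed = ellipse @ rot.T
    if offset is not None:
        placed = placed + offset
    return Polygon(placed)


def _palmate_union(p: LeafParams):
    k = p.leaflet_count
    angles = 90.0 + (np.arange(k) - (k - 1) / 2.0) * PALMATE_GAP_DEG
    parts = [_leaflet(a) for a in angles]
    parts.append(Point(0.0, 0.0).buffer(0.08, quad_segs=12))
    return shapely.unary_union(parts)


def _pinnate_union(p: LeafParams):
    k = p.leaflet_count
    n_side = k - 1  # one terminal leaflet at the rachis tip
    top = 1.4
    rachis = shapely.box(-0.03, -p.petiole_length, 0.03, top)
    parts = [rachis, _leaflet(90.0, offset=np.array([0.0, top - 0.1]))]
    heights = np.linspace(0.15, top - 0.35, max(n_side, 1))
    for j in range(n_side):
        side = 1.0 if j % 2 == 0 else -1.0
        angle = 90.0 - side * 55.0
        parts.append(_leaflet(angle, offset=np.array([0.0, heights[j]])))
    return shapely.unary_union(parts)


def _hole_ring(p: LeafParams) -> np.ndarray:
    """Internal loop emulating the occlusion hole of overlapping leaflets."""
    center = np.array([0.0, 0.45]) if p.petiole_length == 0 else np.array([0.0, 0.7])
    t = np.linspace(0.0, 2.0 * np.pi, 48, endpoint=False)
    return center + 0.07 * np.column_stack([np.cos(t), np.sin(t)])


def _stitch_ring(exterior: np.ndarray, ring: np.ndarray) -> np.ndarray:
    """Insert an internal ring into the outline via a doubled bridge edge.

    The path runs around the exterior to its vertex nearest the ring,
    detours around the ring, and returns, so the result is still a single
    closed polyline (intentionally non-simple at the bridge).
    """
    d_ext = np.linalg.norm(exterior - ring.mean(axis=0), axis=1)
    j = int(np.argmin(d_ext))
    d_ring = np.linalg.norm(ring - exterior[j], axis=1)
    s = int(np.argmin(d_ring))
    ring_path = np.vstack([ring[s:], ring[:s], ring[s : s + 1]])
    return np.vstack([exterior[: j + 1], ring_path, exterior[j:]])


def generate_compound(p: LeafParams, rng: np.random.Generator | None = None) -> Contour:
    """A compound leaf outline traced from the union of leaflet polygons."""
    if p.leaflet_count < 2:
        raise ConfigurationError("generate_compound needs leaflet_count >= 2")
    rng = rng if rng is not None else np.random.default_rng(p.seed)
    union = _palmate_union(p) if p.petiole_length == 0.0 else _pinnate_union(p)
    pts = _resample_closed(_exterior(union), BLADE_VERTICES)
    if p.base_aspect != 1.0:
        pts = pts * np.array([1.0, p.base_aspect])
    pts = _with_noise(pts, p.noise_sd, rng, "compound outline")
    if p.hole:
        ring = _hole_ring(p)
        if p.base_aspect != 1.0:
            ring = ring * np.array([1.0, p.base_aspect])
        if p.noise_sd:
            ring = ring + rng.normal(0.0, p.noise_sd, size=ring.shape)
        pts = _stitch_ring(pts, ring)
    return Contour(points=pts, id="compound")


def generate_leaf(p: LeafParams, rng: np.random.Generator | None = None) -> Contour:
    """Dispatch on leaflet_count: simple blade or compound outline."""
    if p.leaflet_count == 1:
        return generate_blade(p, rng=rng)
    return generate_compound(p, rng=rng)


def _jittered(p: LeafParams, rng: np.random.Generator) -> LeafParams:
    """Per-instance variation: multiplicative jitter of depth/aspect/serration."""
    scale = lambda lo_hi: 1.0 + lo_hi * rng.uniform(-1.0, 1.0)  # noqa: E731
    return dataclasses.replace(
        p,
        lobe_depth=min(p.lobe_depth * scale(0.15), 0.89),
        base_aspect=max(p.base_aspect * scale(0.10), 1.0),
        serration_amp=min(p.serration_amp * scale(0.15), 0.19),
    )


def generate_dataset(
    classes: Mapping[str, LeafParams],
    n_per_class: int,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[Contour], pd.DataFrame]:
    """Generate ``n_per_class`` jittered instances of every class.

    Instance ``i`` of class ``ci`` uses the derived seed
    ``seed + ci * n_per_class + i`` for both parameter jitter and noise, so
    a fixed master seed reproduces every file byte for byte.  When
    ``out_dir`` is given, contour files (``<class>_<i>.txt``) and
    ``manifest.csv`` (columns id, family) are written in the plain-text
    layout that :mod:`phyllo.contour_io` reads.

    Returns the contours (family set to the class name) and the manifest.
    """
    if len(classes) < 2:
        raise ConfigurationError("need at least 2 classes")
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    contours: list[Contour] = []
    records: list[dict] = []
    for ci, (name, params) in enumerate(classes.items()):
        for i in range(n_per_class):
            instance_seed = seed + ci * n_per_class + i
            rng = np.random.default_rng(instance_seed)
            jp = _jittered(params, rng)
            leaf = generate_leaf(jp, rng=rng)
            leaf_id = f"{name}_{i:03d}"
            contours.append(
                Contour(points=leaf.points, id=leaf_id, family=name)
            )
            records.append({"id": leaf_id, "family": name})
    manifest = pd.DataFrame.from_records(records).set_index("id")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for leaf in contours:
            write_contour_file(leaf, out_dir / f"{leaf.id}.txt")
        manifest.reset_index().to_csv(out_dir / "manifest.csv", index=False)
    return contours, manifest


#: Named class collections.  ``four-class`` spans the archetypes the
#: descriptor is meant to separate: an entire elongated blade, a deeply
#: lobed blade, a serrated blade, and a palmately compound leaf.  The
#: noise level (sd 0.002 on roughly unit-radius outlines, about half a
#: pixel at the default raster resolution) emulates digitization jitter.
PRESETS: dict[str, dict[str, LeafParams]] = {
    "four-class": {
        "entire": LeafParams(base_aspect=2.0, noise_sd=0.002),
        "lobed": LeafParams(lobe_count=5, lobe_depth=0.5, noise_sd=0.002),
        "serrated": LeafParams(
            base_aspect=1.5, serration_freq=24, serration_amp=0.12, noise_sd=0.002
        ),
        "compound": LeafParams(leaflet_count=5, noise_sd=0.002),
    },
    "two-class": {
        "entire": LeafParams(base_aspect=1.5, noise_sd=0.002),
        "lobed7": LeafParams(lobe_count=7, lobe_depth=0.55, noise_sd=0.002),
    },
}
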