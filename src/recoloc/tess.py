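"""Voronoi tessellation of a reference channel in 2D or 3D.

Each reference localization seeds one Voronoi region. Regions that reach to
infinity ("edge" regions, equivalently regions of seeds on the convex hull of
the cloud) are flagged unbounded and carry infinite measure; bounded regions
get their polygon area (2D, nm^2) or convex polytope volume (3D, nm^3).
Adjacency is the set of seed pairs sharing a Voronoi facet, i.e. the Delaunay
graph, and the per-seed mean distance to adjacent seeds (``nnd``) serves as a
one-dimensional local-density proxy: dense neighbourhoods give small cells and
small nnd.

Because the analysed field is finite, edge handling matters: a Voronoi region
is a subset of the imaged field. Truly infinite cells are discarded, and
finite cells that spill outside the analysis bounds (cells of near-edge
seeds, whose far Voronoi vertices are artefacts of the missing data beyond
the field) are *clipped* to the bounds: ``measure`` is the measure of
cell ∩ bounds, the area a uniformly-spread primary could actually occupy,
while ``measure_full`` keeps the raw hull measure. Without the clipping the
expected-count denominator counts area no primary can reach and the
uniform-field null is badly biased. The default bounds are the axis-aligned
bounding box of the seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError, Voronoi

from .errors import DegenerateGeometryError, EmptyAnalysisError, ParameterError
from .io import LocalizationSet

__all__ = [
    "Tessellation",
    "tessellate",
    "mean_neighbor_distance",
    "included_regions",
    "export_regions",
]


@dataclass
class Tessellation:
    """Per-region geometry of a Voronoi tessellation of the reference seeds.

    Attributes
    ----------
    seeds
        The reference localization set (possibly deduplicated).
    bounded
        Boolean flag per region; unbounded regions have at least one vertex
        at infinity.
    measure
        Area (2D) or volume (3D) of the region *within the analysis bounds*,
        in nm^2 / nm^3; ``inf`` for unbounded regions. This is the measure
        entering the expected-count formula.
    measure_full
        Raw measure of the full (unclipped) Voronoi cell; equals ``measure``
        for cells entirely inside the bounds.
    vertices
        Per-region array of Voronoi vertex coordinates (bounded regions only;
        ``None`` for unbounded).
    inside
        Boolean flag per region: all Voronoi vertices within the analysis
        bounds (vacuously False for unbounded regions).
    neighbors
        Per-region sorted index array of Voronoi-adjacent seeds.
    nnd
        Per-region mean Euclidean distance (nm) from the seed to its adjacent
        seeds, including seeds of unbounded regions.
    bounds
        ``(2, d)`` (min, max) analysis bounds used for the edge discard.
    roi_measure
        Optional override for the total analysed measure (ROI area/volume).
    """

    seeds: LocalizationSet
    bounded: np.ndarray
    measure: np.ndarray
    measure_full: np.ndarray
    vertices: list
    inside: np.ndarray
    neighbors: list
    nnd: np.ndarray
    bounds: np.ndarray
    roi_measure: float | None = None
    _voronoi: Voronoi | None = field(default=None, repr=False)

    @property
    def n_regions(self) -> int:
        return len(self.bounded)

    @property
    def dim(self) -> int:
        return self.seeds.dim

    @property
    def included_mask(self) -> np.ndarray:
        """Regions entering the enrichment analysis: bounded cells with a
        positive in-bounds measure."""
        return self.bounded & np.isfinite(self.measure) & (self.measure > 0)

    @property
    def total_measure(self) -> float:
        """Total analysed measure: ROI override if set, else the sum of
        included-region measures."""
        if self.roi_measure is not None:
            return float(self.roi_measure)
        return float(self.measure[self.included_mask].sum())


def tessellate(
    reference: LocalizationSet,
    dedupe: bool = False,
    roi_measure: float | None = None,
    bounds: np.ndarray | None = None,
) -> Tessellation:
    """Voronoi-tessellate the reference species.

    Parameters
    ----------
    reference
        Seed localizations; needs at least ``d + 2`` non-degenerate points.
    dedupe
        Merge exact duplicate seeds instead of raising. Duplicates usually
        indicate uncorrected multi-blinking, which should be fixed upstream,
        so the default is to refuse them.
    roi_measure
        ROI area/volume (nm^2 or nm^3) overriding the total analysed measure.
    bounds
        ``(2, d)`` (min, max) corners of the analysed field; bounded regions
        are clipped to it for their analysis measure. Defaults to the
        bounding box of the seeds.

    Raises
    ------
    DegenerateGeometryError
        For collinear/coplanar seeds or (without ``dedupe``) duplicates.
    """
    pts = reference.coords
    d = pts.shape[1]
    uniq, first = np.unique(pts, axis=0, return_index=True)
    if uniq.shape[0] < pts.shape[0]:
        if not dedupe:
            raise DegenerateGeometryError(
                f"{pts.shape[0] - uniq.shape[0]} duplicate seeds; correct "
                "multi-blinking upstream or pass dedupe=True"
            )
        pts = pts[np.sort(first)]
        reference = LocalizationSet(
            pts, channel_label=reference.channel_label, image_id=reference.image_id
        )
    if pts.shape[0] < d + 2:
        raise DegenerateGeometryError(
            f"need at least {d + 2} seeds for a {d}D tessellation, got {pts.shape[0]}"
        )
    if roi_measure is not None and roi_measure <= 0:
        raise ParameterError("roi_measure must be positive")
    try:
        vor = Voronoi(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate seed geometry: {exc}") from exc

    if bounds is None:
        bounds = np.vstack([pts.min(axis=0), pts.max(axis=0)])
    else:
        bounds = np.asarray(bounds, dtype=float)
        if bounds.shape != (2, d):
            raise ParameterError(f"bounds must have shape (2, {d})")
    # tolerance so vertices exactly on the field boundary count as inside
    tol = 1e-9 * float(np.max(bounds[1] - bounds[0]))

    n = pts.shape[0]
    bounded = np.zeros(n, dtype=bool)
    measure = np.full(n, np.inf)
    measure_full = np.full(n, np.inf)
    inside = np.zeros(n, dtype=bool)
    vertices: list = [None] * n
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if len(region) == 0 or -1 in region:
            continue
        verts = vor.vertices[region]
        # Voronoi cells are convex, so the hull measure is exact.
        try:
            hull = ConvexHull(verts)
        except QhullError as exc:  # flat cell: numerically degenerate
            raise DegenerateGeometryError(
                f"degenerate Voronoi cell for seed {i}: {exc}"
            ) from exc
        bounded[i] = True
        measure_full[i] = hull.volume
        vertices[i] = verts
        inside[i] = bool(
            np.all(verts >= bounds[0] - tol) and np.all(verts <= bounds[1] + tol)
        )
        if inside[i]:
            measure[i] = hull.volume
        else:
            measure[i] = _clip_measure(hull, verts, pts[i], bounds, tol)

    neighbors: list = [[] for _ in range(n)]
    for a, b in vor.ridge_points:
        neighbors[a].append(b)
        neighbors[b].append(a)
    neighbors = [np.array(sorted(set(nb)), dtype=int) for nb in neighbors]
    nnd = np.array(
        [
            np.linalg.norm(pts[nb] - pts[i], axis=1).mean() if len(nb) else np.nan
            for i, nb in enumerate(neighbors)
        ]
    )
    return Tessellation(
        seeds=reference,
        bounded=bounded,
        measure=measure,
        measure_full=measure_full,
        vertices=vertices,
        inside=inside,
        neighbors=neighbors,
        nnd=nnd,
        bounds=bounds,
        roi_measure=roi_measure,
        _voronoi=vor,
    )


def _clip_measure(
    hull: ConvexHull,
    verts: np.ndarray,
    seed: np.ndarray,
    bounds: np.ndarray,
    tol: float,
) -> float:
    """Measure of a bounded convex Voronoi cell intersected with the
    axis-aligned analysis bounds.

    2D uses shapely polygon intersection; 3D intersects the cell's facet
    halfspaces with the six box planes around the seed (which lies strictly
    inside both for any non-hull seed). Returns 0.0 — excluding the cell —
    when the seed sits on the box boundary or the intersection is
    numerically degenerate.
    """
    d = verts.shape[1]
    lo, hi = bounds
    if np.any(seed <= lo + tol) or np.any(seed >= hi - tol):
        return 0.0
    if d == 2:
        import shapely

        poly = shapely.Polygon(verts[hull.vertices])
        clipped = poly.intersection(shapely.box(lo[0], lo[1], hi[0], hi[1]))
        return float(clipped.area)
    box_planes = np.zeros((2 * d, d + 1))
    for k in range(d):
        box_planes[2 * k, k] = 1.0
        box_planes[2 * k, d] = -hi[k]
        box_planes[2 * k + 1, k] = -1.0
        box_planes[2 * k + 1, d] = lo[k]
    halfspaces = np.vstack([hull.equations, box_planes])
    try:
        hs = HalfspaceIntersection(halfspaces, seed)
        return float(ConvexHull(hs.intersections).volume)
    except QhullError:
        return 0.0


def mean_neighbor_distance(tess: Tessellation) -> np.ndarray:
    """Per-region mean distance (nm) from the seed to its Voronoi-adjacent
    seeds. Adjacency to seeds of unbounded regions counts."""
    return tess.nnd


def included_regions(tess: Tessellation) -> np.ndarray:
    """Indices of regions entering the enrichment analysis after the edge
    discard: bounded cells with positive in-bounds measure."""
    idx = np.flatnonzero(tess.included_mask)
    if idx.size == 0:
        raise EmptyAnalysisError("no included Voronoi regions; field too sparse")
    return idx


def export_regions(tess: Tessellation, re_scores: np.ndarray | None = None):
    """Region table: seed index and coordinates, boundedness, measure, nnd,
    and (when provided) the RE score. Returns a pandas DataFrame."""
    import pandas as pd

    cols = {"region": np.arange(tess.n_regions)}
    for k, name in enumerate(["x", "y", "z"][: tess.dim]):
        cols[name] = tess.seeds.coords[:, k]
    cols["bounded"] = tess.bounded
    cols["included"] = tess.included_mask
    cols["measure"] = tess.measure
    cols["nnd"] = tess.nnd
    if re_scores is not None:
        cols["re"] = re_scores
    return pd.DataFrame(cols)
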