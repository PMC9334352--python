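"""RE-colour-coded maps and enrichment-profile plots.

Colour maps RE on a diverging scale whose centre is exactly RE = 1, symmetric
in log space so a two-fold enrichment and a two-fold depletion sit equally
far from centre. Colour limits default to the 2nd–98th percentile of
log2(RE), clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import PolyCollection
from matplotlib.colors import Normalize
from scipy.stats import gaussian_kde

from .errors import DimensionalityError, ParameterError
from .io import LocalizationSet
from .stats import ConditionProfile
from .tess import Tessellation

__all__ = [
    "RenderSpec",
    "render_region_map",
    "render_point_map",
    "plot_profile",
    "depth_profile",
]


@dataclass
class RenderSpec:
    """Rendering options shared by the map plots."""

    cmap: str = "coolwarm"
    clim: tuple | None = None  # (lo, hi) in RE units; None = percentile default
    clip_percentiles: tuple = (2.0, 98.0)
    dpi: int = 150
    point_size: float = 2.0
    title: str = ""


def _log_norm(re: np.ndarray, spec: RenderSpec) -> Normalize:
    """Symmetric-in-log normalization centred at RE = 1 (log2 RE = 0)."""
    with np.errstate(divide="ignore"):
        logre = np.log2(np.asarray(re, dtype=float))
    logre = logre[np.isfinite(logre)]
    if spec.clim is not None:
        lo, hi = np.log2(spec.clim[0]), np.log2(spec.clim[1])
    elif logre.size:
        lo, hi = np.percentile(logre, spec.clip_percentiles)
    else:
        lo, hi = -1.0, 1.0
    half = max(abs(lo), abs(hi), 1e-6)
    return Normalize(vmin=-half, vmax=half, clip=True)


def _log_colors(re: np.ndarray, spec: RenderSpec):
    norm = _log_norm(re, spec)
    with np.errstate(divide="ignore"):
        logre = np.log2(np.asarray(re, dtype=float))
    logre = np.where(np.isfinite(logre), logre, norm.vmin)
    return plt.get_cmap(spec.cmap)(norm(logre)), norm


def _save(fig, path: str | Path, spec: RenderSpec) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=spec.dpi)
    plt.close(fig)
    return path


def render_region_map(
    tess: Tessellation,
    re: np.ndarray,
    path: str | Path,
    spec: RenderSpec | None = None,
) -> Path:
    """Filled Voronoi polygons coloured by RE; unbounded regions omitted.

    2D only — for 3D data use :func:`render_point_map`."""
    if tess.dim != 2:
        raise DimensionalityError(
            "polygon maps are 2D only; use render_point_map for 3D data"
        )
    spec = spec or RenderSpec()
    idx = np.flatnonzero(tess.included_mask)
    colors, norm = _log_colors(np.asarray(re)[idx], spec)
    polys = [tess.vertices[i][_ccw_order(tess.vertices[i])] for i in idx]
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.add_collection(PolyCollection(polys, facecolors=colors, edgecolors="0.6", lw=0.2))
    ax.autoscale_view()
    ax.set_aspect("equal")
    ax.set_xlabel("x (nm)")
    ax.set_ylabel("y (nm)")
    ax.set_title(spec.title or "Voronoi regions coloured by RE")
    _add_re_colorbar(fig, ax, norm, spec)
    return _save(fig, path, spec)


def _ccw_order(verts: np.ndarray) -> np.ndarray:
    c = verts.mean(axis=0)
    return np.argsort(np.arctan2(verts[:, 1] - c[1], verts[:, 0] - c[0]))


def _add_re_colorbar(fig, ax, norm, spec) -> None:
    sm = plt.cm.ScalarMappable(norm=norm, cmap=spec.cmap)
    cb = fig.colorbar(sm, ax=ax, fraction=0.046)
    ticks = cb.get_ticks()
    cb.set_ticks(ticks)
    cb.set_ticklabels([f"{2**t:.2g}" for t in ticks])
    cb.set_label("RE (log scale, centre = 1)")


def render_point_map(
    points: LocalizationSet,
    re: np.ndarray,
    path: str | Path,
    spec: RenderSpec | None = None,
    view: str = "top",
) -> Path:
    """Scatter of reference localizations coloured by their region's RE.

    ``view`` selects the projection for 3D data: ``top`` (x–y) or ``side``
    (x–z, depth on the vertical axis).
    """
    re = np.asarray(re, dtype=float)
    if re.shape[0] != points.n:
        raise ParameterError("one RE value per localization required")
    spec = spec or RenderSpec()
    if view == "top" or points.dim == 2:
        xy = points.coords[:, :2]
        ylab = "y (nm)"
    elif view == "side":
        if points.dim != 3:
            raise DimensionalityError("side view requires 3D data")
        xy = points.coords[:, [0, 2]]
        ylab = "z (nm)"
    else:
        raise ParameterError(f"unknown view {view!r}")
    colors, norm = _log_colors(re, spec)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(xy[:, 0], xy[:, 1], c=colors, s=spec.point_size, linewidths=0)
    ax.set_aspect("equal")
    ax.set_xlabel("x (nm)")
    ax.set_ylabel(ylab)
    ax.set_title(spec.title or f"{points.channel_label} coloured by RE")
    _add_re_colorbar(fig, ax, norm, spec)
    return _save(fig, path, spec)


def plot_profile(
    cond_profiles: list[ConditionProfile],
    path: str | Path,
    spec: RenderSpec | None = None,
    significant: np.ndarray | None = None,
) -> Path:
    """Mean-RE line(s) with SEM band (left axis), region-fraction histogram
    (right axis), dashed guide at RE = 1, optional per-bin significance bar.
    """
    if not cond_profiles:
        raise ParameterError("need at least one condition profile")
    edges = cond_profiles[0].bin_edges
    for p in cond_profiles[1:]:
        if not np.array_equal(p.bin_edges, edges):
            raise ParameterError("profiles must share bin edges")
    spec = spec or RenderSpec()
    centers = cond_profiles[0].bin_centers
    width = np.diff(edges)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax2 = ax.twinx()
    ax2.bar(
        centers,
        np.mean([p.region_fraction for p in cond_profiles], axis=0),
        width=width,
        color="0.85",
        zorder=0,
    )
    for p in cond_profiles:
        (line,) = ax.plot(centers, p.mean_re, lw=1.5, label=p.condition or None, zorder=3)
        ok = np.isfinite(p.sem_re)
        ax.fill_between(
            centers[ok],
            (p.mean_re - p.sem_re)[ok],
            (p.mean_re + p.sem_re)[ok],
            alpha=0.3,
            color=line.get_color(),
            zorder=2,
        )
    ax.axhline(1.0, ls="--", color="k", lw=0.8, zorder=1)
    if significant is not None:
        sig = np.asarray(significant, dtype=bool)
        ymax = ax.get_ylim()[1]
        ax.plot(centers[sig], np.full(sig.sum(), ymax), "k_", ms=8)
    ax.set_xlabel("mean neighbour distance (nm)")
    ax.set_ylabel("mean RE")
    ax2.set_ylabel("relative bin distribution")
    ax.set_zorder(ax2.get_zorder() + 1)
    ax.patch.set_visible(False)
    if any(p.condition for p in cond_profiles):
        ax.legend(frameon=False)
    if spec.title:
        ax.set_title(spec.title)
    return _save(fig, path, spec)


def depth_profile(
    sets: list[LocalizationSet],
    path: str | Path,
    normalization: LocalizationSet | None = None,
    spec: RenderSpec | None = None,
) -> Path:
    """Smoothed z-density per species, with depth shifted so the reference
    species' modal depth is 0."""
    if not sets:
        raise ParameterError("need at least one localization set")
    for s in sets:
        if s.dim != 3:
            raise DimensionalityError("depth profiles require 3D data")
    ref = normalization or sets[0]
    if ref.dim != 3:
        raise DimensionalityError("normalization set must be 3D")
    spec = spec or RenderSpec()
    grid = np.linspace(
        min(s.coords[:, 2].min() for s in sets),
        max(s.coords[:, 2].max() for s in sets),
        512,
    )
    mode = grid[np.argmax(gaussian_kde(ref.coords[:, 2])(grid))]
    fig, ax = plt.subplots(figsize=(6, 4))
    for s in sets:
        ax.plot(grid - mode, gaussian_kde(s.coords[:, 2])(grid), label=s.channel_label)
    ax.axvline(0.0, ls="--", color="k", lw=0.8)
    ax.set_xlabel("depth relative to reference mode (nm)")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    if spec.title:
        ax.set_title(spec.title)
    return _save(fig, path, spec)
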