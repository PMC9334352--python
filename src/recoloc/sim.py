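"""Synthetic localization scenes for validation and demonstration.

Scenes mimic the point output of dual-colour SMLM: uniform random fields,
offset Gaussian clusters over uniform background, anti-colocalized clusters,
duplicated point sets, a clustered-versus-uniform pair, and a 3D
docked-vesicle scene with three species (vesicle membrane, active-zone-like
cluster on the coverslip plane, lumenal cargo). Coordinates are nm. Every
generator stores its ground truth (cluster centres, vesicle centres, docked
flags, unjittered positions) alongside the coordinates so tests can compare
samples against the generating parameters.

All randomness flows through ``numpy.random.default_rng(rng_seed)``: equal
seeds and configs give bit-identical scenes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DimensionalityError, GenerationError, ParameterError
from .io import LocalizationSet, write_localizations

__all__ = [
    "SceneConfig",
    "VesicleSceneConfig",
    "Scene",
    "VesicleScene",
    "simulate_scene",
    "simulate_vesicle_scene",
    "project_to_2d",
    "write_scene",
]

SCENE_KINDS = (
    "uniform",
    "offset_clusters",
    "anticolocalized_clusters",
    "identical",
    "clustered_vs_uniform",
    "vesicle_scene",
)


@dataclass
class SceneConfig:
    """Parameters of a simulated two-species scene.

    Cluster scenes draw ``n_points`` per species: a ``background_fraction``
    share uniform over the extent, the rest split evenly over ``n_clusters``
    isotropic Gaussian clusters of standard deviation ``cluster_sd`` (fixed
    per-cluster counts by default; set ``poisson_counts`` for Poisson). For
    ``offset_clusters`` the primary's cluster centres are the reference's
    shifted by ``offset``; for ``anticolocalized_clusters`` they are
    rejection-sampled at least ``exclusion`` (default 4×sd) from every
    reference centre. ``extent`` is the box side length per axis in nm, with
    origin 0.
    """

    kind: str = "uniform"
    extent: tuple = (5000.0, 5000.0)
    n_points: int = 5000
    n_clusters: int = 10
    cluster_sd: float = 50.0
    offset: tuple = (0.0, 0.0)
    background_fraction: float = 0.5
    exclusion: float | None = None
    poisson_counts: bool = False
    jitter_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SCENE_KINDS:
            raise ParameterError(f"unknown scene kind {self.kind!r}")
        if any(e <= 0 for e in self.extent):
            raise ParameterError("extent must be strictly positive per axis")
        if self.n_points <= 0 or self.n_clusters <= 0:
            raise ParameterError("counts must be positive")
        if self.cluster_sd <= 0:
            raise ParameterError("cluster_sd must be positive")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ParameterError("background_fraction must lie in [0, 1]")
        if len(self.offset) != len(self.extent):
            raise ParameterError("offset must match extent dimensionality")


@dataclass
class Scene:
    reference: LocalizationSet
    primary: LocalizationSet
    config: SceneConfig
    ground_truth: dict = field(default_factory=dict)


@dataclass
class VesicleSceneConfig:
    """Docked-vesicle scene: three species around ``n_vesicles`` spherical
    vesicles over a flat membrane plane.

    A ``fraction_docked`` share of vesicles touch the plane (centre at
    ``membrane_plane_z + vesicle_radius``) and each carries an active-zone
    (AZ) cluster of ``az_cluster_size`` points, Gaussian in-plane with
    ``az_cluster_sd``, directly beneath it; undocked vesicle centres float
    strictly above the plane. Membrane points are uniform on each vesicle
    sphere, cargo uniform in each lumen. Anisotropic Gaussian jitter
    emulates localization uncertainty; the z jitter defaults to twice xy,
    matching the poorer axial precision of astigmatic 3D SMLM.
    """

    n_vesicles: int = 20
    fraction_docked: float = 0.5
    vesicle_radius: float = 20.0
    points_per_vesicle_membrane: int = 60
    points_per_lumen: int = 40
    az_cluster_size: int = 50
    az_cluster_sd: float = 10.0
    extent_xy: float = 1000.0
    membrane_plane_z: float = 0.0
    undocked_z_max: float = 200.0
    jitter_sd_xy: float = 5.0
    jitter_sd_z: float | None = None  # default: 2 × jitter_sd_xy
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_docked <= 1.0:
            raise ParameterError("fraction_docked must lie in [0, 1]")
        if self.n_vesicles <= 0 or self.vesicle_radius <= 0:
            raise ParameterError("n_vesicles and vesicle_radius must be positive")
        if self.jitter_sd_z is None:
            self.jitter_sd_z = 2.0 * self.jitter_sd_xy


@dataclass
class VesicleScene:
    membrane: LocalizationSet
    az: LocalizationSet
    cargo: LocalizationSet
    config: VesicleSceneConfig
    ground_truth: dict = field(default_factory=dict)


def _uniform(rng: np.random.Generator, n: int, extent) -> np.ndarray:
    extent = np.asarray(extent, dtype=float)
    return rng.uniform(0.0, extent, size=(n, extent.size))


def _cluster_field(
    rng: np.random.Generator, cfg: SceneConfig, centers: np.ndarray
) -> np.ndarray:
    """Gaussian clusters at the given centres plus uniform background,
    clipped back into the extent by reflection."""
    n_bg = int(round(cfg.background_fraction * cfg.n_points))
    n_cl = cfg.n_points - n_bg
    if cfg.poisson_counts:
        per = rng.poisson(n_cl / cfg.n_clusters, size=cfg.n_clusters)
    else:
        per = np.full(cfg.n_clusters, n_cl // cfg.n_clusters)
        per[: n_cl % cfg.n_clusters] += 1
    pts = [
        centers[i] + rng.normal(0.0, cfg.cluster_sd, size=(per[i], centers.shape[1]))
        for i in range(cfg.n_clusters)
    ]
    pts.append(_uniform(rng, n_bg, cfg.extent))
    out = np.vstack(pts)
    extent = np.asarray(cfg.extent, dtype=float)
    # reflect stray cluster tails back into the box
    out = np.abs(out)
    out = extent - np.abs(extent - out)
    return out


def _cluster_centers(
    rng: np.random.Generator, cfg: SceneConfig, margin: float
) -> np.ndarray:
    extent = np.asarray(cfg.extent, dtype=float)
    lo = np.minimum(margin, extent / 2)
    return rng.uniform(lo, extent - lo, size=(cfg.n_clusters, extent.size))


def simulate_scene(config: SceneConfig) -> Scene:
    """Generate a two-species scene according to ``config.kind``.

    Returns a :class:`Scene` whose ``ground_truth`` holds the generating
    cluster centres (where applicable).
    """
    if config.kind == "vesicle_scene":
        raise ParameterError("use simulate_vesicle_scene for the vesicle scene")
    rng = np.random.default_rng(config.rng_seed)
    gt: dict = {}
    margin = 3.0 * config.cluster_sd

    if config.kind == "uniform":
        ref = _uniform(rng, config.n_points, config.extent)
        prim = _uniform(rng, config.n_points, config.extent)
    elif config.kind == "identical":
        ref = _uniform(rng, config.n_points, config.extent)
        prim = ref.copy()
    elif config.kind == "offset_clusters":
        centers = _cluster_centers(rng, config, margin)
        ref = _cluster_field(rng, config, centers)
        prim_centers = centers + np.asarray(config.offset, dtype=float)
        prim = _cluster_field(rng, config, prim_centers)
        gt = {"ref_centers": centers, "primary_centers": prim_centers}
    elif config.kind == "anticolocalized_clusters":
        centers = _cluster_centers(rng, config, margin)
        ref = _cluster_field(rng, config, centers)
        excl = 4.0 * config.cluster_sd if config.exclusion is None else config.exclusion
        prim_centers = np.empty_like(centers)
        for i in range(config.n_clusters):
            for attempt in range(10_000):
                cand = _cluster_centers(rng, config, margin)[0]
                if np.min(np.linalg.norm(centers - cand, axis=1)) >= excl:
                    prim_centers[i] = cand
                    break
            else:
                raise GenerationError(
                    f"could not place anti-colocalized cluster {i}: exclusion "
                    f"distance {excl} nm infeasible in extent {config.extent}"
                )
        prim = _cluster_field(rng, config, prim_centers)
        gt = {"ref_centers": centers, "primary_centers": prim_centers}
    elif config.kind == "clustered_vs_uniform":
        centers = _cluster_centers(rng, config, margin)
        ref = _cluster_field(rng, config, centers)
        prim = _uniform(rng, config.n_points, config.extent)
        gt = {"ref_centers": centers}
    else:  # pragma: no cover
        raise ParameterError(f"unknown scene kind {config.kind!r}")

    if config.jitter_sd > 0:
        gt["ref_true"], gt["primary_true"] = ref.copy(), prim.copy()
        ref = ref + rng.normal(0.0, config.jitter_sd, size=ref.shape)
        prim = prim + rng.normal(0.0, config.jitter_sd, size=prim.shape)

    return Scene(
        reference=LocalizationSet(ref, channel_label="reference", image_id="sim"),
        primary=LocalizationSet(prim, channel_label="primary", image_id="sim"),
        config=config,
        ground_truth=gt,
    )


def _sphere_points(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform unit-sphere surface samples (normalized Gaussian deviates)."""
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def simulate_vesicle_scene(config: VesicleSceneConfig) -> VesicleScene:
    """Generate the three-species docked-vesicle scene in 3D."""
    rng = np.random.default_rng(config.rng_seed)
    r = config.vesicle_radius
    n_dock = int(round(config.fraction_docked * config.n_vesicles))

    # vesicle centres: rejection-sample xy with minimal separation so
    # vesicles do not interpenetrate
    min_sep = 2.0 * r + 10.0
    centers_xy = np.empty((config.n_vesicles, 2))
    placed = 0
    for attempt in range(100_000):
        cand = rng.uniform(r, config.extent_xy - r, size=2)
        if placed == 0 or np.min(
            np.linalg.norm(centers_xy[:placed] - cand, axis=1)
        ) >= min_sep:
            centers_xy[placed] = cand
            placed += 1
            if placed == config.n_vesicles:
                break
    if placed < config.n_vesicles:
        raise GenerationError(
            f"could not place {config.n_vesicles} vesicles with separation "
            f"{min_sep} nm in a {config.extent_xy} nm field"
        )
    docked = np.zeros(config.n_vesicles, dtype=bool)
    docked[rng.choice(config.n_vesicles, size=n_dock, replace=False)] = True
    z = np.where(
        docked,
        config.membrane_plane_z + r,
        config.membrane_plane_z
        + rng.uniform(r + 10.0, config.undocked_z_max, size=config.n_vesicles),
    )
    centers = np.column_stack([centers_xy, z])

    membrane, cargo = [], []
    for c in centers:
        membrane.append(c + r * _sphere_points(rng, config.points_per_vesicle_membrane))
        radii = r * rng.uniform(size=config.points_per_lumen) ** (1.0 / 3.0)
        cargo.append(c + radii[:, None] * _sphere_points(rng, config.points_per_lumen))
    membrane = np.vstack(membrane)
    cargo = np.vstack(cargo)

    az = []
    for c in centers[docked]:
        xy = c[:2] + rng.normal(0.0, config.az_cluster_sd, size=(config.az_cluster_size, 2))
        az.append(
            np.column_stack([xy, np.full(config.az_cluster_size, config.membrane_plane_z)])
        )
    if not az:
        raise GenerationError("no docked vesicles: the AZ species would be empty")
    az = np.vstack(az)

    gt = {
        "centers": centers,
        "docked": docked,
        "membrane_true": membrane.copy(),
        "az_true": az.copy(),
        "cargo_true": cargo.copy(),
    }
    sd = np.array([config.jitter_sd_xy, config.jitter_sd_xy, config.jitter_sd_z])
    membrane = membrane + rng.normal(0.0, sd, size=membrane.shape)
    az = az + rng.normal(0.0, sd, size=az.shape)
    cargo = cargo + rng.normal(0.0, sd, size=cargo.shape)

    mk = lambda pts, label: LocalizationSet(pts, channel_label=label, image_id="sim")
    return VesicleScene(
        membrane=mk(membrane, "vesicle_membrane"),
        az=mk(az, "az"),
        cargo=mk(cargo, "cargo"),
        config=config,
        ground_truth=gt,
    )


def project_to_2d(points: LocalizationSet) -> LocalizationSet:
    """Drop the z coordinate of a 3D set, emulating a 2D acquisition."""
    if points.dim != 3:
        raise DimensionalityError("project_to_2d requires a 3D localization set")
    return LocalizationSet(
        points.coords[:, :2],
        channel_label=points.channel_label,
        image_id=points.image_id,
    )


def write_scene(scene: Scene | VesicleScene, outdir: str | Path) -> None:
    """Write each species as a localization CSV plus a JSON sidecar holding
    the config and ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(scene, VesicleScene):
        species = {"membrane": scene.membrane, "az": scene.az, "cargo": scene.cargo}
    else:
        species = {"reference": scene.reference, "primary": scene.primary}
    for name, locs in species.items():
        write_localizations(outdir / f"{name}.csv", locs)
    sidecar = {
        "config": dataclasses.asdict(scene.config),
        "ground_truth": {
            k: np.asarray(v).tolist() for k, v in scene.ground_truth.items()
        },
    }
    (outdir / "scene.json").write_text(json.dumps(sidecar, indent=1))
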