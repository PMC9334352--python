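"""Per-region relative enrichment and density-binned enrichment profiles.

The relative enrichment (RE) of a bounded reference region is the ratio of
the observed number of primary localizations inside it to the number expected
if the retained primaries were spread uniformly over the analysed area:

    expected_r = (measure_r / total_measure) * n_primary_retained
    RE_r       = observed_r / expected_r

Edge regions — unbounded cells and cells spilling outside the analysed
field — and the primaries falling in them are discarded before anything is
counted, which makes the conservation identity exact: the
measure-weighted mean RE over included regions equals 1 whenever the total
measure is the sum of included-region measures (no ROI override). RE = 1 is
the random expectation; above 1 enrichment, below 1 depletion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import DimensionalityError, EmptyInputError, ParameterError
from .io import LocalizationSet
from .tess import Tessellation, included_regions

logger = logging.getLogger(__name__)

__all__ = [
    "RegionEnrichment",
    "EnrichmentProfile",
    "assign_primaries",
    "expected_counts",
    "expected_from_measures",
    "relative_enrichment",
    "compute_enrichment",
    "build_profile",
    "default_bin_edges",
    "dense_region_summary",
]


@dataclass
class RegionEnrichment:
    """Per-region observed and expected primary counts and RE scores.

    Arrays are full-length over all regions; unbounded regions carry NaN
    expected/RE. ``n_primary_retained`` is the primary count surviving the
    edge discard, used as the total in the expected-count formula.
    """

    observed: np.ndarray
    expected: np.ndarray
    re: np.ndarray
    n_primary_retained: int
    n_primary_discarded: int


@dataclass
class EnrichmentProfile:
    """Binned enrichment profile over the reference density distribution.

    ``mean_re`` is the unweighted mean RE of regions in each bin (NaN for
    empty bins — absent, not zero); ``region_fraction`` is each bin's share
    of the regions falling within the binned range (the relative bin
    distribution shown on the right-hand axis of profile plots), so it sums
    to 1 over non-empty bins.
    """

    bin_mode: str
    bin_edges: np.ndarray
    mean_re: np.ndarray
    region_fraction: np.ndarray
    region_count: np.ndarray
    image_id: str = ""

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "mean_re": self.mean_re,
                "region_fraction": self.region_fraction,
                "region_count": self.region_count,
                "image_id": self.image_id,
            }
        )


def assign_primaries(tess: Tessellation, primary: LocalizationSet) -> np.ndarray:
    """Count primaries per reference region by nearest-seed assignment.

    Membership in a seed's Voronoi cell is exactly nearest-seed assignment,
    so a KD-tree query replaces point-in-polygon tests. Primaries exactly
    equidistant from two seeds go to the lower seed index. Counts for
    excluded (edge) regions are returned too; callers discard them via
    ``tess.included_mask``.
    """
    if primary.n == 0:
        raise EmptyInputError("empty primary set")
    if primary.dim != tess.dim:
        raise DimensionalityError(
            f"primary is {primary.dim}D but tessellation is {tess.dim}D"
        )
    tree = cKDTree(tess.seeds.coords)
    k = min(2, tess.n_regions)
    dist, idx = tree.query(primary.coords, k=k)
    if k == 2:
        # deterministic tie-break: lowest seed index among exact ties
        tied = dist[:, 0] == dist[:, 1]
        nearest = idx[:, 0].copy()
        nearest[tied] = np.minimum(idx[tied, 0], idx[tied, 1])
    else:
        nearest = np.atleast_1d(idx)
    return np.bincount(nearest, minlength=tess.n_regions)


def expected_from_measures(
    measures: np.ndarray, total_measure: float, n_primary_total: int
) -> np.ndarray:
    """Expected primary counts for regions of the given measures: each
    region's share of the total analysed measure times the primary total."""
    if total_measure <= 0:
        raise ParameterError("total_measure must be positive")
    return np.asarray(measures, dtype=float) / total_measure * n_primary_total


def expected_counts(tess: Tessellation, n_primary_total: int) -> np.ndarray:
    """Per-region expected primary counts (NaN for excluded regions).

    ``n_primary_total`` must be the primary count remaining after discarding
    primaries in edge regions, so that expected and observed totals agree
    exactly.
    """
    included = included_regions(tess)
    expected = np.full(tess.n_regions, np.nan)
    expected[included] = expected_from_measures(
        tess.measure[included], tess.total_measure, n_primary_total
    )
    return expected


def relative_enrichment(observed: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """RE = observed / expected, elementwise; NaN where expected is NaN."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if np.any(expected[np.isfinite(expected)] <= 0):
        raise ParameterError("expected counts must be positive")
    with np.errstate(invalid="ignore"):
        return observed / expected


def compute_enrichment(tess: Tessellation, primary: LocalizationSet) -> RegionEnrichment:
    """Full per-region enrichment: assign, discard edge primaries, score."""
    counts = assign_primaries(tess, primary)
    retained = int(counts[tess.included_mask].sum())
    discarded = int(primary.n - retained)
    if retained == 0:
        raise EmptyInputError("all primaries fell in discarded edge regions")
    expected = expected_counts(tess, retained)
    observed = counts.astype(float)
    observed[~tess.included_mask] = np.nan
    re = relative_enrichment(observed, expected)
    logger.info(
        "enrichment: %d primaries retained, %d discarded with edge regions",
        retained,
        discarded,
    )
    return RegionEnrichment(
        observed=observed,
        expected=expected,
        re=re,
        n_primary_retained=retained,
        n_primary_discarded=discarded,
    )


def default_bin_edges(
    tess: Tessellation, bin_mode: str = "nnd", n_bins: int = 40
) -> np.ndarray:
    """Default bin edges: uniform on [0, 99th percentile of nnd] for nnd
    mode; uniform in log10(measure) over the included range for log_area."""
    included = included_regions(tess)
    if bin_mode == "nnd":
        hi = np.nanpercentile(tess.nnd[included], 99)
        return np.linspace(0.0, hi, n_bins + 1)
    if bin_mode == "log_area":
        logm = np.log10(tess.measure[included])
        return np.linspace(logm.min(), logm.max(), n_bins + 1)
    raise ParameterError(f"unknown bin_mode {bin_mode!r}")


def build_profile(
    tess: Tessellation,
    re: np.ndarray,
    bin_mode: str = "nnd",
    bin_edges: np.ndarray | None = None,
    n_bins: int = 40,
    image_id: str = "",
) -> EnrichmentProfile:
    """Bin included regions by nnd or log10(measure) and average RE per bin.

    Bin means are unweighted over regions. Regions outside the edge range
    are ignored; empty bins carry NaN. For multi-image studies pass common
    ``bin_edges`` so bins are comparable across images.
    """
    if bin_mode not in ("nnd", "log_area"):
        raise ParameterError(f"unknown bin_mode {bin_mode!r}")
    if bin_edges is None:
        bin_edges = default_bin_edges(tess, bin_mode, n_bins)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.ndim != 1 or bin_edges.size < 2 or np.any(np.diff(bin_edges) <= 0):
        raise ParameterError("bin edges must be strictly increasing")

    included = included_regions(tess)
    values = (
        tess.nnd[included] if bin_mode == "nnd" else np.log10(tess.measure[included])
    )
    re_inc = np.asarray(re, dtype=float)[included]
    nb = bin_edges.size - 1
    which = np.digitize(values, bin_edges) - 1
    # right edge of the last bin is inclusive
    which[values == bin_edges[-1]] = nb - 1
    in_range = (which >= 0) & (which < nb)
    which, re_inc = which[in_range], re_inc[in_range]

    counts = np.bincount(which, minlength=nb)
    sums = np.bincount(which, weights=re_inc, minlength=nb)
    with np.errstate(invalid="ignore"):
        mean_re = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    total_in_range = max(int(counts.sum()), 1)
    return EnrichmentProfile(
        bin_mode=bin_mode,
        bin_edges=bin_edges,
        mean_re=mean_re,
        region_fraction=counts / total_in_range,
        region_count=counts,
        image_id=image_id,
    )


def dense_region_summary(
    tess: Tessellation, re: np.ndarray, nnd_threshold: float
) -> tuple[float | None, int]:
    """Unweighted mean RE over included regions with nnd <= threshold (nm).

    Returns ``(mean_re, n_regions)``; ``(None, 0)`` with a warning when no
    region qualifies.
    """
    included = included_regions(tess)
    mask = tess.nnd[included] <= nnd_threshold
    n = int(mask.sum())
    if n == 0:
        warnings.warn(
            f"no regions with nnd <= {nnd_threshold} nm", stacklevel=2
        )
        return None, 0
    return float(np.asarray(re)[included][mask].mean()), n
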