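"""Cross-image aggregation, per-bin hypothesis tests, and tessellation-based
comparison coefficients.

Profiles are computed per image first and then averaged, so the error bars
reflect image-to-image variability (SEM over images), and per-bin condition
differences are tested with unpaired t-tests by image with Holm step-down
family-wise error control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

from .enrich import EnrichmentProfile
from .errors import ParameterError
from .tess import Tessellation, included_regions

__all__ = [
    "ConditionProfile",
    "aggregate",
    "compare_conditions",
    "coloc_coefficients",
]


@dataclass
class ConditionProfile:
    """Condition-level profile: per-bin mean of per-image bin means, with SEM
    over the images contributing to each bin (NaN when fewer than two)."""

    condition: str
    bin_edges: np.ndarray
    mean_re: np.ndarray
    sem_re: np.ndarray
    n_images: int
    region_fraction: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def aggregate(profiles: list[EnrichmentProfile], condition: str = "") -> ConditionProfile:
    """Average per-image profiles sharing identical bin edges.

    Each bin's mean is the unweighted mean over the images whose profile has
    a value in that bin; SEM = sd / sqrt(n images in bin), ddof=1.
    """
    if not profiles:
        raise ParameterError("need at least one profile")
    edges = profiles[0].bin_edges
    for p in profiles[1:]:
        if not np.array_equal(p.bin_edges, edges):
            raise ParameterError("profiles must share identical bin edges")
    stack = np.vstack([p.mean_re for p in profiles])
    frac = np.vstack([p.region_fraction for p in profiles])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        mean = np.nanmean(stack, axis=0)
        n_in_bin = np.sum(np.isfinite(stack), axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    sem = np.where(n_in_bin >= 2, sd / np.sqrt(np.maximum(n_in_bin, 1)), np.nan)
    return ConditionProfile(
        condition=condition,
        bin_edges=edges,
        mean_re=mean,
        sem_re=sem,
        n_images=len(profiles),
        region_fraction=frac.mean(axis=0),
    )


def compare_conditions(
    a: np.ndarray,
    b: np.ndarray,
    sided: str = "two-sided",
    alpha: float = 0.05,
    labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-bin unpaired t-tests by image with Holm FWER correction.

    Parameters
    ----------
    a, b
        Arrays of shape (n_images, n_bins) of per-image bin values (or 1D
        for a single summary scalar per image). NaN marks an image not
        contributing to a bin.
    sided
        't'wo-sided', 'less' (mean(a) < mean(b)) or 'greater'. One-sided
        tests require this explicit direction; it is never inferred.
    labels
        Optional per-bin labels for the output table.

    Bins with fewer than two images in either condition are skipped with a
    warning and excluded from the correction family.
    """
    if sided not in ("two-sided", "less", "greater"):
        raise ParameterError(f"unknown sidedness {sided!r}")
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] == 1 and a.shape[1] > 1 and b.shape[0] == 1:
        # interpret 1D inputs as one scalar per image
        a, b = a.T, b.T
    nb = max(a.shape[1], b.shape[1])
    if a.shape[1] != b.shape[1]:
        raise ParameterError("conditions must cover the same bins")
    rows = []
    for j in range(nb):
        xa = a[:, j][np.isfinite(a[:, j])]
        xb = b[:, j][np.isfinite(b[:, j])]
        if xa.size < 2 or xb.size < 2:
            warnings.warn(f"bin {j}: fewer than 2 images per condition; skipped")
            rows.append((j, np.nan, np.nan))
            continue
        t, p = sps.ttest_ind(xa, xb, alternative=sided)
        rows.append((j, float(t), float(p)))
    df = pd.DataFrame(rows, columns=["bin", "t", "p_raw"])
    tested = df["p_raw"].notna()
    p_holm = np.full(nb, np.nan)
    signif = np.zeros(nb, dtype=bool)
    if tested.any():
        rej, adj, _, _ = multipletests(
            df.loc[tested, "p_raw"].to_numpy(), alpha=alpha, method="holm"
        )
        p_holm[tested.to_numpy()] = adj
        signif[tested.to_numpy()] = rej
    df["p_holm"] = p_holm
    df["significant"] = signif
    if labels is not None:
        df.insert(1, "label", np.asarray(labels)[df["bin"].to_numpy()])
    return df


def _local_density(tess: Tessellation) -> np.ndarray:
    """First-rank Voronoi density per seed: 1 / cell measure (NaN for
    excluded edge cells)."""
    with np.errstate(divide="ignore"):
        dens = 1.0 / tess.measure
    dens[~tess.included_mask] = np.nan
    return dens


def _one_direction(
    tess_from: Tessellation, tess_to: Tessellation, threshold: float | None
) -> tuple[float, float]:
    """Spearman and Mander's-style coefficients of species *from* against
    the density landscape of species *to*."""
    dens_own = _local_density(tess_from)
    dens_other_all = _local_density(tess_to)
    tree = cKDTree(tess_to.seeds.coords)
    _, host = tree.query(tess_from.seeds.coords)
    dens_other = dens_other_all[host]
    ok = np.isfinite(dens_own) & np.isfinite(dens_other)
    if ok.sum() < 3:
        raise ParameterError("too few paired densities for rank correlation")
    rho = sps.spearmanr(dens_own[ok], dens_other[ok]).statistic
    thr = np.nanmean(dens_other_all) if threshold is None else threshold
    manders = float(np.mean(dens_other[ok] >= thr))
    return float(rho), manders


def coloc_coefficients(
    tessA: Tessellation,
    tessB: Tessellation,
    density_threshold: float | None = None,
) -> dict:
    """Tessellation-based Spearman and Mander's comparison coefficients.

    A benchmarking approximation of coefficients defined elsewhere in the
    literature, provided for side-by-side comparison only — not part of the
    relative-enrichment measure itself. For each localization of species A,
    its own first-rank Voronoi density (1/cell measure) is paired with the
    density of the species-B cell containing it; Spearman is the rank
    correlation of those pairs. The Mander's-style fraction is the share of
    species-A localizations lying in species-B cells whose density exceeds a
    threshold (default: the mean species-B cell density). Both directions are
    reported as ``{"spearman_ab", "manders_ab", "spearman_ba", "manders_ba"}``.
    """
    s_ab, m_ab = _one_direction(tessA, tessB, density_threshold)
    s_ba, m_ba = _one_direction(tessB, tessA, density_threshold)
    return {
        "spearman_ab": s_ab,
        "manders_ab": m_ab,
        "spearman_ba": s_ba,
        "manders_ba": m_ba,
    }
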