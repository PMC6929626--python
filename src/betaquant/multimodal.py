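"""Multimodal PET-MR statistics: VOI handling, block downsampling,
log10 Pearson correlation, Welch t and Wilcoxon rank-sum tests.

The central analysis relates tracer uptake (%ID/mL, beta-cell mass proxy)
to the Mn-driven relaxation rate R1 (beta-cell function proxy) inside a
co-registered pancreas VOI, either on region summaries across animals or
voxel-wise within one region.  Voxel-wise data are block-averaged (factors
2-8 per axis) first to blunt residual co-registration mismatch between the
PET and MR grids.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .volume import ImageVolume

__all__ = [
    "VOIMask",
    "CorrelationResult",
    "TestResult",
    "resample_to_reference",
    "downsample_blocks",
    "summarize_region",
    "correlate",
    "welch_t",
    "rank_sum",
]


@dataclass
class VOIMask:
    mask: np.ndarray
    name: str = "other"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"VOI {self.name!r} is empty")


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    level: str            # "region_mean" | "voxelwise"
    transform: str        # "log10" | "none"
    n_excluded: int = 0   # pairs dropped by the log10 positivity filter


@dataclass
class TestResult:
    statistic: float
    p: float
    test: str
    df: float | None = None
    n1: int = 0
    n2: int = 0


def resample_to_reference(
    volume: ImageVolume,
    transform: np.ndarray,
    reference: ImageVolume,
) -> tuple[ImageVolume, np.ndarray]:
    """Resample ``volume`` onto the grid of ``reference``.

    ``transform`` is a 4x4 rigid/affine matrix mapping source world
    coordinates (mm) to reference world coordinates.  Sampling is trilinear
    in world space; reference voxels whose pre-image falls outside the
    source grid are returned as 0 with validity False.
    """
    transform = np.asarray(transform, dtype=float)
    if transform.shape != (4, 4):
        raise ValueError("transform must be 4x4")
    try:
        inv_t = np.linalg.inv(transform)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular transform") from exc

    # reference voxel index -> source voxel index (both as homogeneous maps)
    full = np.linalg.inv(volume.affine) @ inv_t @ reference.affine
    idx = np.indices(reference.shape, dtype=float).reshape(3, -1)
    src = full[:3, :3] @ idx + full[:3, 3:4]

    shape = np.array(volume.shape, dtype=float)
    eps = 1e-9
    inside = np.all((src >= -eps) & (src <= (shape - 1)[:, None] + eps), axis=0)
    data = ndimage.map_coordinates(
        np.asarray(volume.data, dtype=float), src, order=1, mode="nearest"
    )
    data[~inside] = 0.0
    return (
        reference.with_data(data.reshape(reference.shape), units=volume.units),
        inside.reshape(reference.shape),
    )


def downsample_blocks(
    values: np.ndarray | ImageVolume,
    mask: np.ndarray,
    factors: tuple[int, int, int],
    min_in_mask: float = 0.5,
) -> np.ndarray:
    """Non-overlapping block averaging of in-mask voxels.

    Blocks are anchored at the VOI bounding-box corner so the partition is
    reproducible regardless of grid phase.  Each retained block contributes
    the mean of its in-mask voxels; blocks whose in-mask fraction is below
    ``min_in_mask`` are dropped.  Factor 1 on every axis is a pass-through
    returning the in-mask voxels themselves.
    """
    arr = np.asarray(values.data if isinstance(values, ImageVolume) else values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if arr.shape != mask.shape:
        raise ValueError("values and mask shapes differ")
    factors = tuple(int(f) for f in factors)
    if any(f < 1 or f > 8 for f in factors):
        raise ValueError(f"block factors must lie in [1, 8], got {factors}")
    if not mask.any():
        raise ValueError("empty mask")

    # crop to the mask bounding box, then pad up to a multiple of the factors
    slices = ndimage.find_objects(mask.astype(np.int8))[0]
    sub_v, sub_m = arr[slices], mask[slices]
    pad = [(0, (-sub_m.shape[i]) % factors[i]) for i in range(3)]
    sub_v = np.pad(sub_v, pad)
    sub_m = np.pad(sub_m, pad)

    nb = [sub_m.shape[i] // factors[i] for i in range(3)]
    resh_v = sub_v.reshape(nb[0], factors[0], nb[1], factors[1], nb[2], factors[2])
    resh_m = sub_m.reshape(nb[0], factors[0], nb[1], factors[1], nb[2], factors[2])
    counts = resh_m.sum(axis=(1, 3, 5)).ravel()
    sums = (resh_v * resh_m).sum(axis=(1, 3, 5)).ravel()
    frac = counts / float(np.prod(factors))
    keep = frac >= min_in_mask
    if not keep.any():
        raise ValueError("no block meets the in-mask fraction threshold")
    return sums[keep] / counts[keep]


def summarize_region(values: np.ndarray | ImageVolume, mask: np.ndarray, stat: str = "median") -> float:
    """Region summary used for region-level correlation (median by default)."""
    arr = np.asarray(values.data if isinstance(values, ImageVolume) else values, dtype=float)
    sel = arr[np.asarray(mask, dtype=bool)]
    if sel.size == 0:
        raise ValueError("empty region")
    if stat == "median":
        return float(np.median(sel))
    if stat == "mean":
        return float(np.mean(sel))
    raise ValueError(f"unknown summary statistic {stat!r}")


def correlate(
    pet_values,
    mr_values,
    level: str = "voxelwise",
    transform: str = "log10",
) -> CorrelationResult:
    """Pearson correlation of paired PET and MR quantities.

    Under ``transform="log10"`` any pair in which either value is
    non-positive is excluded (pairwise) and the exclusion count reported;
    the correlation and its two-sided p (t distribution, n-2 df) are then
    computed on the log10 pairs.
    """
    x = np.asarray(pet_values, dtype=float).ravel()
    y = np.asarray(mr_values, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    n_in = x.size
    if transform == "log10":
        keep = (x > 0) & (y > 0)
        x, y = np.log10(x[keep]), np.log10(y[keep])
    elif transform == "none":
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
    else:
        raise ValueError(f"unknown transform {transform!r}")
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 retained pairs, have {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(
        r=float(r), p=float(p), n=int(n), level=level,
        transform=transform, n_excluded=int(n_in - n),
    )


def welch_t(group_a, group_b) -> TestResult:
    """Two-sample t test assuming unequal variances (Welch-Satterthwaite df)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(
        statistic=float(res.statistic), p=float(res.pvalue),
        test="welch_t", df=float(res.df), n1=a.size, n2=b.size,
    )


def _rank_sum_exact_p(ranks: np.ndarray, n1: int, w_obs: float) -> float:
    """Exact two-sided p by enumerating all assignments of midranks to group 1."""
    sums = np.fromiter(
        (sum(c) for c in itertools.combinations(ranks, n1)),
        dtype=float,
        count=math.comb(ranks.size, n1),
    )
    tol = 1e-9
    p_lo = np.mean(sums <= w_obs + tol)
    p_hi = np.mean(sums >= w_obs - tol)
    return float(min(1.0, 2.0 * min(p_lo, p_hi)))


def rank_sum(group_a, group_b, exact_max_n: int = 10) -> TestResult:
    """Wilcoxon rank-sum test with midrank ties.

    The statistic is the rank sum of the first group in the pooled sample.
    For combined n <= ``exact_max_n`` the two-sided p is exact (enumeration
    of all group assignments of the observed midranks); beyond that a
    normal approximation with tie correction and continuity correction
    is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("groups must be non-empty")
    n1, n2 = a.size, b.size
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([a, b]))
    w = float(ranks[:n1].sum())

    if n <= exact_max_n:
        p = _rank_sum_exact_p(ranks, n1, w)
    else:
        mean_w = n1 * (n + 1) / 2.0
        _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
        var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var_w <= 0:
            p = 1.0
        else:
            # continuity correction: shrink |W - E[W]| by 0.5
            z = (w - mean_w - math.copysign(0.5, w - mean_w)) / math.sqrt(var_w)
            if (w - mean_w) == 0:
                z = 0.0
            p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return TestResult(statistic=w, p=p, test="wilcoxon_rank_sum", df=None, n1=n1, n2=n2)
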