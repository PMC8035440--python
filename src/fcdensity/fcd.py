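"""Binarized local and long-range functional connectivity density (FCD).

For every gray-matter voxel the pipeline counts, in the undirected graph
obtained by thresholding pairwise Pearson correlations at ``r > 0.3``, how
many other gray voxels it connects to.  The count is split by world-space
(mm) Euclidean distance at a 6 mm sphere:

* **local FCD** — connections to voxels at distance <= 6 mm (the sphere is
  inclusive at exactly 6 mm);
* **long-range FCD** — connections beyond 6 mm.

Their sum is the voxel's total degree, a conservation law the test suite
asserts on every instance.  Self-correlation is excluded throughout, and
zero-variance series contribute no edges.

Raw counts are normalized per subject — divided by the within-mask mean and
converted to Z scores (population SD) — and finally smoothed with a 6 mm
FWHM Gaussian kernel, using mask renormalization so values near the mask
edge are not diluted by the zeros outside.

Two independent code paths compute the counts: :func:`compute_fcd` streams
correlations in voxel blocks and handles arbitrarily large masks, while
:func:`brute_force_fcd` materializes the full correlation and distance
matrices and serves as the exact-integer oracle for small instances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import BoldRun, GridGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "FcdParams",
    "FcdMap",
    "neighborhood_offsets",
    "compute_fcd",
    "brute_force_fcd",
    "normalize_fcd",
    "smooth_map",
    "subject_fcd_maps",
    "fwhm_to_sigma",
]

#: FWHM of a Gaussian equals sigma * 2*sqrt(2*ln 2).
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm_mm: float) -> float:
    return fwhm_mm / _FWHM_PER_SIGMA


@dataclass(frozen=True)
class FcdParams:
    """Correlation threshold, local-sphere radius and smoothing kernel."""

    r_threshold: float = 0.3
    radius_mm: float = 6.0
    fwhm_mm: float = 6.0

    def __post_init__(self) -> None:
        if not 0.0 < self.r_threshold < 1.0:
            raise ValueError("r_threshold must lie in (0, 1)")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if self.fwhm_mm <= 0:
            raise ValueError("fwhm_mm must be positive")


@dataclass(frozen=True)
class FcdMap:
    """One subject's 3D FCD map at a given processing stage.

    ``kind`` distinguishes local from long-range density; ``stage`` tracks
    whether values are raw integer counts, normalized Z scores, or smoothed
    Z scores.  Values are zero outside the gray mask at every stage.
    """

    values: np.ndarray
    kind: str  # "local" | "long_range"
    params: FcdParams
    mask: np.ndarray = field(repr=False)
    stage: str = "raw_count"  # "raw_count" | "normalized" | "smoothed"

    def __post_init__(self) -> None:
        if self.kind not in ("local", "long_range"):
            raise ValueError(f"kind must be 'local' or 'long_range', got {self.kind!r}")
        if self.stage not in ("raw_count", "normalized", "smoothed"):
            raise ValueError(f"unknown stage {self.stage!r}")
        vals = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if vals.shape != mask.shape:
            raise ValueError("values and mask shapes differ")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "mask", mask)


def neighborhood_offsets(
    voxel_size_mm: tuple[float, float, float],
    radius_mm: float,
    max_offset: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Integer voxel offsets within ``radius_mm`` world distance of a voxel.

    Enumerates the lattice ball of the given radius on an axis-aligned grid
    (self excluded).  For a 3 mm isotropic grid and a 6 mm radius this is
    the 32 offsets with dx^2+dy^2+dz^2 <= 4, minus the origin.
    ``max_offset`` caps the per-axis search range (used internally to avoid
    enumerating beyond the grid when the radius exceeds the grid extent).
    """
    if radius_mm < 0:
        raise ValueError("radius_mm must be non-negative")
    sx, sy, sz = (float(s) for s in voxel_size_mm)
    if min(sx, sy, sz) <= 0:
        raise ValueError("voxel sizes must be positive")
    bounds = [int(np.floor(radius_mm / s)) for s in (sx, sy, sz)]
    if max_offset is not None:
        bounds = [min(b, int(m)) for b, m in zip(bounds, max_offset)]
    ax = [np.arange(-b, b + 1) for b in bounds]
    dx, dy, dz = np.meshgrid(*ax, indexing="ij")
    offs = np.column_stack([dx.ravel(), dy.ravel(), dz.ravel()]).astype(np.int64)
    d2 = (offs[:, 0] * sx) ** 2 + (offs[:, 1] * sy) ** 2 + (offs[:, 2] * sz) ** 2
    keep = (d2 <= radius_mm**2) & np.any(offs != 0, axis=1)
    return offs[keep].reshape(-1, 3)


def _standardized_series(
    run: BoldRun, gray: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gray-voxel series scaled so that X @ X.T gives Pearson correlations.

    Returns (X, gray_index_array, valid_row_mask); zero-variance rows are
    zeroed out so they produce r = 0 against everything (no edges).
    """
    gray = np.asarray(gray, dtype=bool)
    if not gray.any():
        raise ValueError("gray mask is empty")
    if run.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints to correlate")
    idx = np.argwhere(gray)
    X = run.data[gray].astype(np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("BOLD series contain non-finite values")
    X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    valid = norms > 0
    if not valid.all():
        logger.info("%d zero-variance gray voxels excluded from edges",
                    int((~valid).sum()))
    X[valid] /= norms[valid, None]
    X[~valid] = 0.0
    return X, idx, valid


def compute_fcd(
    run: BoldRun, gray: np.ndarray, params: FcdParams = FcdParams()
) -> tuple[FcdMap, FcdMap]:
    """Raw local and long-range FCD count maps for one preprocessed run.

    The total degree is accumulated over voxel blocks (the full
    correlation matrix is never materialized); the local count reuses the
    precomputed lattice offsets of the local sphere, and the long-range
    count is their difference.
    """
    X, idx, valid = _standardized_series(run, gray)
    n = len(idx)
    thr = params.r_threshold
    geom = run.geometry

    # Total degree, blocked over rows.
    total = np.zeros(n, dtype=np.int64)
    block = max(1, int(2**22 // max(n, 1)))  # ~32 MB of float64 per block
    for start in range(0, n, block):
        stop = min(start + block, n)
        r = X[start:stop] @ X.T
        hits = r > thr
        # remove self-hits (r(v,v)=1 > thr for valid rows)
        rows = np.arange(start, stop)
        hits[np.arange(stop - start), rows] = False
        total[start:stop] = hits.sum(axis=1)

    # Local degree via the lattice-ball offsets, capped at the grid extent.
    offsets = neighborhood_offsets(
        geom.voxel_size_mm, params.radius_mm,
        max_offset=tuple(d - 1 for d in geom.dims),
    )
    row_of = -np.ones(geom.dims, dtype=np.int64)
    row_of[tuple(idx.T)] = np.arange(n)
    dims = np.array(geom.dims)
    local = np.zeros(n, dtype=np.int64)
    for off in offsets:
        nb = idx + off
        ok = np.all((nb >= 0) & (nb < dims), axis=1)
        rows = np.nonzero(ok)[0]
        nb_rows = row_of[tuple(nb[rows].T)]
        present = nb_rows >= 0
        rows, nb_rows = rows[present], nb_rows[present]
        r = np.einsum("ij,ij->i", X[rows], X[nb_rows])
        local[rows] += (r > thr).astype(np.int64)

    long_range = total - local
    gray = np.asarray(gray, dtype=bool)
    lmap = np.zeros(geom.dims)
    gmap = np.zeros(geom.dims)
    lmap[tuple(idx.T)] = local
    gmap[tuple(idx.T)] = long_range
    return (
        FcdMap(values=lmap, kind="local", params=params, mask=gray, stage="raw_count"),
        FcdMap(values=gmap, kind="long_range", params=params, mask=gray,
               stage="raw_count"),
    )


def brute_force_fcd(
    run: BoldRun,
    gray: np.ndarray,
    params: FcdParams = FcdParams(),
    max_voxels: int = 5000,
) -> tuple[FcdMap, FcdMap]:
    """Reference implementation: full correlation and distance matrices.

    Exact integer agreement with :func:`compute_fcd` is the contract; kept
    deliberately naive and limited to small masks.
    """
    gray = np.asarray(gray, dtype=bool)
    n = int(gray.sum())
    if n > max_voxels:
        raise ValueError(f"brute force limited to {max_voxels} voxels, got {n}")
    X, idx, valid = _standardized_series(run, gray)
    R = X @ X.T
    np.fill_diagonal(R, 0.0)
    world = np.atleast_2d(run.geometry.voxel_to_world(idx))
    D = np.linalg.norm(world[:, None, :] - world[None, :, :], axis=2)
    edges = R > params.r_threshold
    local = (edges & (D <= params.radius_mm)).sum(axis=1)
    long_range = (edges & (D > params.radius_mm)).sum(axis=1)
    lmap = np.zeros(run.geometry.dims)
    gmap = np.zeros(run.geometry.dims)
    lmap[tuple(idx.T)] = local
    gmap[tuple(idx.T)] = long_range
    return (
        FcdMap(values=lmap, kind="local", params=params, mask=gray, stage="raw_count"),
        FcdMap(values=gmap, kind="long_range", params=params, mask=gray,
               stage="raw_count"),
    )


def normalize_fcd(fcd_map: FcdMap, gray: np.ndarray | None = None) -> FcdMap:
    """Divide by the within-mask mean, then convert to Z scores.

    Z-scoring uses the population SD (divide by N).  The mean division is
    the classic grand-mean scaling step; since Z-scoring is affine
    invariant the combined transform is scale-free, which the tests assert.
    """
    if fcd_map.stage != "raw_count":
        raise ValueError(f"expected a raw_count map, got stage {fcd_map.stage!r}")
    mask = fcd_map.mask if gray is None else np.asarray(gray, dtype=bool)
    vals = fcd_map.values[mask]
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("no connections above threshold: mask mean of counts is 0")
    scaled = vals / mean
    sd = scaled.std()  # population SD
    if sd == 0:
        raise ValueError("degenerate FCD map: zero variance after scaling")
    z = (scaled - scaled.mean()) / sd
    out = np.zeros_like(fcd_map.values)
    out[mask] = z
    return replace(fcd_map, values=out, stage="normalized")


def smooth_map(
    fcd_map: FcdMap,
    geometry: GridGeometry,
    fwhm_mm: float | None = None,
) -> FcdMap:
    """Gaussian smoothing with mask renormalization.

    The map (zeros outside the mask) and the mask itself are convolved with
    the same kernel and divided, so edge voxels average only over in-mask
    neighbours instead of being pulled toward zero.  sigma per axis is
    ``fwhm / (2*sqrt(2 ln 2))`` converted to voxel units.
    """
    if fcd_map.stage != "normalized":
        raise ValueError(f"expected a normalized map, got stage {fcd_map.stage!r}")
    fwhm = fcd_map.params.fwhm_mm if fwhm_mm is None else float(fwhm_mm)
    if fwhm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    mask = fcd_map.mask
    if fwhm == 0:
        return replace(fcd_map, stage="smoothed")
    sigma_vox = [fwhm_to_sigma(fwhm) / s for s in geometry.voxel_size_mm]
    num = gaussian_filter(fcd_map.values * mask, sigma_vox, mode="constant")
    den = gaussian_filter(mask.astype(float), sigma_vox, mode="constant")
    out = np.zeros_like(fcd_map.values)
    inside = mask & (den > 0)
    out[inside] = num[inside] / den[inside]
    return replace(fcd_map, values=out, stage="smoothed")


def subject_fcd_maps(
    run: BoldRun, gray: np.ndarray, params: FcdParams = FcdParams()
) -> dict[str, dict[str, FcdMap]]:
    """Raw, normalized and smoothed local/long-range maps for one subject.

    Returns ``{kind: {stage: FcdMap}}`` for kind in {local, long_range}.
    """
    local_raw, long_raw = compute_fcd(run, gray, params)
    out: dict[str, dict[str, FcdMap]] = {}
    for raw in (local_raw, long_raw):
        norm = normalize_fcd(raw)
        smooth = smooth_map(norm, run.geometry)
        out[raw.kind] = {"raw_count": raw, "normalized": norm, "smoothed": smooth}
    return out
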