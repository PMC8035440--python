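"""Synthetic two-group resting-state cohorts with planted connectivity.

The generator emulates the study design the pipeline targets: two groups of
subjects, each scanned for 240 volumes at TR = 2 s on a 3 mm isotropic
grid.  Correlated low-frequency (0.01-0.1 Hz) signal is planted in two
forms:

* **local hubs** — a sphere of gray-matter voxels sharing one band-limited
  source, producing elevated local connectivity density at the hub;
* **long-range pairs** — two distant gray-matter regions sharing a source,
  producing elevated long-range connectivity density in both.

Every planted voxel mixes the shared source with its own noise as

    y = sqrt(s) * source + sqrt(1 - s) * noise_sd * e,

where ``s`` is the signal share and ``e`` is unit-variance AR(1)-plus-white
noise.  With ``noise_sd = 1`` (the default) both terms have unit variance,
so the expected Pearson correlation between two voxels sharing a source at
share ``s`` is exactly ``s`` — an analytic ground truth the tests lean on.
Group differences are planted by giving the two groups different shares.

Everything is deterministic given the spec seed: subject ``i`` of group
``g`` is generated from an RNG keyed on ``(seed, group, i)``, so cohorts
are reproducible byte for byte and individual subjects can be regenerated
in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .core import BoldRun, GridGeometry, MotionParams, TissueMasks

__all__ = [
    "LocalHub",
    "LongRangePair",
    "SyntheticSpec",
    "SubjectData",
    "Cohort",
    "make_masks",
    "hub_voxels",
    "generate_subject",
    "generate_motion",
    "generate_cohort",
    "default_two_group_spec",
]

GROUPS = ("A", "B")

# Baseline BOLD intensity inside the brain; arbitrary units. Gives the
# global-mean nuisance regressor something realistic to remove.
_BASELINE = 100.0


@dataclass(frozen=True)
class LocalHub:
    """A sphere of gray voxels sharing one band-limited source."""

    center: tuple[int, int, int]
    radius_mm: float
    share: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("hub radius must be positive")
        if not 0.0 <= self.share <= 1.0:
            raise ValueError("signal share must lie in [0, 1]")


@dataclass(frozen=True)
class LongRangePair:
    """Two distant gray-matter regions sharing one source."""

    region_a: tuple[tuple[int, int, int], ...]
    region_b: tuple[tuple[int, int, int], ...]
    share: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.share <= 1.0:
            raise ValueError("signal share must lie in [0, 1]")
        object.__setattr__(
            self, "region_a", tuple(tuple(int(i) for i in v) for v in self.region_a)
        )
        object.__setattr__(
            self, "region_b", tuple(tuple(int(i) for i in v) for v in self.region_b)
        )


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic cohort.

    Defaults mirror the acquisition the pipeline emulates: 240 volumes at
    TR = 2 s, 32 subjects per group, signal confined to 0.01-0.1 Hz.
    """

    geometry: GridGeometry
    n_timepoints: int = 240
    tr_s: float = 2.0
    n_per_group: int = 32
    local_hubs: dict[str, tuple[LocalHub, ...]] = field(default_factory=dict)
    long_pairs: dict[str, tuple[LongRangePair, ...]] = field(default_factory=dict)
    signal_band_hz: tuple[float, float] = (0.01, 0.1)
    ar1_coeff: float = 0.3
    noise_sd: float = 1.0
    motion_severity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        low, high = self.signal_band_hz
        nyquist = 1.0 / (2.0 * self.tr_s)
        if not (0.0 < low < high):
            raise ValueError("signal band must satisfy 0 < low < high")
        if high > nyquist:
            raise ValueError(
                f"signal band upper edge {high} Hz exceeds Nyquist {nyquist} Hz"
            )
        if not 0.0 <= self.ar1_coeff < 1.0:
            raise ValueError("ar1_coeff must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.motion_severity < 0:
            raise ValueError("motion_severity must be non-negative")
        for g in self.local_hubs:
            if g not in GROUPS:
                raise ValueError(f"unknown group label {g!r}")
        for g in self.long_pairs:
            if g not in GROUPS:
                raise ValueError(f"unknown group label {g!r}")

    def replace(self, **kwargs) -> "SyntheticSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SubjectData:
    """One simulated subject: BOLD run, motion trace and group label."""

    bold: BoldRun
    motion: MotionParams
    group: str
    subject_id: str


@dataclass
class Cohort:
    subjects: list[SubjectData]
    masks: TissueMasks
    spec: SyntheticSpec


def make_masks(geometry: GridGeometry) -> TissueMasks:
    """Concentric-shell tissue masks: GM core, WM shell, CSF rim.

    The synthetic "head" is a sphere centred on the grid.  Gray matter is
    the core, white matter the next shell, CSF the outer rim; their union
    is strictly inside the whole-brain mask, mirroring how real masks
    partition a brain volume.
    """
    dims = np.array(geometry.dims)
    center = (dims - 1) / 2.0
    ii, jj, kk = np.indices(geometry.dims)
    # Radius in voxel units of the smallest axis so anisotropic grids work.
    r = np.sqrt(
        ((ii - center[0]) ** 2 + (jj - center[1]) ** 2 + (kk - center[2]) ** 2)
    )
    r_brain = 0.475 * dims.min()
    r_wm = 0.40 * dims.min()
    r_gm = 0.32 * dims.min()
    whole = r <= r_brain
    gray = r <= r_gm
    white = (r > r_gm) & (r <= r_wm)
    csf = (r > r_wm) & (r <= r_brain)
    return TissueMasks(
        gray=gray, white=white, csf=csf, whole_brain=whole, geometry=geometry
    )


def hub_voxels(
    hub: LocalHub, geometry: GridGeometry, gray: np.ndarray
) -> np.ndarray:
    """Gray voxels within ``radius_mm`` (world distance) of the hub centre.

    Raises if the centre itself is outside the gray mask.
    """
    center = tuple(int(c) for c in hub.center)
    if not gray[center]:
        raise ValueError(f"hub centre {center} lies outside the gray-matter mask")
    ijk = np.argwhere(gray)
    world = geometry.voxel_to_world(ijk)
    cw = geometry.voxel_to_world(np.array(center))
    dist = np.linalg.norm(np.atleast_2d(world) - cw, axis=1)
    return ijk[dist <= hub.radius_mm]


def _band_limited_source(
    rng: np.random.Generator, n: int, tr_s: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance Gaussian series with power confined to ``band``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=tr_s)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():  # degenerate short series: keep the closest bin
        keep[np.argmin(np.abs(freqs - np.mean(band)))] = True
    spec[~keep] = 0.0
    src = np.fft.irfft(spec, n=n)
    sd = src.std()
    return src / sd if sd > 0 else src


def _unit_noise(
    rng: np.random.Generator, shape: tuple[int, ...], phi: float
) -> np.ndarray:
    """Unit-variance AR(1)-plus-white noise, rows independent.

    The AR(1) component has marginal variance 1 (innovation variance
    1 - phi^2); mixing it 1:1 with white noise and scaling by 1/sqrt(2)
    keeps the total marginal variance at 1 for any phi.
    """
    innov = rng.standard_normal(shape) * np.sqrt(max(1.0 - phi**2, 0.0))
    if phi > 0:
        ar = lfilter([1.0], [1.0, -phi], innov, axis=-1)
        # start the recursion from a stationary draw instead of zero
        init = rng.standard_normal(shape[:-1])
        decay = phi ** np.arange(1, shape[-1] + 1)
        ar = ar + init[..., None] * decay
    else:
        ar = innov
    white = rng.standard_normal(shape)
    return (ar + white) / np.sqrt(2.0)


def _subject_rng(spec: SyntheticSpec, group: str, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(
        [int(spec.seed) & 0x7FFFFFFF, GROUPS.index(group), int(subject_index)]
    )


def generate_subject(
    spec: SyntheticSpec,
    group: str,
    subject_index: int,
    masks: TissueMasks | None = None,
) -> SubjectData:
    """Simulate one subject's BOLD run and motion trace.

    Deterministic given ``(spec.seed, group, subject_index)``.  Sources are
    drawn per subject: subjects share the *structure* of planted
    connectivity, not the time courses themselves, as in real resting-state
    data.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    if subject_index >= spec.n_per_group:
        raise ValueError(
            f"subject_index {subject_index} >= n_per_group {spec.n_per_group}"
        )
    if masks is None:
        masks = make_masks(spec.geometry)
    rng = _subject_rng(spec, group, subject_index)
    T = spec.n_timepoints
    geometry = spec.geometry

    brain_idx = np.argwhere(masks.whole_brain)
    n_brain = len(brain_idx)
    noise = _unit_noise(rng, (n_brain, T), spec.ar1_coeff)

    # Row lookup: voxel (i,j,k) -> row in the brain-voxel table.
    row_of = -np.ones(geometry.dims, dtype=np.int64)
    row_of[tuple(brain_idx.T)] = np.arange(n_brain)

    series = spec.noise_sd * noise

    planted = np.zeros(n_brain, dtype=bool)

    def plant(voxels: np.ndarray, share: float) -> None:
        rows = row_of[tuple(np.asarray(voxels).T)]
        if np.any(rows < 0):
            raise ValueError("planted voxel lies outside the whole-brain mask")
        if np.any(planted[rows]):
            raise ValueError("planted structures overlap; give each voxel one source")
        planted[rows] = True
        source = _band_limited_source(rng, T, spec.tr_s, spec.signal_band_hz)
        series[rows] = (
            np.sqrt(share) * source
            + np.sqrt(1.0 - share) * spec.noise_sd * noise[rows]
        )

    for hub in spec.local_hubs.get(group, ()):
        plant(hub_voxels(hub, geometry, masks.gray), hub.share)
    for pair in spec.long_pairs.get(group, ()):
        vox = np.array(list(pair.region_a) + list(pair.region_b))
        for v in vox:
            if not masks.gray[tuple(v)]:
                raise ValueError(
                    f"long-range pair voxel {tuple(v)} is outside the gray mask"
                )
        plant(vox, pair.share)

    # Slow per-voxel scanner drift, removed later by detrending; scales
    # with noise_sd so noise_sd = 0 yields pure planted signal.
    drift_amp = spec.noise_sd * rng.normal(0.0, 0.2, n_brain)
    ramp = np.linspace(-1.0, 1.0, T)
    series = series + drift_amp[:, None] * ramp[None, :] + _BASELINE

    data = np.zeros(geometry.dims + (T,), dtype=np.float64)
    data[tuple(brain_idx.T)] = series

    motion = generate_motion(
        spec, seed_offset=GROUPS.index(group) * spec.n_per_group + subject_index
    )
    bold = BoldRun(data=data, geometry=geometry, tr_s=spec.tr_s)
    return SubjectData(
        bold=bold,
        motion=motion,
        group=group,
        subject_id=f"sub-{group}{subject_index:03d}",
    )


def generate_motion(spec: SyntheticSpec, seed_offset: int) -> MotionParams:
    """Smooth random-walk motion trace for one subject.

    Each of the six parameters is a cumulative random walk smoothed in
    time and rescaled so its standard deviation is
    ``0.15 * motion_severity`` (mm or degrees).  Severity 0 yields an
    all-zero trace; severity around 10 makes the >1.5 mm translation limit
    exceeded with high probability.
    """
    rng = np.random.default_rng(
        [int(spec.seed) & 0x7FFFFFFF, len(GROUPS), int(seed_offset)]
    )
    T = spec.n_timepoints
    steps = rng.standard_normal((T, 6))
    if spec.motion_severity == 0:
        return MotionParams.from_matrix(np.zeros((T, 6)))
    walk = np.cumsum(steps, axis=0)
    # light temporal smoothing: moving average over ~5 volumes
    kernel = np.ones(5) / 5.0
    walk = np.apply_along_axis(
        lambda c: np.convolve(c, kernel, mode="same"), 0, walk
    )
    walk = walk - walk.mean(axis=0, keepdims=True)
    sd = walk.std(axis=0)
    sd[sd == 0] = 1.0
    trace = 0.15 * spec.motion_severity * walk / sd
    return MotionParams.from_matrix(trace)


def generate_cohort(spec: SyntheticSpec) -> Cohort:
    """Simulate the full two-group cohort plus its tissue masks."""
    masks = make_masks(spec.geometry)
    subjects: list[SubjectData] = []
    for group in GROUPS:
        for i in range(spec.n_per_group):
            subjects.append(generate_subject(spec, group, i, masks=masks))
    return Cohort(subjects=subjects, masks=masks, spec=spec)


def default_two_group_spec(
    dims: tuple[int, int, int] = (20, 20, 20),
    voxel_mm: float = 3.0,
    n_per_group: int = 32,
    hub_share_a: float = 0.8,
    hub_share_b: float = 0.0,
    pair_share_a: float = 0.8,
    pair_share_b: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> SyntheticSpec:
    """Desk-scale two-group spec with one local hub and one long-range pair.

    Group A carries the planted signal at ``hub_share_a``/``pair_share_a``;
    group B at the (default zero) B shares — a pure group difference in
    connection density, which is what the downstream contrast detects.
    The hub sits off-centre in the gray core; the long-range pair links two
    gray patches on opposite sides of the brain, well beyond the 6 mm
    local neighbourhood.
    """
    geometry = GridGeometry.isotropic(dims, voxel_mm)
    masks = make_masks(geometry)
    center = tuple(int(c) for c in (np.array(dims) - 1) // 2)
    # hub: offset from centre along +x, still inside the gray core
    gm_r = 0.32 * min(dims)
    off = max(1, int(round(gm_r / 2)))
    hub_center = (center[0] + off, center[1], center[2])
    if not masks.gray[hub_center]:
        raise ValueError("default hub centre fell outside gray matter")

    def patch(cx: int, cy: int, cz: int) -> tuple[tuple[int, int, int], ...]:
        vox = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    v = (cx + dx, cy + dy, cz + dz)
                    if masks.gray[v]:
                        vox.append(v)
        if not vox:
            raise ValueError("long-range patch fell outside gray matter")
        return tuple(vox)

    # two patches on opposite sides along y, away from the hub
    pa = patch(center[0] - off, center[1] + off, center[2])
    pb = patch(center[0] - off, center[1] - off, center[2])

    def group_cfg(hub_share: float, pair_share: float):
        hubs = (LocalHub(center=hub_center, radius_mm=2 * voxel_mm, share=hub_share),)
        pairs = (LongRangePair(region_a=pa, region_b=pb, share=pair_share),)
        return hubs, pairs

    hubs_a, pairs_a = group_cfg(hub_share_a, pair_share_a)
    hubs_b, pairs_b = group_cfg(hub_share_b, pair_share_b)
    local_hubs = {
        "A": tuple(h for h in hubs_a if h.share > 0),
        "B": tuple(h for h in hubs_b if h.share > 0),
    }
    long_pairs = {
        "A": tuple(p for p in pairs_a if p.share > 0),
        "B": tuple(p for p in pairs_b if p.share > 0),
    }
    return SyntheticSpec(
        geometry=geometry,
        n_per_group=n_per_group,
        local_hubs=local_hubs,
        long_pairs=long_pairs,
        seed=seed,
        **kwargs,
    )
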