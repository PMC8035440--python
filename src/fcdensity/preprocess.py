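"""Temporal preprocessing of BOLD runs.

The chain, applied in this fixed order, is:

1. drop the initial volumes acquired before signal equilibrium;
2. exclude subjects whose head motion exceeds the translation/rotation
   limits (strictly more than 1.5 mm or 1.5 degrees by default);
3. regress out nuisance covariates — the Friston-24 head-motion expansion
   plus the global, white-matter and CSF mean signals and their temporal
   derivatives — by ordinary least squares per voxel;
4. linearly detrend and bandpass to 0.01-0.1 Hz with a zero-phase
   frequency-domain filter.

Regression precedes filtering; the filter is zero-phase so it cannot lag
one voxel's series relative to another, which would distort the
correlations computed downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.linalg import qr

from .core import BoldRun, MotionParams, TissueMasks

logger = logging.getLogger(__name__)

__all__ = [
    "NuisanceDesign",
    "drop_initial_volumes",
    "motion_exceeds_limits",
    "friston24",
    "build_nuisance",
    "nuisance_regress",
    "detrend_bandpass",
    "preprocess_run",
]


@dataclass
class NuisanceDesign:
    """A t x k matrix of nuisance regressors with column names."""

    columns: np.ndarray
    column_names: list[str]

    def __post_init__(self) -> None:
        self.columns = np.atleast_2d(np.asarray(self.columns, dtype=float))
        if self.columns.shape[1] != len(self.column_names):
            raise ValueError("column count does not match column_names")
        if not np.all(np.isfinite(self.columns)):
            raise ValueError("nuisance design contains non-finite values")

    @property
    def n_columns(self) -> int:
        return self.columns.shape[1]


def drop_initial_volumes(
    run: BoldRun, motion: MotionParams, n_drop: int = 10
) -> tuple[BoldRun, MotionParams]:
    """Discard the first ``n_drop`` volumes and motion rows."""
    if n_drop < 0:
        raise ValueError("n_drop must be non-negative")
    if run.n_timepoints <= n_drop:
        raise ValueError(
            f"cannot drop {n_drop} volumes from a run of {run.n_timepoints}"
        )
    if motion.n_timepoints != run.n_timepoints:
        raise ValueError(
            f"motion rows ({motion.n_timepoints}) do not match "
            f"volumes ({run.n_timepoints})"
        )
    new_run = BoldRun(
        data=run.data[..., n_drop:], geometry=run.geometry, tr_s=run.tr_s
    )
    new_motion = MotionParams(
        translations_mm=motion.translations_mm[n_drop:],
        rotations_deg=motion.rotations_deg[n_drop:],
    )
    return new_run, new_motion


def motion_exceeds_limits(
    motion: MotionParams,
    trans_limit_mm: float = 1.5,
    rot_limit_deg: float = 1.5,
) -> bool:
    """True iff the subject should be excluded for excessive head motion.

    The comparison is strict: a maximum displacement of exactly the limit
    is retained ("more than" the limit excludes).
    """
    if motion.n_timepoints == 0:
        raise ValueError("empty motion trace")
    mat = motion.as_matrix()
    if not np.all(np.isfinite(mat)):
        raise ValueError("motion parameters contain non-finite values")
    max_trans = np.abs(motion.translations_mm).max()
    max_rot = np.abs(motion.rotations_deg).max()
    return bool(max_trans > trans_limit_mm or max_rot > rot_limit_deg)


def friston24(motion: MotionParams) -> NuisanceDesign:
    """Friston 24-parameter head-motion expansion.

    Columns: the 6 rigid-body parameters, their one-lag copies (first row
    zero), and the squares of both sets.
    """
    p = motion.as_matrix()
    lag = np.vstack([np.zeros((1, 6)), p[:-1]])
    cols = np.hstack([p, lag, p**2, lag**2])
    base = ["tx", "ty", "tz", "rx", "ry", "rz"]
    names = (
        [f"mot_{b}" for b in base]
        + [f"mot_{b}_lag" for b in base]
        + [f"mot_{b}_sq" for b in base]
        + [f"mot_{b}_lag_sq" for b in base]
    )
    return NuisanceDesign(columns=cols, column_names=names)


def _mask_mean_series(run: BoldRun, mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError(f"tissue mask '{name}' is empty")
    return run.data[mask].mean(axis=0)


def _first_difference(col: np.ndarray) -> np.ndarray:
    """First difference, zero-padded at the first row."""
    out = np.zeros_like(col)
    out[1:] = np.diff(col)
    return out


def build_nuisance(
    run: BoldRun, masks: TissueMasks, motion: MotionParams
) -> NuisanceDesign:
    """Friston-24 plus global/WM/CSF mean signals and their derivatives.

    30 columns by default: 24 motion terms, 3 tissue means, 3 first
    differences of the tissue means.
    """
    if motion.n_timepoints != run.n_timepoints:
        raise ValueError("motion rows must match run timepoints")
    f24 = friston24(motion)
    glob = _mask_mean_series(run, masks.whole_brain, "whole_brain")
    wm = _mask_mean_series(run, masks.white, "white")
    csf = _mask_mean_series(run, masks.csf, "csf")
    signals = np.column_stack(
        [glob, wm, csf, _first_difference(glob), _first_difference(wm),
         _first_difference(csf)]
    )
    names = f24.column_names + [
        "global_mean", "wm_mean", "csf_mean",
        "global_mean_deriv", "wm_mean_deriv", "csf_mean_deriv",
    ]
    return NuisanceDesign(
        columns=np.hstack([f24.columns, signals]), column_names=names
    )


def _drop_dependent_columns(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Keep a maximal linearly independent column subset (pivoted QR)."""
    if X.shape[1] == 0:
        return X, names
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    keep = np.sort(piv[:rank])
    if rank < X.shape[1]:
        dropped = [names[i] for i in sorted(set(range(X.shape[1])) - set(keep))]
        logger.warning("nuisance design rank-deficient; dropping %s", dropped)
    return X[:, keep], [names[i] for i in keep]


def nuisance_regress(run: BoldRun, design: NuisanceDesign) -> BoldRun:
    """Replace every voxel series by its OLS residual on [intercept|design].

    Residuals are orthogonal to every retained design column and have
    exactly zero mean (the intercept is always included).  Rank-deficient
    designs are repaired by dropping dependent columns with a warning.
    """
    T = run.n_timepoints
    if design.columns.shape[0] != T:
        raise ValueError(
            f"design rows ({design.columns.shape[0]}) != timepoints ({T})"
        )
    X = np.column_stack([np.ones(T), design.columns])
    names = ["intercept"] + list(design.column_names)
    X, _ = _drop_dependent_columns(X, names)
    Y = run.data.reshape(-1, T).T  # (T, n_voxels)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    data = resid.T.reshape(run.data.shape)
    return BoldRun(data=data, geometry=run.geometry, tr_s=run.tr_s)


def _band_window(n: int, tr_s: float, low_hz: float, high_hz: float) -> np.ndarray:
    """Zero-phase passband window with cosine-tapered transitions.

    The taper half-width is two frequency bins (at least 2 mHz), narrow
    enough that a tone at twice the band-edge distance is fully rejected
    while in-band tones pass essentially untouched.
    """
    freqs = np.fft.rfftfreq(n, d=tr_s)
    df = 1.0 / (n * tr_s)
    taper = max(2.0 * df, 0.002)
    w = np.zeros_like(freqs)
    inband = (freqs >= low_hz) & (freqs <= high_hz)
    w[inband] = 1.0
    lo_ramp = (freqs >= low_hz - taper) & (freqs < low_hz)
    w[lo_ramp] = 0.5 * (1 + np.cos(np.pi * (low_hz - freqs[lo_ramp]) / taper))
    hi_ramp = (freqs > high_hz) & (freqs <= high_hz + taper)
    w[hi_ramp] = 0.5 * (1 + np.cos(np.pi * (freqs[hi_ramp] - high_hz) / taper))
    return w


def detrend_bandpass(
    run: BoldRun, low_hz: float = 0.01, high_hz: float = 0.1
) -> BoldRun:
    """Linear detrend then zero-phase bandpass to [low_hz, high_hz].

    A pure tone inside the band retains essentially all of its amplitude;
    tones well outside (at twice the band-edge distance or more) and
    linear ramps are suppressed to below 10%.
    """
    nyquist = run.nyquist_hz
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyquist} Hz)"
        )
    T = run.n_timepoints
    Y = run.data.reshape(-1, T)
    Y = sps.detrend(Y, axis=-1, type="linear")
    w = _band_window(T, run.tr_s, low_hz, high_hz)
    spec = np.fft.rfft(Y, axis=-1)
    spec *= w[None, :]
    out = np.fft.irfft(spec, n=T, axis=-1)
    return BoldRun(
        data=out.reshape(run.data.shape), geometry=run.geometry, tr_s=run.tr_s
    )


def preprocess_run(
    run: BoldRun,
    motion: MotionParams,
    masks: TissueMasks,
    n_drop: int = 10,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
) -> BoldRun:
    """Full preprocessing chain for one retained subject.

    Motion screening is the caller's job (see :func:`motion_exceeds_limits`);
    this function assumes the subject passed.
    """
    run, motion = drop_initial_volumes(run, motion, n_drop=n_drop)
    design = build_nuisance(run, masks, motion)
    run = nuisance_regress(run, design)
    run = detrend_bandpass(run, low_hz=low_hz, high_hz=high_hz)
    if not np.all(np.isfinite(run.data)):
        raise ValueError("preprocessing produced non-finite values")
    return run
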