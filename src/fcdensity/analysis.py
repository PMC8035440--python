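"""End-to-end in-memory analysis of a two-group cohort.

This is the pipeline's computational spine, shared by the command-line
stages: motion screening, preprocessing, per-subject FCD mapping, group t
statistics with Monte-Carlo cluster-extent correction, and per-cluster ROC
discrimination.  It works entirely on in-memory objects; the disk-facing
stage functions in :mod:`fcdensity.pipeline` wrap it with NIfTI/TSV I/O.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from dataclasses import replace as _dc_replace

from .config import StudyConfig
from .core import BoldRun, MotionParams, TissueMasks
from .fcd import FcdMap, subject_fcd_maps
from .group_stats import (
    ClusterTable,
    StatMap,
    cluster_extent_threshold,
    estimate_map_fwhm,
    extract_clusters,
    one_sample_t,
    two_sample_t,
)
from .preprocess import motion_exceeds_limits, preprocess_run
from .roc import CIRCULARITY_WARNING, RocResult, cluster_mean_values, roc_auc
from .synthetic import SubjectData

logger = logging.getLogger(__name__)

__all__ = ["KindResult", "CohortResult", "screen_motion", "analyze_cohort"]

KINDS = ("local", "long_range")


@dataclass
class KindResult:
    """Group-level results for one FCD kind (local or long-range)."""

    two_sample: StatMap
    one_sample: dict[str, StatMap]
    clusters: ClusterTable
    roc: list[RocResult]
    subject_maps: dict[str, list[FcdMap]]  # smoothed maps per group
    extent_threshold: int = 0
    noise_fwhm_mm: tuple[float, float, float] | None = None


@dataclass
class CohortResult:
    kinds: dict[str, KindResult]
    excluded: list[str] = field(default_factory=list)
    config: StudyConfig | None = None


def screen_motion(
    subjects: list[SubjectData], config: StudyConfig
) -> tuple[list[SubjectData], list[str]]:
    """Split subjects into retained and excluded by the motion limits.

    Motion is screened on the volumes that enter analysis, i.e. after the
    initial-volume drop.
    """
    keep: list[SubjectData] = []
    excluded: list[str] = []
    for s in subjects:
        motion = MotionParams(
            translations_mm=s.motion.translations_mm[config.n_drop:],
            rotations_deg=s.motion.rotations_deg[config.n_drop:],
        )
        if motion_exceeds_limits(
            motion, config.trans_limit_mm, config.rot_limit_deg
        ):
            excluded.append(s.subject_id)
        else:
            keep.append(s)
    if excluded:
        logger.info("excluded %d subjects for motion: %s", len(excluded), excluded)
    return keep, excluded


def _preprocess_and_map(
    subject: SubjectData, masks: TissueMasks, config: StudyConfig
) -> dict[str, FcdMap]:
    run = preprocess_run(
        subject.bold,
        subject.motion,
        masks,
        n_drop=config.n_drop,
        low_hz=config.low_hz,
        high_hz=config.high_hz,
    )
    maps = subject_fcd_maps(run, masks.gray, config.fcd)
    return {kind: maps[kind]["smoothed"] for kind in KINDS}


def analyze_cohort(
    subjects: list[SubjectData],
    masks: TissueMasks,
    config: StudyConfig | None = None,
    extent_threshold: int | None = None,
) -> CohortResult:
    """Run the complete analysis on an in-memory cohort.

    ``extent_threshold`` may be supplied to reuse a Monte-Carlo null
    computed once for the same mask/smoothing/threshold settings (the null
    depends only on those, not on the data).
    """
    config = config or StudyConfig()
    ga, gb = config.group_labels
    retained, excluded = screen_motion(subjects, config)
    by_group: dict[str, list[SubjectData]] = {ga: [], gb: []}
    for s in retained:
        if s.group not in by_group:
            raise ValueError(f"subject {s.subject_id} has unknown group {s.group!r}")
        by_group[s.group].append(s)
    if len(by_group[ga]) < 2 or len(by_group[gb]) < 2:
        raise ValueError("need at least 2 retained subjects per group")

    smoothed: dict[str, dict[str, list[FcdMap]]] = {
        kind: {ga: [], gb: []} for kind in KINDS
    }
    for group in (ga, gb):
        for s in by_group[group]:
            maps = _preprocess_and_map(s, masks, config)
            for kind in KINDS:
                smoothed[kind][group].append(maps[kind])

    geometry = subjects[0].bold.geometry

    logger.warning(CIRCULARITY_WARNING)
    kinds: dict[str, KindResult] = {}
    for kind in KINDS:
        maps_a = smoothed[kind][ga]
        maps_b = smoothed[kind][gb]
        ts = two_sample_t(
            maps_a, maps_b, masks.gray, contrast=f"{kind}:{ga}-{gb}"
        )
        os = {
            g: one_sample_t(smoothed[kind][g], masks.gray, contrast=f"{kind}:{g}")
            for g in (ga, gb)
        }
        noise_fwhm = None
        if extent_threshold is not None:
            extent = int(extent_threshold)
        else:
            corr = config.correction
            if corr.fwhm_mm is None:
                mean_a = np.mean([m.values for m in maps_a], axis=0)
                mean_b = np.mean([m.values for m in maps_b], axis=0)
                resid = [m.values - mean_a for m in maps_a] + [
                    m.values - mean_b for m in maps_b
                ]
                noise_fwhm = estimate_map_fwhm(resid, masks.gray, geometry)
                corr = _dc_replace(corr, fwhm_mm=noise_fwhm)
            extent = cluster_extent_threshold(masks.gray, geometry, corr)
        table = extract_clusters(ts, config.correction, extent, geometry)
        rocs = []
        for i, cluster in enumerate(table):
            vals = cluster_mean_values(
                maps_a, maps_b, cluster, cluster_id=f"{kind}_{i}"
            )
            rocs.append(
                roc_auc(
                    vals,
                    group_labels=(ga, gb),
                    ci_method=config.ci_method,
                    n_boot=config.n_boot,
                    seed=config.seed,
                )
            )
        kinds[kind] = KindResult(
            two_sample=ts,
            one_sample=os,
            clusters=table,
            roc=rocs,
            subject_maps={ga: maps_a, gb: maps_b},
            extent_threshold=extent,
            noise_fwhm_mm=noise_fwhm,
        )
    return CohortResult(kinds=kinds, excluded=excluded, config=config)
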