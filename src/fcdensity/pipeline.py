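"""Disk-facing pipeline stages and the end-to-end runner.

Each stage reads and writes ordinary files (NIfTI volumes, whitespace
motion text, TSV tables, JSON provenance) so stages can be chained from
the command line; :func:`run_pipeline` simply calls them in order, which
makes "run the stages one by one" and "run everything" identical by
construction.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import KINDS, analyze_cohort
from .config import StudyConfig
from .core import TissueMasks
from .fcd import FcdMap, subject_fcd_maps
from .group_stats import (
    Cluster,
    ClusterTable,
    CorrectionParams,
    cluster_extent_threshold,
    extract_clusters,
    one_sample_t,
    two_sample_t,
)
from .io import (
    read_bold,
    read_manifest,
    read_mask,
    read_masks,
    read_motion,
    write_bold,
    write_manifest,
    write_map,
    write_masks,
    write_motion,
)
from .preprocess import drop_initial_volumes, motion_exceeds_limits, preprocess_run
from .roc import CIRCULARITY_WARNING, cluster_mean_values, roc_auc, roc_curve_points
from .synthetic import SyntheticSpec, generate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "simulate_stage",
    "preprocess_stage",
    "fcd_stage",
    "group_stage",
    "roc_stage",
    "run_pipeline",
]


def _write_provenance(out_dir: Path, stage: str, params: dict) -> None:
    payload = {"stage": stage, "software": "fcdensity", "version": __version__,
               "parameters": params}
    with open(out_dir / f"provenance_{stage}.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)


def simulate_stage(spec: SyntheticSpec, out_dir: str | Path) -> Path:
    """Generate a synthetic cohort and write it to ``out_dir``.

    Emits one BOLD NIfTI and one 6-column motion text file per subject,
    the four tissue masks, a manifest TSV and a provenance JSON.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(spec)
    write_masks(cohort.masks, spec.geometry, out_dir)
    records = []
    for s in cohort.subjects:
        bold_path = out_dir / f"{s.subject_id}_bold.nii.gz"
        motion_path = out_dir / f"{s.subject_id}_motion.txt"
        write_bold(s.bold, bold_path)
        write_motion(s.motion, motion_path)
        records.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "bold_path": bold_path.name,
                "motion_path": motion_path.name,
            }
        )
    write_manifest(records, out_dir / "manifest.tsv")
    _write_provenance(
        out_dir, "simulate",
        {"seed": spec.seed, "n_per_group": spec.n_per_group,
         "n_timepoints": spec.n_timepoints, "tr_s": spec.tr_s,
         "dims": list(spec.geometry.dims)},
    )
    return out_dir


def _load_cohort_paths(manifest_path: Path) -> pd.DataFrame:
    df = read_manifest(manifest_path)
    base = manifest_path.parent
    for col in ("bold_path", "motion_path"):
        df[col] = df[col].map(lambda p: str(p) if Path(p).is_absolute() else str(base / p))
    return df


def preprocess_stage(
    data_dir: str | Path, out_dir: str | Path, config: StudyConfig
) -> Path:
    """Motion-screen and preprocess every subject in a cohort directory.

    Excluded subjects are listed in ``exclusions.tsv`` and omitted from the
    output manifest, so they can never reach later stages.
    """
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = _load_cohort_paths(data_dir / "manifest.tsv")
    geometry = None
    masks = None
    records, exclusions = [], []
    for _, row in df.iterrows():
        run = read_bold(row.bold_path, tr_s=config.tr_s)
        if geometry is None:
            geometry = run.geometry
            masks = read_masks(data_dir, geometry)
            write_masks(masks, geometry, out_dir)
        motion = read_motion(row.motion_path, expected_rows=run.n_timepoints)
        _, motion_kept = drop_initial_volumes(run, motion, config.n_drop)
        if motion_exceeds_limits(
            motion_kept, config.trans_limit_mm, config.rot_limit_deg
        ):
            exclusions.append(
                {
                    "subject_id": row.subject_id,
                    "reason": "head motion exceeds limits",
                    "max_trans_mm": float(np.abs(motion_kept.translations_mm).max()),
                    "max_rot_deg": float(np.abs(motion_kept.rotations_deg).max()),
                }
            )
            continue
        clean = preprocess_run(
            run, motion, masks,
            n_drop=config.n_drop, low_hz=config.low_hz, high_hz=config.high_hz,
        )
        bold_path = out_dir / f"{row.subject_id}_preproc.nii.gz"
        write_bold(clean, bold_path)
        records.append(
            {
                "subject_id": row.subject_id,
                "group": row.group,
                "bold_path": bold_path.name,
                "motion_path": row.motion_path,
            }
        )
    pd.DataFrame(
        exclusions,
        columns=["subject_id", "reason", "max_trans_mm", "max_rot_deg"],
    ).to_csv(out_dir / "exclusions.tsv", sep="\t", index=False)
    write_manifest(records, out_dir / "manifest.tsv")
    _write_provenance(
        out_dir, "preprocess",
        {"n_drop": config.n_drop, "band_hz": [config.low_hz, config.high_hz],
         "trans_limit_mm": config.trans_limit_mm,
         "rot_limit_deg": config.rot_limit_deg,
         "n_excluded": len(exclusions)},
    )
    return out_dir


def fcd_stage(
    preproc_dir: str | Path, out_dir: str | Path, config: StudyConfig
) -> Path:
    """Compute raw/normalized/smoothed local and long-range maps per subject."""
    preproc_dir, out_dir = Path(preproc_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = _load_cohort_paths(preproc_dir / "manifest.tsv")
    records = []
    geometry = None
    for _, row in df.iterrows():
        run = read_bold(row.bold_path, tr_s=config.tr_s)
        if geometry is None:
            geometry = run.geometry
            masks = read_masks(preproc_dir, geometry)
            write_masks(masks, geometry, out_dir)
        maps = subject_fcd_maps(run, masks.gray, config.fcd)
        rec = {"subject_id": row.subject_id, "group": row.group}
        for kind in KINDS:
            for stage_name, m in maps[kind].items():
                p = out_dir / f"{row.subject_id}_{kind}_{stage_name}.nii.gz"
                write_map(m.values, geometry, p)
                rec[f"{kind}_{stage_name}"] = p.name
        records.append(rec)
    pd.DataFrame(records).to_csv(out_dir / "fcd_manifest.tsv", sep="\t", index=False)
    _write_provenance(
        out_dir, "fcd",
        {"r_threshold": config.fcd.r_threshold, "radius_mm": config.fcd.radius_mm,
         "fwhm_mm": config.fcd.fwhm_mm},
    )
    return out_dir


def _load_smoothed(fcd_dir: Path, config: StudyConfig):
    df = pd.read_csv(fcd_dir / "fcd_manifest.tsv", sep="\t",
                     dtype={"subject_id": str, "group": str})
    sample = read_bold_header_geometry(fcd_dir, df)
    masks = read_masks(fcd_dir, sample)
    ga, gb = config.group_labels
    maps = {kind: {ga: [], gb: []} for kind in KINDS}
    subject_ids = {ga: [], gb: []}
    import nibabel as nib

    for _, row in df.iterrows():
        for kind in KINDS:
            arr = np.asanyarray(
                nib.load(str(fcd_dir / row[f"{kind}_smoothed"])).dataobj
            ).astype(float)
            maps[kind][row.group].append(arr)
        subject_ids[row.group].append(row.subject_id)
    return maps, subject_ids, masks, sample


def read_bold_header_geometry(fcd_dir: Path, df: pd.DataFrame):
    import nibabel as nib

    from .core import GridGeometry

    first = df.iloc[0]
    img = nib.load(str(fcd_dir / first[f"{KINDS[0]}_smoothed"]))
    return GridGeometry(dims=img.shape[:3], affine=img.affine)


def group_stage(
    fcd_dir: str | Path, out_dir: str | Path, config: StudyConfig
) -> Path:
    """Group t maps, Monte-Carlo extent threshold and cluster tables.

    Writes, per FCD kind: the two-sample t map and per-group one-sample t
    maps (NIfTI), an integer cluster-label volume, and a cluster table TSV.
    """
    from dataclasses import replace as _dc_replace

    from .group_stats import estimate_map_fwhm

    fcd_dir, out_dir = Path(fcd_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    maps, _, masks, geometry = _load_smoothed(fcd_dir, config)
    ga, gb = config.group_labels
    extents: dict[str, int] = {}
    noise_fwhms: dict[str, list[float] | str] = {}
    for kind in KINDS:
        corr = config.correction
        if corr.fwhm_mm is None:
            mean_a = np.mean(maps[kind][ga], axis=0)
            mean_b = np.mean(maps[kind][gb], axis=0)
            resid = [m - mean_a for m in maps[kind][ga]] + [
                m - mean_b for m in maps[kind][gb]
            ]
            est = estimate_map_fwhm(resid, masks.gray, geometry)
            corr = _dc_replace(corr, fwhm_mm=est)
            noise_fwhms[kind] = [round(float(f), 4) for f in est]
        else:
            noise_fwhms[kind] = "fixed"
        extent = extents[kind] = cluster_extent_threshold(
            masks.gray, geometry, corr
        )
        ts = two_sample_t(maps[kind][ga], maps[kind][gb], masks.gray,
                          contrast=f"{kind}:{ga}-{gb}")
        write_map(ts.t_values, geometry, out_dir / f"tmap_two_sample_{kind}.nii.gz")
        for g in (ga, gb):
            os = one_sample_t(maps[kind][g], masks.gray, contrast=f"{kind}:{g}")
            write_map(os.t_values, geometry,
                      out_dir / f"tmap_one_sample_{kind}_{g}.nii.gz")
        table = extract_clusters(ts, config.correction, extent, geometry)
        labels = np.zeros(geometry.dims, dtype=np.int16)
        for i, c in enumerate(table, start=1):
            labels[tuple(np.array(c.voxels).T)] = i
        write_map(labels.astype(float), geometry,
                  out_dir / f"cluster_labels_{kind}.nii.gz")
        tdf = table.to_dataframe()
        tdf.insert(0, "kind", kind)
        tdf.insert(1, "contrast", f"{ga}-{gb}")
        tdf["df"] = ts.df
        tdf.to_csv(out_dir / f"clusters_{kind}.tsv", sep="\t", index=False,
                   float_format="%.6f")
    with open(out_dir / "extent_threshold.json", "w") as fh:
        json.dump({"extent_threshold_voxels": {k: int(v) for k, v in extents.items()},
                   "noise_fwhm_mm": noise_fwhms,
                   "n_simulations": config.correction.n_simulations,
                   "seed": config.correction.seed}, fh, indent=2)
    _write_provenance(
        out_dir, "group",
        {"voxel_p": config.correction.voxel_p,
         "cluster_p": config.correction.cluster_p,
         "connectivity": config.correction.connectivity,
         "n_simulations": config.correction.n_simulations,
         "fwhm_mm": config.correction.fwhm_mm,
         "noise_fwhm_mm": noise_fwhms,
         "seed": config.correction.seed,
         "extent_threshold": {k: int(v) for k, v in extents.items()}},
    )
    return out_dir


def roc_stage(
    fcd_dir: str | Path, group_dir: str | Path, out_dir: str | Path,
    config: StudyConfig,
) -> Path:
    """Per-cluster ROC: AUC, 95% CI, p, accuracy band, plus curve points."""
    fcd_dir, group_dir, out_dir = Path(fcd_dir), Path(group_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    maps, _, masks, geometry = _load_smoothed(fcd_dir, config)
    ga, gb = config.group_labels
    logger.warning(CIRCULARITY_WARNING)
    rows = []
    for kind in KINDS:
        labels = read_mask_int(group_dir / f"cluster_labels_{kind}.nii.gz")
        tdf = pd.read_csv(group_dir / f"clusters_{kind}.tsv", sep="\t")
        for _, crow in tdf.iterrows():
            cid = int(crow.cluster_id)
            vox = np.argwhere(labels == cid + 1)
            cluster = Cluster(
                voxels=tuple(tuple(int(i) for i in v) for v in vox),
                size=len(vox),
                peak_t=float(crow.peak_t),
                peak_voxel=(0, 0, 0),
                peak_world_mm=(crow.peak_x_mm, crow.peak_y_mm, crow.peak_z_mm),
                sign=crow.sign,
            )
            vals = cluster_mean_values(
                maps[kind][ga], maps[kind][gb], cluster,
                cluster_id=f"{kind}_{cid}",
            )
            res = roc_auc(vals, group_labels=(ga, gb),
                          ci_method=config.ci_method, n_boot=config.n_boot,
                          seed=config.seed)
            pts = roc_curve_points(vals, res.positive_group, (ga, gb))
            pd.DataFrame(pts, columns=["fpr", "tpr"]).to_csv(
                out_dir / f"roc_curve_{kind}_{cid}.csv", index=False
            )
            rows.append(
                {
                    "kind": kind, "cluster_id": cid, "sign": crow.sign,
                    "size_voxels": int(crow.size_voxels),
                    "peak_t": float(crow.peak_t),
                    "peak_x_mm": crow.peak_x_mm, "peak_y_mm": crow.peak_y_mm,
                    "peak_z_mm": crow.peak_z_mm,
                    "auc": res.auc, "ci_low": res.ci_low, "ci_high": res.ci_high,
                    "p_value": res.p_value, "band": res.band,
                    "positive_group": res.positive_group,
                }
            )
    pd.DataFrame(
        rows,
        columns=["kind", "cluster_id", "sign", "size_voxels", "peak_t",
                 "peak_x_mm", "peak_y_mm", "peak_z_mm", "auc", "ci_low",
                 "ci_high", "p_value", "band", "positive_group"],
    ).to_csv(out_dir / "roc_results.tsv", sep="\t", index=False,
             float_format="%.6f")
    _write_provenance(
        out_dir, "roc",
        {"ci_method": config.ci_method, "n_boot": config.n_boot,
         "seed": config.seed, "note": CIRCULARITY_WARNING},
    )
    return out_dir


def read_mask_int(path: Path) -> np.ndarray:
    import nibabel as nib

    return np.rint(np.asanyarray(nib.load(str(path)).dataobj)).astype(int)


def run_pipeline(config: StudyConfig, data_dir: str | Path | None = None) -> Path:
    """Chain preprocess -> fcd -> group -> roc on an existing cohort directory.

    ``data_dir`` defaults to the directory of the configured manifest.
    Outputs land in subdirectories of ``config.out_dir``; rerunning with
    the same config and seeds reproduces all numeric outputs.
    """
    if data_dir is None:
        data_dir = Path(config.manifest).parent
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "provenance_run.json", "w") as fh:
        json.dump({"software": "fcdensity", "version": __version__,
                   "config": config.to_dict()}, fh, indent=2, default=str)
    preprocess_stage(data_dir, out / "preproc", config)
    fcd_stage(out / "preproc", out / "fcd", config)
    group_stage(out / "fcd", out / "group", config)
    roc_stage(out / "fcd", out / "group", out / "roc", config)
    return out
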