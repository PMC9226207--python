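"""File I/O: NIfTI volumes, frame-schedule CSVs, cohort manifests, atlas tables.

NIfTI is used for every image (via nibabel, with a diagonal affine built from
the voxel size); tabular interchange is plain CSV.  A 4D dynamic image always
travels with a two-column frame-schedule CSV (``start_s``, ``end_s``) so the
frame timing can never be separated from the data.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import (
    AtlasDefinition,
    Cohort,
    DynamicImage,
    FrameSchedule,
    ImageVolume,
    Subject,
)

log = logging.getLogger(__name__)


def _affine(voxel_size) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0])
    return aff


def _voxel_size_from(img: nib.Nifti1Image) -> tuple[float, float, float]:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def write_volume(volume: ImageVolume, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(volume.data, _affine(volume.voxel_size)), path)
    return path


def read_volume(path) -> ImageVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    img = nib.load(path)
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path} holds a {data.ndim}D image; read_volume expects 3D "
            "(use read_dynamic for 4D data)"
        )
    return ImageVolume(data, _voxel_size_from(img))


def write_schedule(schedule: FrameSchedule, path) -> Path:
    path = Path(path)
    pd.DataFrame({"start_s": schedule.starts, "end_s": schedule.ends}).to_csv(
        path, index=False
    )
    return path


def read_schedule(path) -> FrameSchedule:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such schedule: {path}")
    df = pd.read_csv(path)
    for col in ("start_s", "end_s"):
        if col not in df.columns:
            raise ValueError(f"schedule {path} lacks required column {col!r}")
    return FrameSchedule(df["start_s"].to_numpy(), df["end_s"].to_numpy())


def write_dynamic(dyn: DynamicImage, path, schedule_path=None) -> Path:
    """Write a 4D image plus its schedule sidecar (``<stem>_frames.csv``)."""
    path = Path(path)
    if dyn.data.shape[3] != len(dyn.schedule):
        raise ValueError("frame count does not match schedule length")
    nib.save(nib.Nifti1Image(dyn.data, _affine(dyn.voxel_size)), path)
    if schedule_path is None:
        schedule_path = _default_schedule_path(path)
    write_schedule(dyn.schedule, schedule_path)
    return path


def _default_schedule_path(path: Path) -> Path:
    stem = path.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return path.with_name(stem + "_frames.csv")


def read_dynamic(path, schedule_path=None) -> DynamicImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    img = nib.load(path)
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(
            f"{path} holds a {data.ndim}D image; read_dynamic expects 4D "
            "(use read_volume for 3D data)"
        )
    if schedule_path is None:
        schedule_path = _default_schedule_path(path)
    if not Path(schedule_path).exists():
        raise FileNotFoundError(
            f"dynamic image {path} has no frame-timing sidecar at {schedule_path}; "
            "a 4D image cannot be interpreted without its frame schedule"
        )
    schedule = read_schedule(schedule_path)
    return DynamicImage(data, schedule, _voxel_size_from(img))


def load_region_combination(path) -> dict[str, str]:
    """Read a two-column region -> lobe table.

    Duplicate rows that agree are tolerated; a region listed under two
    different lobes is an error (each region belongs to exactly one lobe).
    An empty table yields an empty map with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such region table: {path}")
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("region table needs two columns: region, lobe")
    region_col, lobe_col = df.columns[:2]
    lobe_map: dict[str, str] = {}
    for region, lobe in zip(df[region_col].astype(str), df[lobe_col].astype(str)):
        if region in lobe_map and lobe_map[region] != lobe:
            raise ValueError(
                f"region {region!r} mapped to both {lobe_map[region]!r} and {lobe!r}"
            )
        lobe_map[region] = lobe
    if not lobe_map:
        warnings.warn("region-combination table is empty", stacklevel=2)
        log.warning("region-combination table %s is empty", path)
    return lobe_map


def unmapped_regions(atlas_region_names, lobe_map) -> list[str]:
    """Atlas regions absent from the combination table (reported, not dropped)."""
    return sorted(set(atlas_region_names) - set(lobe_map))


def write_atlas(atlas: AtlasDefinition, path, table_path=None) -> Path:
    path = Path(path)
    nib.save(
        nib.Nifti1Image(atlas.labels.astype(np.int16), _affine(atlas.voxel_size)), path
    )
    if table_path is not None:
        rows = [
            {"label": lab, "region": name, "lobe": atlas.lobe_map[name]}
            for lab, name in sorted(atlas.region_names.items())
        ]
        pd.DataFrame(rows).to_csv(table_path, index=False)
    return path


def read_atlas(path, table_path) -> AtlasDefinition:
    img = nib.load(path)
    labels = np.asanyarray(img.dataobj).astype(int)
    df = pd.read_csv(table_path)
    region_names = dict(zip(df["label"].astype(int), df["region"].astype(str)))
    lobe_map = dict(zip(df["region"].astype(str), df["lobe"].astype(str)))
    return AtlasDefinition(labels, region_names, lobe_map, _voxel_size_from(img))


def write_manifest(cohort: Cohort, out_dir, name="manifest.csv") -> Path:
    """Write each subject image as NIfTI plus a manifest CSV pointing at them."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        img_path = out_dir / f"{s.subject_id}.nii.gz"
        write_volume(s.image, img_path)
        rows.append({"subject_id": s.subject_id, "group": s.group, "path": img_path.name})
    manifest = out_dir / name
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest(manifest_path, mask: np.ndarray) -> Cohort:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    subjects = []
    for row in df.itertuples():
        p = Path(row.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        subjects.append(Subject(str(row.subject_id), str(row.group), read_volume(p)))
    vox = subjects[0].image.voxel_size if subjects else (2.0, 2.0, 2.0)
    return Cohort(subjects, mask, vox)


def _strip_nii(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)])
    return path


def save_pattern(pattern, mask: np.ndarray, path, sidecar_path=None):
    """Save a disease pattern: weights + HC-profile NIfTIs and a JSON sidecar.

    The JSON carries the fit bookkeeping (included PCs, coefficients,
    variance fractions, HC LOOCV score statistics); the training HC mean
    profile is stored as ``<base>_hcmean.nii.gz`` so prospective scoring can
    reproduce the training-time preprocessing exactly.
    """
    path = Path(path)
    mask = np.asarray(mask, dtype=bool)
    vol = np.zeros(mask.shape)
    vol[mask] = pattern.weights
    nib.save(nib.Nifti1Image(vol, _affine(pattern.voxel_size)), path)
    base = _strip_nii(path)
    hc_vol = np.zeros(mask.shape)
    hc_vol[mask] = pattern.training_hc_mean_profile
    nib.save(
        nib.Nifti1Image(hc_vol, _affine(pattern.voxel_size)),
        base.with_name(base.name + "_hcmean.nii.gz"),
    )
    if sidecar_path is None:
        sidecar_path = base.with_suffix(".json")
    meta = {
        "included_pcs": [int(i) for i in pattern.included_pcs],
        "logistic_coefficients": [float(b) for b in pattern.logistic_coefficients],
        "intercept": float(pattern.intercept),
        "dp_variance_explained_pct": float(pattern.dp_variance_explained),
        "training_hc_score_mean": float(pattern.training_hc_score_mean),
        "training_hc_score_sd": float(pattern.training_hc_score_sd),
        "variance_fractions": [float(v) for v in pattern.variance_fractions],
        "log_transform": bool(pattern.log_transform),
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=2))
    return path


def load_pattern(path, mask: np.ndarray, sidecar_path=None):
    """Load a disease pattern saved by :func:`save_pattern`."""
    from .ssm_pca import DiseasePattern  # local import: avoid cycle

    path = Path(path)
    mask = np.asarray(mask, dtype=bool)
    base = _strip_nii(path)
    if sidecar_path is None:
        sidecar_path = base.with_suffix(".json")
    meta = json.loads(Path(sidecar_path).read_text())
    weights_vol = read_volume(path)
    hc_path = base.with_name(base.name + "_hcmean.nii.gz")
    if hc_path.exists():
        hc_profile = read_volume(hc_path).data[mask]
    else:
        hc_profile = np.zeros(int(mask.sum()))
    return DiseasePattern(
        weights=weights_vol.data[mask],
        mask=mask,
        voxel_size=weights_vol.voxel_size,
        included_pcs=list(meta["included_pcs"]),
        logistic_coefficients=list(meta["logistic_coefficients"]),
        intercept=float(meta["intercept"]),
        dp_variance_explained=float(meta["dp_variance_explained_pct"]),
        variance_fractions=np.asarray(meta["variance_fractions"]),
        training_hc_mean_profile=hc_profile,
        log_transform=bool(meta.get("log_transform", False)),
        training_hc_score_mean=float(meta["training_hc_score_mean"]),
        training_hc_score_sd=float(meta["training_hc_score_sd"]),
    )
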