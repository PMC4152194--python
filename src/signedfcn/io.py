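"""Readers and writers: TSV matrices/time series, JSON partitions and reports,
ROI-mean extraction from labelled imaging volumes (NIfTI)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import FCMatrix, ROITimeSeries
from .modularity import ModularityResult, Partition
from .reproducibility import ReproducibilityReport


# --------------------------------------------------------------------------
# time series


def write_timeseries(ts: ROITimeSeries, path: str | Path) -> None:
    """One subject's time series as TSV: rows = timepoints, columns = ROIs."""
    pd.DataFrame(ts.values, columns=ts.roi_labels).to_csv(path, sep="\t", index=False)


def read_timeseries(path: str | Path, subject_id: str | None = None) -> ROITimeSeries:
    df = pd.read_csv(path, sep="\t")
    if subject_id is None:
        subject_id = Path(path).stem
    return ROITimeSeries(
        values=df.to_numpy(dtype=float),
        roi_labels=[str(c) for c in df.columns],
        subject_id=subject_id,
    )


def write_cohort(cohort: list[ROITimeSeries], out_dir: str | Path, sidecar: dict | None = None) -> list[Path]:
    """Write one TSV per subject plus an optional JSON sidecar (``cohort.json``)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ts in cohort:
        p = out_dir / f"{ts.subject_id}.tsv"
        write_timeseries(ts, p)
        paths.append(p)
    if sidecar is not None:
        write_json(sidecar, out_dir / "cohort.json")
    return paths


def read_cohort(in_dir: str | Path) -> list[ROITimeSeries]:
    """Read every ``*.tsv`` in a directory as one subject each (sorted by name)."""
    paths = sorted(Path(in_dir).glob("*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no .tsv time-series files in {in_dir}")
    return [read_timeseries(p) for p in paths]


# --------------------------------------------------------------------------
# matrices


def write_matrix(z: np.ndarray, roi_labels: list[str], path: str | Path) -> None:
    """Square matrix as TSV with ROI labels as header row and index column."""
    pd.DataFrame(z, index=roi_labels, columns=roi_labels).to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_fc(fc: FCMatrix, path: str | Path) -> None:
    write_matrix(fc.z, fc.roi_labels, path)


def read_fc(path: str | Path, n_subjects_averaged: int = 1) -> FCMatrix:
    z, labels = read_matrix(path)
    return FCMatrix(
        z=z,
        roi_labels=labels,
        subject_id=Path(path).stem,
        n_subjects_averaged=n_subjects_averaged,
    )


# --------------------------------------------------------------------------
# JSON artefacts


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(data: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True, default=_jsonify) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_partition(
    result: ModularityResult, roi_labels: list[str], path: str | Path
) -> None:
    """Partition JSON keyed by ROI label, with the Q* decomposition."""
    data = {
        "affiliation": dict(zip(roi_labels, result.partition.affiliation)),
        "n_modules": result.partition.n_modules,
        "q_star": result.q_star,
        "q_pos": result.q_pos,
        "q_neg": result.q_neg,
        "n_restarts": result.n_restarts,
        "seed": result.seed,
    }
    write_json(data, path)


def read_partition(path: str | Path, roi_labels: list[str] | None = None) -> Partition:
    data = read_json(path)
    aff = data["affiliation"]
    if roi_labels is None:
        roi_labels = list(aff.keys())
    return Partition(tuple(int(aff[label]) for label in roi_labels))


def write_report(report: ReproducibilityReport, path: str | Path) -> None:
    write_json(report.to_dict(), path)


def read_report(path: str | Path) -> ReproducibilityReport:
    return ReproducibilityReport(**read_json(path))


# --------------------------------------------------------------------------
# imaging volumes


def extract_roi_timeseries(
    image4d: np.ndarray,
    atlas: np.ndarray,
    label_table: list[tuple[int, str]],
    subject_id: str = "",
) -> ROITimeSeries:
    """ROI-mean time series from a 4-D volume and an integer label atlas.

    ``image4d`` has shape (x, y, z, t); ``atlas`` has the matching spatial
    shape with 0 = background.  Column ``u`` of the output holds, at each
    timepoint, the mean over all voxels carrying label ``u``; column order
    follows ``label_table``.  Volumes are assumed co-registered (no
    coordinate transforms are applied).
    """
    image4d = np.asarray(image4d, dtype=float)
    atlas = np.asarray(atlas)
    if image4d.ndim != 4:
        raise ValueError("functional image must be 4-D (x, y, z, t)")
    if atlas.shape != image4d.shape[:3]:
        raise ValueError(
            f"atlas grid {atlas.shape} does not match image grid {image4d.shape[:3]}"
        )
    names = [name for _, name in label_table]
    if len(set(names)) != len(names):
        raise ValueError("ROI names must be unique")
    t = image4d.shape[3]
    flat_img = image4d.reshape(-1, t)
    flat_atlas = atlas.reshape(-1)
    columns = np.empty((t, len(label_table)))
    for k, (label, name) in enumerate(label_table):
        mask = flat_atlas == label
        if not mask.any():
            raise ValueError(f"ROI {name!r} (label {label}) has no voxels in the atlas")
        columns[:, k] = flat_img[mask].mean(axis=0)
    return ROITimeSeries(values=columns, roi_labels=names, subject_id=subject_id)


def extract_roi_timeseries_nifti(
    image_path: str | Path,
    atlas_path: str | Path,
    label_table: list[tuple[int, str]] | None = None,
    subject_id: str = "",
) -> ROITimeSeries:
    """As :func:`extract_roi_timeseries`, reading NIfTI files from disk.

    Without an explicit label table, every nonzero integer label found in
    the atlas becomes an ROI named ``ROI<label>``.
    """
    import nibabel as nib

    img = np.asanyarray(nib.load(str(image_path)).dataobj)
    atlas = np.asanyarray(nib.load(str(atlas_path)).dataobj).astype(int)
    if label_table is None:
        labels = sorted(int(v) for v in np.unique(atlas) if v != 0)
        label_table = [(v, f"ROI{v:02d}") for v in labels]
    if subject_id == "":
        subject_id = Path(image_path).stem
    return extract_roi_timeseries(img, atlas, label_table, subject_id=subject_id)
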