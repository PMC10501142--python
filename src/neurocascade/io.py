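"""Format round-tripping: feature tables and demographics as CSV (+ JSON
sidecar for column metadata), volumes as NIfTI, reports as JSON/text."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .classify import ClassificationReport
from .roi import FeatureTable, LabelVolume

__all__ = [
    "write_feature_table",
    "read_feature_table",
    "save_volume",
    "load_label_volume",
    "load_volume",
    "report_to_dict",
    "report_to_text",
]


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """CSV with 'metric|label' flattened headers plus a .meta.json sidecar."""
    path = Path(path)
    flat = table.values.copy()
    flat.columns = [f"{m}|{l}" for m, l in table.values.columns]
    flat.insert(0, "group", table.groups)
    flat.to_csv(path)
    meta = {
        "columns": [[m, int(l)] for m, l in table.values.columns],
        "label_names": {str(k): v for k, v in table.label_names.items()},
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    flat = pd.read_csv(path, index_col=0)
    if "group" not in flat.columns:
        raise ValueError(f"{path}: missing required 'group' column")
    groups = flat.pop("group")
    cols = []
    for c in flat.columns:
        if "|" not in c:
            raise ValueError(f"{path}: malformed feature header {c!r}")
        m, l = c.rsplit("|", 1)
        cols.append((m, int(l)))
    values = flat.copy()
    values.columns = pd.MultiIndex.from_tuples(cols, names=["metric", "label"])
    label_names: dict[int, str] = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        label_names = {int(k): v for k, v in meta.get("label_names", {}).items()}
    return FeatureTable(values=values, groups=groups, label_names=label_names)


def save_volume(
    data: np.ndarray,
    path: str | Path,
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0),
) -> None:
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), voxel


def load_label_volume(
    path: str | Path,
    empty_labels: set[int] | None = None,
    names_path: str | Path | None = None,
) -> LabelVolume:
    """Label NIfTI plus optional two-column (label, name) text table."""
    data, voxel = load_volume(path)
    labels = np.rint(np.asarray(data, dtype=float)).astype(np.int32)
    names: dict[int, str] = {}
    if names_path is not None:
        for line in Path(names_path).read_text().splitlines():
            parts = line.split(maxsplit=1)
            if len(parts) == 2:
                names[int(parts[0])] = parts[1].strip()
    return LabelVolume(
        labels=labels,
        voxel_size=voxel,
        label_names=names,
        empty_labels=set(empty_labels or ()),
    )


def report_to_dict(report: ClassificationReport) -> dict:
    return {
        "method": report.method,
        "seed": report.seed,
        "overall_acc": report.overall_acc,
        "per_class_acc": report.per_class_acc,
        "auc_stage1": report.auc_stage1,
        "auc_stage2": report.auc_stage2,
        "stage2_acc": report.stage2_acc,
        "confusion": {
            "classes": list(report.confusion.index),
            "counts": report.confusion.to_numpy().tolist(),
        },
        "n_features_per_fold": report.n_features_per_fold,
        "per_fold_features": [
            {k: [list(f) if isinstance(f, tuple) else f for f in v] for k, v in fold.items()}
            for fold in report.per_fold_features
        ],
    }


def report_to_text(report: ClassificationReport) -> str:
    """Human-readable summary mirroring the study's results-table layout."""
    lines = [
        f"method: {report.method}   seed: {report.seed}",
        f"overall accuracy: {report.overall_acc:.2f}%",
        "per-class correct rate: "
        + "  ".join(f"{c} {v:.2f}%" for c, v in report.per_class_acc.items()),
    ]
    if report.auc_stage1 is not None:
        lines.append(f"stage-1 (patients vs HC) AUC: {report.auc_stage1:.2f}")
    for key, label in (
        ("predicted_patients", "stage-2 AUC (stage-1-correct patients)"),
        ("all_patients", "stage-2 AUC (all patients)"),
    ):
        v = report.auc_stage2.get(key)
        if v is not None:
            lines.append(f"{label}: {v:.2f}")
    lines.append(
        "features per fold: "
        + " ".join(str(n) for n in report.n_features_per_fold)
    )
    lines.append("confusion matrix (rows = true):")
    lines.append(report.confusion.to_string())
    return "\n".join(lines)
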