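"""Atlas-based ROI reduction and the multi-modal feature table.

The parcellation convention follows the 170-label AAL3 atlas: labels 35,
36, 81 and 82 are defined empty, and the two small labels 133/134 are lost
when the 1 mm atlas is resampled to 3 mm, leaving 164 usable regions.  The
assembled table holds four metrics per region — left/right hippocampus seed
connectivity (L.Hip, R.Hip), Hurst exponent (HE) and gray-matter volume
(GMV) — with each hippocampus seed (labels 41/42) excluded from its own
connectivity metric, for 163 + 163 + 164 + 164 = 654 columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "METRICS",
    "SEED_LABELS",
    "SEED_EXCLUSIONS",
    "AAL3_MAX_LABEL",
    "AAL3_EMPTY_LABELS",
    "aal3_usable_labels",
    "feature_columns",
    "LabelVolume",
    "FeatureTable",
    "resample_labels",
    "extract_roi_means",
    "compute_gmv",
    "assemble_features",
]

#: Canonical metric order of the assembled table (metric-major columns).
METRICS = ("L.Hip", "R.Hip", "HE", "GMV")

#: Atlas labels of the bilateral hippocampus seeds.
SEED_LABELS = {"L.Hip": 41, "R.Hip": 42}

#: Each seed-connectivity metric excludes its own seed region (self-correlation
#: is degenerate, r = 1).
SEED_EXCLUSIONS = dict(SEED_LABELS)

AAL3_MAX_LABEL = 170
#: 35/36, 81/82 defined empty; 133/134 lost at 3 mm resampling.
AAL3_EMPTY_LABELS = frozenset({35, 36, 81, 82, 133, 134})


def aal3_usable_labels() -> list[int]:
    """The 164 usable AAL3 labels (1..170 minus the six empty ones)."""
    return [l for l in range(1, AAL3_MAX_LABEL + 1) if l not in AAL3_EMPTY_LABELS]


def feature_columns(region_labels: tuple[int, ...] | list[int]) -> list[tuple[str, int]]:
    """Canonical (metric, label) column order: metric-major, label ascending."""
    labels = sorted(region_labels)
    cols: list[tuple[str, int]] = []
    for metric in METRICS:
        excl = SEED_EXCLUSIONS.get(metric)
        cols.extend((metric, l) for l in labels if l != excl)
    return cols


@dataclass
class LabelVolume:
    """Integer atlas volume (0 = background) with voxel geometry and bookkeeping."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    label_names: dict[int, str] = field(default_factory=dict)
    empty_labels: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must hold integers")
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def present_labels(self) -> list[int]:
        """Labels that actually occupy >= 1 voxel, ascending."""
        vals = np.unique(self.labels)
        return [int(v) for v in vals if v != 0]

    def usable_labels(self) -> list[int]:
        """Present labels not flagged empty."""
        empty = set(self.empty_labels)
        return [l for l in self.present_labels() if l not in empty]


def resample_labels(
    vol: LabelVolume, target_voxel: tuple[float, float, float]
) -> LabelVolume:
    """Nearest-neighbour resampling of a label volume to a coarser grid.

    Labels whose every voxel vanishes under the coarser sampling are
    appended to ``empty_labels`` (this is how the two small atlas regions
    are lost when going from 1 mm to 3 mm).
    """
    src = np.asarray(vol.voxel_size, dtype=float)
    tgt = np.asarray(target_voxel, dtype=float)
    if np.any(tgt < src - 1e-9):
        raise ValueError("target voxel must be >= source voxel along every axis")
    if np.allclose(tgt, src):
        return LabelVolume(
            labels=vol.labels.copy(),
            voxel_size=tuple(tgt),
            label_names=dict(vol.label_names),
            empty_labels=set(vol.empty_labels),
        )
    factor = tgt / src
    new_shape = tuple(int(np.ceil(s / f)) for s, f in zip(vol.labels.shape, factor))
    # sample the source voxel nearest to each target voxel centre
    grids = [
        np.clip(np.round((np.arange(ns) + 0.5) * f - 0.5).astype(int), 0, s - 1)
        for ns, f, s in zip(new_shape, factor, vol.labels.shape)
    ]
    out = vol.labels[np.ix_(*grids)]

    before = set(vol.present_labels())
    after = set(int(v) for v in np.unique(out) if v != 0)
    vanished = before - after
    return LabelVolume(
        labels=out,
        voxel_size=tuple(tgt),
        label_names=dict(vol.label_names),
        empty_labels=set(vol.empty_labels) | vanished,
    )


def extract_roi_means(volume: np.ndarray, vol: LabelVolume) -> dict[int, float]:
    """Unweighted voxel mean of ``volume`` over each usable label.

    Empty labels are reported as NaN so downstream assembly can flag them
    explicitly rather than silently dropping regions.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.shape != vol.labels.shape:
        raise ValueError(
            f"map shape {volume.shape} != label shape {vol.labels.shape}"
        )
    usable = vol.usable_labels()
    means = ndimage.mean(volume, labels=vol.labels, index=usable)
    out = {int(l): float(m) for l, m in zip(usable, means)}
    for l in sorted(vol.empty_labels):
        out[int(l)] = float("nan")
    return out


def compute_gmv(modulated_gm: np.ndarray, vol: LabelVolume) -> dict[int, float]:
    """Regional gray-matter volume in millilitres.

    Sum of Jacobian-modulated GM probabilities per region × voxel volume
    (mm³) / 1000.  Modulation preserves tissue amounts, so the sum is a true
    volume.  Negative voxels (interpolation artefacts) are clamped to zero
    with a warning.
    """
    gm = np.asarray(modulated_gm, dtype=float)
    if gm.shape != vol.labels.shape:
        raise ValueError(f"map shape {gm.shape} != label shape {vol.labels.shape}")
    if (gm < 0).any():
        warnings.warn(
            f"{int((gm < 0).sum())} negative GM voxels clamped to 0 "
            "(policy: clamp; see log)"
        )
        gm = np.clip(gm, 0.0, None)
    usable = vol.usable_labels()
    sums = ndimage.sum_labels(gm, labels=vol.labels, index=usable)
    scale = vol.voxel_volume_mm3 / 1000.0
    out = {int(l): float(s) * scale for l, s in zip(usable, sums)}
    for l in sorted(vol.empty_labels):
        out[int(l)] = float("nan")
    return out


@dataclass
class FeatureTable:
    """Subjects × (metric, region) feature matrix with three-class labels.

    ``values`` is a DataFrame indexed by subject id with a (metric, label)
    MultiIndex on the columns; ``groups`` maps subject id -> class.  This is
    the central exchange object between extraction, selection, the
    classifiers and the post-hoc statistics.
    """

    values: pd.DataFrame
    groups: pd.Series
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.values.columns, pd.MultiIndex):
            raise ValueError("values must have a (metric, label) MultiIndex")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicated (metric, label) columns: {dups}")
        self.groups = self.groups.reindex(self.values.index)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()].tolist()
            raise ValueError(f"subjects without a group label: {missing}")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def X(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.groups.to_numpy()

    def column_keys(self) -> list[tuple[str, int]]:
        return [(str(m), int(l)) for m, l in self.values.columns]

    def class_counts(self) -> dict[str, int]:
        return self.groups.value_counts().to_dict()

    def select_metrics(self, metrics: list[str]) -> "FeatureTable":
        """Restrict to a subset of metrics, preserving canonical order."""
        unknown = set(metrics) - set(METRICS)
        if unknown:
            raise ValueError(f"unknown metrics {sorted(unknown)}")
        keep = [c for c in self.values.columns if c[0] in metrics]
        return FeatureTable(
            values=self.values[keep],
            groups=self.groups.copy(),
            label_names=dict(self.label_names),
        )

    def subset_rows(self, subject_ids) -> "FeatureTable":
        return FeatureTable(
            values=self.values.loc[subject_ids],
            groups=self.groups.loc[subject_ids],
            label_names=dict(self.label_names),
        )


def assemble_features(
    per_subject: dict[str, dict[str, dict[int, float]]],
    vol: LabelVolume,
    groups: dict[str, str] | pd.Series,
) -> FeatureTable:
    """Assemble per-subject metric maps into the canonical feature table.

    ``per_subject`` maps subject id -> metric name -> (label -> value).
    Subjects missing any of the four metrics are excluded with a warning
    naming the gap.  Rows are sorted by subject id so the table is
    deterministic regardless of input ordering.
    """
    usable = vol.usable_labels()
    cols = feature_columns(usable)
    rows, kept_ids = [], []
    for sid in sorted(per_subject):
        metrics_map = per_subject[sid]
        missing = [m for m in METRICS if m not in metrics_map]
        if missing:
            warnings.warn(f"subject {sid!r} lacks metrics {missing}; excluded")
            continue
        row = []
        bad = False
        for metric, label in cols:
            v = metrics_map[metric].get(label, float("nan"))
            if not np.isfinite(v):
                warnings.warn(
                    f"subject {sid!r}: non-finite {metric} value for label {label}; excluded"
                )
                bad = True
                break
            row.append(v)
        if bad:
            continue
        rows.append(row)
        kept_ids.append(sid)
    if not rows:
        raise ValueError("no subject has a complete set of metrics")

    frame = pd.DataFrame(
        np.asarray(rows, dtype=float),
        index=pd.Index(kept_ids, name="subject_id"),
        columns=pd.MultiIndex.from_tuples(cols, names=["metric", "label"]),
    )
    grp = pd.Series(groups).reindex(kept_ids)
    grp.name = "group"
    return FeatureTable(values=frame, groups=grp, label_names=dict(vol.label_names))
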