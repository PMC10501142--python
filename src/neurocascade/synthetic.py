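"""Synthetic cohort generation.

Every input the analysis pipeline consumes — BOLD-like time series with a
known Hurst exponent, seed-correlated multi-unit series, class-structured
multi-modal feature tables, toy atlas label volumes with matched metric
volumes, and demographics tables — can be generated here with a fixed seed,
so the whole pipeline is testable without any imaging download.

The fractional Gaussian noise (fGn) generator uses exact-covariance
circulant embedding (Davies–Harte), so the requested H is the *true*
population value rather than an approximation; it is the validation oracle
for the rescaled-range estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .roi import (
    AAL3_EMPTY_LABELS,
    AAL3_MAX_LABEL,
    FeatureTable,
    METRICS,
    SEED_EXCLUSIONS,
    aal3_usable_labels,
    feature_columns,
)
from .timeseries import RoiTimeSeries

__all__ = [
    "FgnSpec",
    "CohortSpec",
    "fgn_autocovariance",
    "generate_fgn",
    "generate_seeded_timeseries",
    "generate_feature_table",
    "generate_label_volume",
    "generate_demographics",
    "TABLE1_DEMOGRAPHICS",
]


@dataclass(frozen=True)
class FgnSpec:
    """Parameters of a fractional Gaussian noise sequence.

    H is the Hurst parameter in (0, 1): 0.5 is white noise, above 0.5
    persistent, below anti-persistent.
    """

    H: float
    length: int
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.H < 1.0:
            raise ValueError(f"H must lie in (0, 1), got {self.H}")
        if self.length < 16:
            raise ValueError(f"length must be >= 16, got {self.length}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


#: Per-class mean shifts that make the three groups trivially separable
#: (used by the oracle cohort in tests); metric/label must exist in the table.
EffectMap = list[tuple[str, int, tuple[float, float, float]]]

CLASSES = ("AD", "MCI", "HC")


@dataclass
class CohortSpec:
    """Design of a synthetic three-group cohort feature table.

    ``n_per_class`` follows the study's group sizes (AD, MCI, HC).
    ``effect_map`` lists (metric, region label, per-class mean offsets) for
    the columns that carry signal; all other columns are pure Gaussian noise
    with standard deviation ``noise_sd``.
    """

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {"AD": 44, "MCI": 66, "HC": 58}
    )
    region_labels: tuple[int, ...] = field(
        default_factory=lambda: tuple(aal3_usable_labels())
    )
    effect_map: EffectMap = field(default_factory=list)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.n_per_class) != set(CLASSES):
            raise ValueError(f"n_per_class must have keys {CLASSES}")
        if any(n < 2 for n in self.n_per_class.values()):
            raise ValueError("all class counts must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        labels = set(self.region_labels)
        for metric, label, offsets in self.effect_map:
            if metric not in METRICS:
                raise ValueError(f"unknown metric {metric!r}")
            if label not in labels:
                raise ValueError(f"effect label {label} not in region_labels")
            if len(offsets) != 3:
                raise ValueError("offsets must give one value per class")

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)


def fgn_autocovariance(lags: np.ndarray, H: float, sigma: float = 1.0) -> np.ndarray:
    """Closed-form fGn autocovariance gamma(k) = sigma^2/2 (|k+1|^2H - 2|k|^2H + |k-1|^2H)."""
    k = np.abs(np.asarray(lags, dtype=float))
    return sigma**2 / 2.0 * (np.abs(k + 1) ** (2 * H) - 2 * k ** (2 * H) + np.abs(k - 1) ** (2 * H))


def generate_fgn(spec: FgnSpec) -> np.ndarray:
    """Sample one exact-covariance fGn sequence by circulant embedding.

    The first row of the 2N-point circulant matrix embeds the Toeplitz
    autocovariance; its DFT eigenvalues are nonnegative for fGn, so the
    synthesis is exact and the spectral weights sqrt(lambda_k) colour a
    Hermitian complex white-noise vector.
    """
    n = spec.length
    gamma = fgn_autocovariance(np.arange(n + 1), spec.H, spec.sigma)
    circ = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2n
    lam = np.fft.fft(circ).real
    # tiny negative eigenvalues can arise from float round-off only
    if lam.min() < -1e-8 * lam.max():
        raise RuntimeError("circulant embedding produced negative eigenvalues")
    lam = np.maximum(lam, 0.0)

    m = 2 * n
    rng = np.random.default_rng(spec.seed)
    w = np.zeros(m, dtype=complex)
    w[0] = rng.standard_normal() * np.sqrt(m)
    w[n] = rng.standard_normal() * np.sqrt(m)
    u = rng.standard_normal(n - 1)
    v = rng.standard_normal(n - 1)
    w[1:n] = (u + 1j * v) * np.sqrt(m / 2.0)
    w[n + 1 :] = np.conj(w[1:n][::-1])
    x = np.fft.ifft(np.sqrt(lam) * w)[:n].real
    return x


def generate_seeded_timeseries(
    n_units: int,
    seed_corr: float,
    length: int,
    seed: int = 0,
    dt: float = 2.0,
) -> RoiTimeSeries:
    """Multi-unit Gaussian series where unit 0 is the designated seed.

    Every other unit is built by Gaussian mixing ``rho*z + sqrt(1-rho^2)*eps``
    so its population correlation with the seed is exactly ``seed_corr``.
    """
    if not -1.0 <= seed_corr <= 1.0:
        raise ValueError(f"seed_corr must lie in [-1, 1], got {seed_corr}")
    if length < 16:
        raise ValueError(f"length must be >= 16, got {length}")
    if n_units < 2:
        raise ValueError("need at least the seed and one target unit")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(length)
    eps = rng.standard_normal((length, n_units - 1))
    rest = seed_corr * z[:, None] + np.sqrt(1.0 - seed_corr**2) * eps
    data = np.column_stack([z, rest])
    return RoiTimeSeries(data=data, dt=dt)


def generate_feature_table(spec: CohortSpec) -> FeatureTable:
    """Class-structured subjects × (metric, region) feature table.

    Column layout matches the assembled multi-modal table: metric-major
    (L.Hip, R.Hip, HE, GMV), region labels ascending, each hippocampus seed
    excluded from its own connectivity metric.  With the default 164 usable
    regions this yields 163 + 163 + 164 + 164 = 654 columns.
    """
    columns = feature_columns(spec.region_labels)
    rng = np.random.default_rng(spec.seed)

    groups: list[str] = []
    subject_ids: list[str] = []
    for cls in CLASSES:
        n = spec.n_per_class[cls]
        groups.extend([cls] * n)
        subject_ids.extend(f"{cls}{i:03d}" for i in range(n))

    n_total = len(subject_ids)
    values = rng.normal(0.0, spec.noise_sd, size=(n_total, len(columns)))

    col_index = {col: j for j, col in enumerate(columns)}
    class_offsets = {cls: i for i, cls in enumerate(CLASSES)}
    group_arr = np.asarray(groups)
    for metric, label, offsets in spec.effect_map:
        j = col_index.get((metric, label))
        if j is None:
            # seed region excluded from its own metric; reject loudly
            raise ValueError(f"({metric}, {label}) is not a column of the table")
        for cls in CLASSES:
            values[group_arr == cls, j] += offsets[class_offsets[cls]]

    frame = pd.DataFrame(
        values,
        index=pd.Index(subject_ids, name="subject_id"),
        columns=pd.MultiIndex.from_tuples(columns, names=["metric", "label"]),
    )
    return FeatureTable(values=frame, groups=pd.Series(groups, index=frame.index, name="group"))


def generate_label_volume(
    shape: tuple[int, int, int],
    labels: list[int] | None = None,
    empty_labels: set[int] | None = None,
    seed: int = 0,
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0),
):
    """Toy atlas fixture: a label volume plus a matched metric volume.

    Every non-empty label occupies at least one voxel; the paired real-valued
    volume is constant within each label (value = a known per-label constant),
    so ROI extraction can be checked exactly.  Defaults mimic the AAL3
    convention: labels 1..170 with {35, 36, 81, 82, 133, 134} empty.

    Returns ``(label_volume, metric_volume, constants)`` where ``constants``
    maps label -> the constant planted in the metric volume.
    """
    from .roi import LabelVolume  # local import to avoid cycle at module load

    if labels is None:
        labels = list(range(1, AAL3_MAX_LABEL + 1))
    if empty_labels is None:
        empty_labels = set(AAL3_EMPTY_LABELS)
    present = [l for l in labels if l not in empty_labels]
    if any(l in empty_labels for l in labels) and not set(labels).isdisjoint(empty_labels):
        # empty labels may be listed among labels; they simply get no voxels
        pass
    n_vox = int(np.prod(shape))
    if n_vox < len(present):
        raise ValueError(
            f"shape {shape} has {n_vox} voxels, cannot host {len(present)} labels"
        )

    rng = np.random.default_rng(seed)
    lab = np.zeros(shape, dtype=np.int32)
    flat = rng.permutation(n_vox)
    # round-robin assignment: each present label gets ceil-share of voxels >= 1
    assignment = np.zeros(n_vox, dtype=np.int32)
    per = n_vox // len(present)
    for i, l in enumerate(present):
        lo = i * per
        hi = (i + 1) * per if i < len(present) - 1 else n_vox
        assignment[lo:hi] = l
    lab.flat[flat] = assignment

    constants = {l: float(np.round(rng.uniform(-5, 5), 3)) for l in present}
    metric = np.zeros(shape, dtype=float)
    for l, c in constants.items():
        metric[lab == l] = c

    vol = LabelVolume(
        labels=lab,
        voxel_size=voxel_size,
        empty_labels=set(empty_labels),
    )
    return vol, metric, constants


#: Printed group summaries (mean, sd per class) used as simulation defaults.
TABLE1_DEMOGRAPHICS = {
    "age": {"AD": (67.70, 5.24), "MCI": (67.11, 7.22), "HC": (65.21, 7.42)},
    "education": {"AD": (9.45, 4.72), "MCI": (9.74, 4.18), "HC": (10.14, 4.33)},
    "MMSE": {"AD": (20.81, 2.25), "MCI": (24.96, 1.98), "HC": (28.76, 1.05)},
    "AVLT-ir": {"AD": (5.50, 3.46), "MCI": (7.95, 2.56), "HC": (13.00, 2.98)},
    "AVLT-dr": {"AD": (2.20, 2.55), "MCI": (4.15, 3.20), "HC": (9.89, 2.72)},
    "AVLT-r": {"AD": (4.45, 2.69), "MCI": (7.05, 3.51), "HC": (11.53, 2.24)},
}

#: CDR is a diagnostic constant per group, not a random draw.
CDR_BY_GROUP = {"AD": 1.0, "MCI": 0.5, "HC": 0.0}

#: Printed male/female counts per group, used for sex assignment proportions.
SEX_COUNTS = {"AD": (24, 20), "MCI": (30, 36), "HC": (26, 32)}


def generate_demographics(spec: CohortSpec) -> pd.DataFrame:
    """One row per subject: group, sex, age, education, CDR, MMSE, AVLT scores.

    Clinical scores are independent per-group Gaussians with the study's
    printed means/SDs; sex follows the printed male fraction of each group.
    """
    rng = np.random.default_rng(spec.seed + 1)  # decoupled from feature noise
    rows = []
    for cls in CLASSES:
        n = spec.n_per_class[cls]
        m, f = SEX_COUNTS[cls]
        p_male = m / (m + f)
        for i in range(n):
            row = {
                "subject_id": f"{cls}{i:03d}",
                "group": cls,
                "sex": "M" if rng.random() < p_male else "F",
                "CDR": CDR_BY_GROUP[cls],
            }
            for trait, per_group in TABLE1_DEMOGRAPHICS.items():
                mu, sd = per_group[cls]
                row[trait] = rng.normal(mu, sd)
            rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def oracle_cohort(
    n_per_class: dict[str, int] | None = None,
    n_signal_columns: int = 4,
    effect: float = 6.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> FeatureTable:
    """Separable three-class cohort for end-to-end oracle checks.

    Plants strong (``effect``·sigma) class-dependent offsets in a few HE and
    GMV columns so the three groups are essentially linearly separable; the
    cascade should reach ~100% accuracy on it.
    """
    if n_per_class is None:
        n_per_class = {"AD": 20, "MCI": 20, "HC": 20}
    labels = aal3_usable_labels()
    effects: EffectMap = []
    patterns = [
        (0.0, effect, 2 * effect),
        (2 * effect, 0.0, effect),
        (effect, 2 * effect, 0.0),
        (0.0, 2 * effect, effect),
    ]
    metrics_cycle = ["HE", "GMV", "HE", "GMV", "L.Hip", "R.Hip"]
    for i in range(n_signal_columns):
        metric = metrics_cycle[i % len(metrics_cycle)]
        label = labels[(7 * i + 3) % len(labels)]
        if (metric, label) in SEED_EXCLUSIONS.items():
            label = labels[(7 * i + 4) % len(labels)]
        effects.append((metric, label, patterns[i % len(patterns)]))
    spec = CohortSpec(
        n_per_class=dict(n_per_class),
        effect_map=effects,
        noise_sd=noise_sd,
        seed=seed,
    )
    return generate_feature_table(spec)
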