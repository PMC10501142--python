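"""Signal cleaning and the two fMRI-derived ROI statistics.

The processing order is fixed: confound regression, then band-pass
filtering, then metric computation (Hurst exponent by rescaled-range
analysis; seed-based Pearson connectivity).  Cleaning uses ordinary least
squares against the nuisance set (motion parameters, global/WM/CSF means);
filtering is an ideal rectangular filter in the DFT domain, the convention
of the resting-state toolchains this pipeline mirrors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "RoiTimeSeries",
    "ConfoundSet",
    "HurstEstimate",
    "regress_confounds",
    "bandpass_filter",
    "default_window_sizes",
    "expected_rs_anis_lloyd",
    "hurst_rs",
    "hurst_map",
    "seed_connectivity",
]


@dataclass
class RoiTimeSeries:
    """A time × unit signal matrix with its sampling interval (TR) in seconds."""

    data: np.ndarray
    dt: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.data.ndim != 2:
            raise ValueError("data must be a time × unit matrix")
        if self.data.shape[0] < 16:
            raise ValueError(f"need >= 16 time points, got {self.data.shape[0]}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_units(self) -> int:
        return self.data.shape[1]

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.dt


@dataclass
class ConfoundSet:
    """Nuisance regressors (time × k): motion parameters, global/WM/CSF means."""

    regressors: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regressors = np.asarray(self.regressors, dtype=float)
        if self.regressors.ndim == 1:
            self.regressors = self.regressors[:, None]
        if self.regressors.size and self.regressors.ndim != 2:
            raise ValueError("regressors must be a time × k matrix")
        if not self.names:
            k = self.regressors.shape[1] if self.regressors.size else 0
            self.names = [f"confound_{i}" for i in range(k)]

    @classmethod
    def empty(cls, n_timepoints: int) -> "ConfoundSet":
        return cls(regressors=np.empty((n_timepoints, 0)), names=[])


@dataclass
class HurstEstimate:
    """Result of a rescaled-range fit: H plus the per-window (R/S) curve."""

    H: float
    window_sizes: list[int]
    rs_values: list[float]
    fit_r2: float
    corrected: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.H):
            raise ValueError("H is not finite")
        if not 0.0 <= self.H <= 1.0:
            warnings.warn(
                f"estimated H={self.H:.3f} outside [0, 1]; series may be "
                "too short or strongly trended",
                stacklevel=3,
            )


def regress_confounds(series: RoiTimeSeries, confounds: ConfoundSet) -> RoiTimeSeries:
    """OLS residuals of every unit on [intercept | confounds].

    With an empty confound set this reduces to removing each unit's temporal
    mean.  The design must be full column rank; collinear columns are named
    in the error.
    """
    T = series.n_timepoints
    R = confounds.regressors
    if R.size and R.shape[0] != T:
        raise ValueError(
            f"confound length {R.shape[0]} does not match series length {T}"
        )
    design = np.column_stack([np.ones(T), R]) if R.size else np.ones((T, 1))
    names = ["intercept"] + list(confounds.names)

    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns via QR pivot magnitude
        _, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in range(len(diag)) if diag[i] < 1e-10 * diag.max()]
        raise ValueError(f"confound design is rank deficient; collinear columns: {bad}")

    beta, *_ = np.linalg.lstsq(design, series.data, rcond=None)
    resid = series.data - design @ beta
    return RoiTimeSeries(data=resid, dt=series.dt)


def bandpass_filter(series: RoiTimeSeries, low_hz: float, high_hz: float) -> RoiTimeSeries:
    """Ideal rectangular band-pass in the DFT domain.

    Coefficients at frequencies outside [low_hz, high_hz] (both conjugate
    halves) are zeroed and the inverse transform returned.  The DC bin is
    dropped whenever low_hz > 0, so the output is mean-free.
    """
    nyq = series.nyquist_hz
    if not 0.0 <= low_hz < high_hz:
        raise ValueError(f"need 0 <= low < high, got [{low_hz}, {high_hz}]")
    if high_hz > nyq + 1e-12:
        raise ValueError(f"high_hz={high_hz} exceeds Nyquist {nyq:.4f} Hz")
    T = series.n_timepoints
    freqs = np.fft.rfftfreq(T, d=series.dt)
    keep = (freqs >= low_hz - 1e-12) & (freqs <= high_hz + 1e-12)
    spec = np.fft.rfft(series.data, axis=0)
    spec[~keep, :] = 0.0
    out = np.fft.irfft(spec, n=T, axis=0)
    return RoiTimeSeries(data=out, dt=series.dt)


def default_window_sizes(length: int) -> list[int]:
    """Power-of-two R/S window ladder spanning [length/16, length/2].

    The lower cut drops the smallest windows, where the rescaled-range
    statistic of a dependent series is still far from its asymptotic
    power law and drags the log–log slope toward 0.5 (calibrated against
    exact-covariance fGn).  Windows never go below 8.
    """
    if length < 16:
        raise ValueError("series too short for R/S analysis")
    lo = max(8, length // 16)
    hi = length // 2
    sizes = []
    w = 8
    while w <= hi:
        if w >= lo:
            sizes.append(w)
        w *= 2
    if len(sizes) < 2:  # very short series: fall back to everything >= 8
        sizes = []
        w = 8
        while w <= hi:
            sizes.append(w)
            w *= 2
    return sizes


def expected_rs_anis_lloyd(n: int) -> float:
    """Anis–Lloyd expected R/S of an i.i.d. series of length n.

    Includes the (n - 1/2)/n finite-sample factor; the small-n branch uses
    the exact Gamma-ratio front factor, the large-n branch its Stirling
    limit 1/sqrt(n*pi/2).
    """
    if n < 2:
        raise ValueError("window must have n >= 2")
    i = np.arange(1, n)
    s = float(np.sum(np.sqrt((n - i) / i)))
    if n <= 340:
        front = float(np.exp(gammaln((n - 1) / 2.0) - gammaln(n / 2.0)) / np.sqrt(np.pi))
    else:
        front = 1.0 / np.sqrt(n * np.pi / 2.0)
    return (n - 0.5) / n * front * s


def _rs_at_window(x: np.ndarray, n: int) -> float:
    """Mean rescaled range over non-overlapping blocks of size n.

    Per block: R = range of the cumulative sum of mean-centred values,
    S = sample standard deviation (ddof=1); degenerate (S=0) blocks are
    dropped.  Returns NaN when every block is degenerate.
    """
    nb = len(x) // n
    b = x[: nb * n].reshape(nb, n)
    dev = b - b.mean(axis=1, keepdims=True)
    z = np.cumsum(dev, axis=1)
    R = z.max(axis=1) - z.min(axis=1)
    S = b.std(axis=1, ddof=1)
    ok = S > 0
    if not ok.any():
        return np.nan
    return float(np.mean(R[ok] / S[ok]))


def hurst_rs(
    series: np.ndarray,
    window_sizes: list[int] | None = None,
    corrected: bool = True,
) -> HurstEstimate:
    """Hurst exponent by rescaled-range (R/S) analysis.

    H is the least-squares slope of log(R/S)_n on log n over the window
    ladder.  With ``corrected`` (default), the Anis–Lloyd expected R/S of
    i.i.d. data is subtracted and the asymptotic sqrt(n*pi/2) added back
    before fitting, which removes the small-sample bias that otherwise
    pushes white-noise estimates well above 0.5.
    """
    x = np.asarray(series, dtype=float).ravel()
    if window_sizes is None:
        window_sizes = default_window_sizes(len(x))
    window_sizes = sorted(int(w) for w in window_sizes)
    if any(w < 8 for w in window_sizes):
        raise ValueError("window sizes must be >= 8")
    if len(set(window_sizes)) < 2:
        raise ValueError("need at least two distinct window sizes")
    if len(x) < 2 * max(window_sizes):
        raise ValueError(
            f"series length {len(x)} < 2 × max window {max(window_sizes)}"
        )

    log_n, log_rs, rs_out = [], [], []
    for n in window_sizes:
        rs = _rs_at_window(x, n)
        if not np.isfinite(rs):
            continue
        rs_out.append(rs)
        if corrected:
            rs = rs - expected_rs_anis_lloyd(n) + np.sqrt(n * np.pi / 2.0)
        if rs <= 0:
            continue
        log_n.append(np.log(n))
        log_rs.append(np.log(rs))
    if len(log_n) < 2:
        raise ValueError("all R/S blocks degenerate; cannot estimate H")

    ln = np.asarray(log_n)
    lr = np.asarray(log_rs)
    A = np.column_stack([ln, np.ones_like(ln)])
    coef, *_ = np.linalg.lstsq(A, lr, rcond=None)
    fitted = A @ coef
    ss_res = float(np.sum((lr - fitted) ** 2))
    ss_tot = float(np.sum((lr - lr.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return HurstEstimate(
        H=float(coef[0]),
        window_sizes=window_sizes,
        rs_values=rs_out,
        fit_r2=r2,
        corrected=corrected,
    )


def hurst_map(
    series: RoiTimeSeries,
    window_sizes: list[int] | None = None,
    corrected: bool = True,
) -> np.ndarray:
    """Per-unit Hurst exponents; failed units become NaN with a warning."""
    out = np.full(series.n_units, np.nan)
    failed = []
    for j in range(series.n_units):
        try:
            out[j] = hurst_rs(series.data[:, j], window_sizes, corrected).H
        except ValueError:
            failed.append(j)
    if failed:
        warnings.warn(f"Hurst estimation failed for units {failed}; set to NaN")
    return out


def seed_connectivity(
    series: RoiTimeSeries,
    seed_units: list[int],
    fisher_z: bool = False,
) -> np.ndarray:
    """Pearson correlation of every unit with the mean seed signal.

    The seed reference is the unweighted mean over ``seed_units``.  Zero
    variance units yield NaN with a warning.  ``fisher_z`` applies atanh.
    """
    if not seed_units:
        raise ValueError("seed_units must be non-empty")
    X = series.data
    ref = X[:, seed_units].mean(axis=1)
    ref_c = ref - ref.mean()
    ref_ss = float(ref_c @ ref_c)
    if ref_ss == 0:
        raise ValueError("seed reference has zero variance")
    Xc = X - X.mean(axis=0, keepdims=True)
    denom = np.sqrt(np.sum(Xc**2, axis=0) * ref_ss)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ ref_c) / denom
    zero_var = np.sum(Xc**2, axis=0) == 0
    if zero_var.any():
        warnings.warn(
            f"zero-variance units {np.flatnonzero(zero_var).tolist()}; correlations set to NaN"
        )
        r[zero_var] = np.nan
    r = np.clip(r, -1.0, 1.0)
    if fisher_z:
        with np.errstate(divide="ignore"):
            r = np.arctanh(r)
    return r
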