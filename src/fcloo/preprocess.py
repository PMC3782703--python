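"""BOLD time-series cleaning: detrend + bandpass, nuisance regression, and
motion scrubbing with retained-volume accounting.

Conventions chosen where the field offers more than one:

* The bandpass is an FFT-domain ideal mask applied after linear detrending —
  deterministic and with exactly testable gains, at the cost of the usual
  sharp-cutoff ringing (irrelevant for correlation estimates).
* Framewise displacement (FD) is the root-mean-square of the six frame-to-
  frame rigid-body parameter differences, rotations converted to arc length at
  a 50 mm radius.  The L1 variant (sum of absolute differences, the other
  common convention) is available via ``mode="l1"``.
* DVARS is the RMS temporal difference across channels, by default divided by
  the series' global standard deviation so that one numeric threshold can be
  applied to FD (mm) and DVARS (signal units) alike; the scaling is a knob.
* FD[0] and DVARS[0] are defined as 0: the first frame is never flagged by
  itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.signal
from scipy import stats


class PreprocessError(ValueError):
    """Raised on invalid preprocessing inputs."""


@dataclass
class BandpassParams:
    """Passband (Hz) and repetition time (s) for temporal filtering."""

    low: float = 0.001
    high: float = 0.1
    tr: float = 2.0

    def __post_init__(self) -> None:
        nyquist = 1.0 / (2.0 * self.tr)
        if not (0.0 <= self.low < self.high):
            raise PreprocessError("need 0 <= low < high")
        if self.high >= nyquist:
            raise PreprocessError(
                f"high cutoff {self.high} Hz is at or above the Nyquist limit "
                f"{nyquist} Hz for TR={self.tr} s"
            )


@dataclass
class ScrubParams:
    """Motion-scrub thresholding: flag FD/DVARS above ``threshold`` and drop
    ``drop_before``/``drop_after`` neighbors of every flagged frame."""

    threshold: float = 0.2
    rotation_radius: float = 50.0
    drop_before: int = 1
    drop_after: int = 1

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise PreprocessError("threshold must be positive")


def _as_2d(series: np.ndarray) -> np.ndarray:
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[None, :]
    if series.ndim != 2:
        raise PreprocessError("series must be channels x T")
    return series


def temporal_filter(series: np.ndarray, params: BandpassParams) -> np.ndarray:
    """Linear detrend combined with an ideal FFT bandpass, per channel.

    Frequencies f with params.low <= f <= params.high are retained exactly and
    everything else (including DC unless low == 0) is zeroed; the trend
    component that survives inside the passband is then removed, making the
    whole operation one orthogonal projection (onto the intersection of the
    band-limited subspace and the trend-free subspace).  Applying the filter
    twice therefore reproduces the first application to round-off, and each
    output channel has |mean| < 1e-8 times its standard deviation.
    """
    x = _as_2d(series)
    T = x.shape[1]
    if T < 8:
        raise PreprocessError("need at least 8 volumes to filter")
    freqs = np.fft.rfftfreq(T, d=params.tr)
    keep = (freqs >= params.low) & (freqs <= params.high)

    def band_project(y: np.ndarray) -> np.ndarray:
        spec = np.fft.rfft(y, axis=-1)
        spec[..., ~keep] = 0.0
        return np.fft.irfft(spec, n=T, axis=-1)

    x = scipy.signal.detrend(x, axis=1, type="linear")
    y = band_project(x)
    # remove what remains of the trend basis inside the passband
    t = np.arange(T, dtype=float)
    trend = np.stack([np.ones(T), t - t.mean()])
    basis = band_project(trend)
    basis = basis[np.linalg.norm(basis, axis=1) > 1e-9 * np.sqrt(T)]
    if basis.size:
        coef, *_ = np.linalg.lstsq(basis.T, y.T, rcond=None)
        y = y - (basis.T @ coef).T
    return y


def nuisance_regression(series: np.ndarray, nuisance: np.ndarray) -> np.ndarray:
    """Residualize each channel on the nuisance regressors plus an intercept.

    Rank-deficient nuisance sets are handled by a minimum-norm least-squares
    fit (equivalent to dropping dependent columns for the residual) with a
    warning.  Residuals are orthogonal to every regressor.
    """
    y = _as_2d(series)
    nuis = _as_2d(nuisance)
    T = y.shape[1]
    if nuis.shape[1] != T:
        raise PreprocessError("series and nuisance must share T")
    if nuis.shape[0] >= T:
        raise PreprocessError("need fewer nuisance regressors than time points")
    if not np.isfinite(nuis).all():
        raise PreprocessError("nuisance regressors must be finite")
    X = np.column_stack([np.ones(T), nuis.T])
    beta, _, rank, _ = np.linalg.lstsq(X, y.T, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            f"nuisance design is rank deficient ({rank} < {X.shape[1]}); "
            "dependent columns ignored",
            RuntimeWarning,
            stacklevel=2,
        )
    return y - (X @ beta).T


def framewise_displacement(
    motion: np.ndarray, rotation_radius: float = 50.0, mode: str = "rms"
) -> np.ndarray:
    """Per-frame head displacement from 6 rigid-body parameters.

    ``motion`` rows are 3 translations (mm) then 3 rotations (radians);
    rotations become arc length at ``rotation_radius`` mm.  ``mode="rms"``
    (default) returns the root-mean-square of the 6 differences; ``mode="l1"``
    the sum of absolute differences.  FD[0] = 0.
    """
    m = np.asarray(motion, dtype=float)
    if m.ndim != 2 or m.shape[0] != 6:
        raise PreprocessError("motion must be a 6 x T array")
    if m.shape[1] < 2:
        raise PreprocessError("need at least 2 frames")
    d = np.diff(m, axis=1)
    d[3:] *= rotation_radius
    if mode == "rms":
        fd = np.sqrt(np.mean(d**2, axis=0))
    elif mode == "l1":
        fd = np.sum(np.abs(d), axis=0)
    else:
        raise ValueError(f"unknown FD mode {mode!r}")
    return np.concatenate([[0.0], fd])


def dvars(series: np.ndarray, scale: str | float | None = "sd") -> np.ndarray:
    """RMS temporal difference across channels; DVARS[0] = 0.

    ``scale="sd"`` divides by the global standard deviation of the series (so
    one threshold applies to normalized data); a float divides by that value;
    ``None`` returns the raw RMS difference.
    """
    x = _as_2d(series)
    if x.shape[1] < 2:
        raise PreprocessError("need at least 2 frames")
    raw = np.sqrt(np.mean(np.diff(x, axis=1) ** 2, axis=0))
    if scale == "sd":
        sd = x.std()
        raw = raw / sd if sd > 0 else raw
    elif scale is not None:
        raw = raw / float(scale)
    return np.concatenate([[0.0], raw])


def scrub_mask(fd: np.ndarray, dv: np.ndarray, params: ScrubParams) -> np.ndarray:
    """Boolean retained-frame mask for the given FD and DVARS traces."""
    fd = np.asarray(fd, dtype=float)
    dv = np.asarray(dv, dtype=float)
    if fd.shape != dv.shape:
        raise PreprocessError("fd and dvars lengths differ")
    T = fd.shape[0]
    flagged = (fd > params.threshold) | (dv > params.threshold)
    removed = np.zeros(T, dtype=bool)
    for t in np.flatnonzero(flagged):
        lo = max(0, t - params.drop_before)
        hi = min(T, t + params.drop_after + 1)
        removed[lo:hi] = True
    return ~removed


def scrub(
    series: np.ndarray,
    fd: np.ndarray,
    dv: np.ndarray,
    params: ScrubParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove flagged frames (and neighbors) and concatenate survivors.

    A frame is removed when FD or DVARS exceeds the threshold, or when it lies
    within ``drop_before``/``drop_after`` frames of such a frame.  Returns the
    concatenated series and the boolean retained mask (mask.sum() == T').
    """
    params = params or ScrubParams()
    x = _as_2d(series)
    if x.shape[1] != len(np.asarray(fd)):
        raise PreprocessError("series and fd lengths differ")
    mask = scrub_mask(fd, dv, params)
    if not mask.any():
        raise PreprocessError("motion scrubbing removed all frames (0 retained)")
    return x[:, mask], mask


@dataclass
class RetentionSummary:
    """Cohort-level retained-volume statistics."""

    n: int
    fraction_over_half: float
    fraction_over_half_by_group: dict[str, float]
    proportion_z: float
    proportion_p: float
    t_stat: float
    t_p: float
    degenerate: bool


def retained_volume_stats(records) -> RetentionSummary:
    """Summarize motion-scrub retention across a cohort.

    Reports the fraction of subjects retaining more than half their acquired
    volumes (overall and per diagnosis, compared by a pooled two-proportion
    z-test) and a pooled two-sample t-test on retained counts by diagnosis.
    Zero-variance retained counts are flagged degenerate (t reported as 0).
    """
    from .evaluation import two_proportion_z

    rows = [
        (r.diagnosis, r.n_volumes_acquired, r.n_volumes_retained)
        for r in records
        if r.n_volumes_acquired is not None and r.n_volumes_retained is not None
    ]
    if not rows:
        raise PreprocessError("no records carry retained-volume counts")
    groups = {
        d: [(a, ret) for (dd, a, ret) in rows if dd == d] for d in ("autism", "control")
    }
    if any(len(v) == 0 for v in groups.values()):
        raise PreprocessError("a diagnosis group has no retained-volume data")

    over = {d: sum(1 for a, ret in v if ret / a > 0.5) for d, v in groups.items()}
    fracs = {d: over[d] / len(groups[d]) for d in groups}
    z, pz = two_proportion_z(
        over["autism"], len(groups["autism"]), over["control"], len(groups["control"])
    )
    ret_a = np.array([ret for _, ret in groups["autism"]], dtype=float)
    ret_c = np.array([ret for _, ret in groups["control"]], dtype=float)
    degenerate = ret_a.std(ddof=1 if len(ret_a) > 1 else 0) == 0 and ret_c.std(
        ddof=1 if len(ret_c) > 1 else 0
    ) == 0
    if degenerate:
        t, pt = (0.0, 1.0) if ret_a.mean() == ret_c.mean() else (float("nan"), float("nan"))
    else:
        t, pt = stats.ttest_ind(ret_a, ret_c, equal_var=True)
    total = sum(len(v) for v in groups.values())
    return RetentionSummary(
        n=total,
        fraction_over_half=sum(over.values()) / total,
        fraction_over_half_by_group=fracs,
        proportion_z=float(z),
        proportion_p=float(pz),
        t_stat=float(t),
        t_p=float(pt),
        degenerate=bool(degenerate),
    )
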