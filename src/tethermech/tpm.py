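"""Tethered-particle-motion pipeline: trajectories -> screened RMS -> persistence length.

A tethered bead is imaged at video rate (25 Hz here) and its in-plane
centroid position recorded. The pipeline stages are:

1. read/validate a trajectory,
2. high-pass drift correction (moving-average subtraction),
3. windowed RMS excursion (4 s default, matching the acquisition protocol),
4. screening: circularity of the motion (multiple tethers are anisotropic)
   and detection of discrete stuck-bead drops,
5. inversion of the mean RMS to a persistence length via the
   Gaussian-chain bead-excursion relation in :mod:`tethermech.models`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .models import NoSolutionError, persistence_from_rms

__all__ = [
    "Trajectory",
    "RmsSeries",
    "ScreenReport",
    "StuckEvent",
    "PersistenceEstimate",
    "NonStationaryError",
    "read_trajectory",
    "write_trajectory",
    "read_rms_series",
    "write_rms_series",
    "drift_filter",
    "windowed_rms",
    "circularity_screen",
    "detect_stuck_events",
    "mask_stuck_events",
    "persistence_from_trajectory",
]


class NonStationaryError(ValueError):
    """The record's RMS level changes too much for a stationary estimate."""


@dataclass
class Trajectory:
    """In-plane positions of one tethered bead, uniformly sampled.

    ``t`` in seconds, ``x``/``y`` in nm relative to an arbitrary origin.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    bead_id: str = "bead0"
    sample_rate: float = 25.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.t)
        if n < 2 or len(self.x) != n or len(self.y) != n:
            raise ValueError("t, x, y must have equal length >= 2")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("positions must be finite")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
        dt0 = dt.mean()
        if np.max(np.abs(dt - dt0)) > 1e-6 * max(dt0, 1.0) + 1e-12:
            raise ValueError("non-uniform sampling beyond tolerance")
        self.sample_rate = 1.0 / dt0

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class RmsSeries:
    """Windowed RMS excursion versus time; the observable of TPM kinetics."""

    t: np.ndarray
    rms: np.ndarray
    window: float = 4.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.rms = np.asarray(self.rms, dtype=float)
        if len(self.t) != len(self.rms):
            raise ValueError("t and rms must have equal length")
        if not self.window > 0:
            raise ValueError("window must be > 0")
        if np.any(self.rms[np.isfinite(self.rms)] < 0):
            raise ValueError("rms values must be >= 0")


@dataclass
class StuckEvent:
    """A discrete, persistent drop of the RMS level (bead stuck to surface)."""

    time: float
    magnitude: float  # nm, pre-drop minus post-drop level


@dataclass
class ScreenReport:
    """Outcome of the multiple-tether / stuck-bead screen for one bead."""

    bead_id: str
    circularity: float
    passed: bool
    threshold: float = 0.10
    stuck_events: list[StuckEvent] = field(default_factory=list)
    drift_removed_nm: float = 0.0
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "bead_id": self.bead_id,
            "circularity": self.circularity,
            "passed": bool(self.passed),
            "threshold": self.threshold,
            "stuck_events": [[e.time, e.magnitude] for e in self.stuck_events],
            "drift_removed_nm": self.drift_removed_nm,
            "note": self.note,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


# ---------------------------------------------------------------- I/O


def _sniff_sep(path: Path) -> str:
    for line in path.read_text().splitlines():
        if line.strip() and not line.lstrip().startswith("#"):
            return "\t" if "\t" in line else ","
    raise ValueError(f"{path}: no data lines")


def read_trajectory(path: str | Path, bead_id: str | None = None) -> Trajectory:
    """Read a trajectory CSV/TSV with header ``time_s,x_nm,y_nm[,bead_id]``.

    Comment lines start with ``#``. Malformed (non-numeric) rows are
    reported with their line numbers; non-uniform timestamps raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    required = {"time_s", "x_nm", "y_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    num = df[["time_s", "x_nm", "y_nm"]].apply(pd.to_numeric, errors="coerce")
    bad = num.isna().any(axis=1)
    if bad.any():
        lines = (num.index[bad] + 2).tolist()  # +1 header, +1 one-based
        raise ValueError(f"{path}: non-numeric entries at lines {lines[:10]}")
    if bead_id is None:
        bead_id = str(df["bead_id"].iloc[0]) if "bead_id" in df.columns else path.stem
    return Trajectory(
        t=num["time_s"].to_numpy(),
        x=num["x_nm"].to_numpy(),
        y=num["y_nm"].to_numpy(),
        bead_id=bead_id,
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": traj.t, "x_nm": traj.x, "y_nm": traj.y, "bead_id": traj.bead_id}
    ).to_csv(path, index=False)


def read_rms_series(path: str | Path, window: float = 4.0) -> RmsSeries:
    df = pd.read_csv(path, comment="#")
    return RmsSeries(df["time_s"].to_numpy(), df["rms_nm"].to_numpy(), window=window)


def write_rms_series(series: RmsSeries, path: str | Path) -> None:
    pd.DataFrame({"time_s": series.t, "rms_nm": series.rms}).to_csv(path, index=False)


# ---------------------------------------------------------------- filters


def drift_filter(traj: Trajectory, cutoff_window: float = 20.0) -> Trajectory:
    """Remove slow stage drift by subtracting a centered moving average.

    ``cutoff_window`` (s) sets the averaging span per axis; it must exceed
    the RMS window downstream so genuine tether motion is preserved.
    Endpoint windows shrink, so a constant offset is removed everywhere.
    """
    if not cutoff_window > 0:
        raise ValueError("cutoff_window must be > 0")
    span = max(int(round(cutoff_window * traj.sample_rate)), 1)
    out = {}
    for name in ("x", "y"):
        v = pd.Series(getattr(traj, name))
        baseline = v.rolling(span, center=True, min_periods=1).mean().to_numpy()
        out[name] = v.to_numpy() - baseline
    return Trajectory(t=traj.t.copy(), x=out["x"], y=out["y"], bead_id=traj.bead_id)


def drift_magnitude(traj: Trajectory, cutoff_window: float = 20.0) -> float:
    """RMS magnitude (nm) of the low-frequency displacement a drift filter removes."""
    filtered = drift_filter(traj, cutoff_window)
    dx = traj.x - traj.x.mean() - filtered.x
    dy = traj.y - traj.y.mean() - filtered.y
    return float(np.sqrt(np.mean(dx**2 + dy**2)))


def windowed_rms(
    traj: Trajectory, window: float = 4.0, center: str = "window"
) -> RmsSeries:
    """Dense moving-window RMS excursion of the in-plane position.

    For each window the RMS is ``sqrt(mean((x - xm)^2 + (y - ym)^2))``.
    With ``center="window"`` (default) ``xm, ym`` are the in-window means,
    so residual slow drift does not inflate the RMS; ``center="global"``
    uses the whole-record means instead. Window stride is one frame; output
    timestamps are window centers and the length is
    ``len(traj) - span + 1``.
    """
    span = int(round(window * traj.sample_rate))
    if span < 2:
        raise ValueError("window must span at least 2 samples")
    if span > len(traj):
        raise ValueError("trajectory shorter than one window")
    if center not in ("window", "global"):
        raise ValueError("center must be 'window' or 'global'")

    def _roll_mean(v: np.ndarray) -> np.ndarray:
        c = np.concatenate(([0.0], np.cumsum(v)))
        return (c[span:] - c[:-span]) / span

    x, y = traj.x, traj.y
    if center == "global":
        x = x - x.mean()
        y = y - y.mean()
    m2 = _roll_mean(x**2) + _roll_mean(y**2)
    if center == "window":
        m2 = m2 - _roll_mean(x) ** 2 - _roll_mean(y) ** 2
    t = _roll_mean(traj.t)
    return RmsSeries(t=t, rms=np.sqrt(np.maximum(m2, 0.0)), window=window)


# ---------------------------------------------------------------- screening


def circularity_screen(
    traj: Trajectory,
    threshold: float = 0.10,
    metric: str = "covariance",
) -> ScreenReport:
    """Screen a bead for anisotropic motion (sign of multiple tethers).

    Circularity is ``sqrt(lambda_minor / lambda_major)`` from the
    eigenvalues of the 2x2 position covariance (rotation invariant);
    ``metric="axes"`` instead uses ``sigma_min/sigma_max`` along the fixed
    x/y axes. The bead passes when ``1 - circularity <= threshold``.
    A zero-variance record fails with a diagnostic rather than raising.
    """
    xc = traj.x - traj.x.mean()
    yc = traj.y - traj.y.mean()
    if metric == "covariance":
        cov = np.cov(np.vstack([xc, yc]))
        lam = np.sort(np.linalg.eigvalsh(cov))
        lo, hi = float(lam[0]), float(lam[1])
    elif metric == "axes":
        vx, vy = float(np.var(xc, ddof=1)), float(np.var(yc, ddof=1))
        lo, hi = min(vx, vy), max(vx, vy)
    else:
        raise ValueError("metric must be 'covariance' or 'axes'")
    if hi <= 0:
        return ScreenReport(
            traj.bead_id, 0.0, False, threshold, note="degenerate: zero variance"
        )
    circ = float(np.sqrt(max(lo, 0.0) / hi))
    return ScreenReport(traj.bead_id, circ, (1.0 - circ) <= threshold, threshold)


def detect_stuck_events(
    series: RmsSeries, drop_fraction: float = 0.5, dwell: float = 10.0
) -> list[StuckEvent]:
    """Find discrete, persistent RMS drops (bead sticking to the coverslip).

    Compares the median RMS over the ``dwell`` seconds before and after
    each sample; a drop by more than ``drop_fraction`` of the pre-level
    that persists for the dwell is one event. Smooth collapse (minutes-long
    exponential decay) changes the level by only a few percent per dwell
    and is never flagged.
    """
    n = len(series.rms)
    if n < 4:
        return []
    dt = float(np.median(np.diff(series.t))) if n > 1 else 1.0
    k = max(int(round(dwell / dt)), 2)
    if 2 * k > n:
        k = n // 2
    r = pd.Series(series.rms)
    med = r.rolling(k).median()
    before = med.shift(1).to_numpy()  # median over [i-k, i-1]
    after = med.shift(-(k - 1)).to_numpy()  # median over [i, i+k-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        drop = 1.0 - after / before
    flag = np.nan_to_num(drop, nan=0.0) >= drop_fraction

    events: list[StuckEvent] = []
    i = 0
    while i < n:
        if flag[i]:
            j = i
            while j + 1 < n and flag[j + 1]:
                j += 1
            # the max-drop plateau is symmetric about the step; use its center
            run = drop[i : j + 1]
            top = np.flatnonzero(run >= np.nanmax(run) - 1e-9)
            peak = i + int(top[(len(top) - 1) // 2])
            events.append(
                StuckEvent(
                    time=float(series.t[peak]),
                    magnitude=float(before[peak] - after[peak]),
                )
            )
            i = j + 1
        else:
            i += 1
    return events


def mask_stuck_events(
    series: RmsSeries,
    events: list[StuckEvent],
    recovery_fraction: float = 0.8,
) -> RmsSeries:
    """Cleaned copy with stuck spans set to NaN.

    Each event masks from its onset until the RMS recovers above
    ``recovery_fraction`` of the pre-event level (or to the record end).
    """
    rms = series.rms.copy().astype(float)
    for ev in events:
        i0 = int(np.searchsorted(series.t, ev.time))
        pre = rms[max(i0 - 1, 0)] if i0 > 0 else rms[0]
        level = recovery_fraction * pre
        i1 = i0
        while i1 < len(rms) and not rms[i1] >= level:
            i1 += 1
        rms[i0:i1] = np.nan
    return RmsSeries(series.t.copy(), rms, window=series.window)


# ---------------------------------------------------------------- estimation


@dataclass
class PersistenceEstimate:
    """Persistence length inferred from one trajectory's mean RMS excursion."""

    persistence_length: float  # nm
    stderr: float  # nm
    r_rms: float  # nm, mean windowed RMS
    r_rms_stderr: float  # nm
    n_windows: int  # effective (non-overlapping) window count


def persistence_from_trajectory(
    traj: Trajectory,
    contour_length: float,
    bead_radius: float,
    window: float = 4.0,
    stationarity_tol: float = 0.10,
    center: str = "global",
) -> PersistenceEstimate:
    """Invert a stationary trajectory's mean windowed RMS to a persistence length.

    The record must be stationary: the first- and second-half mean RMS have
    to agree within ``stationarity_tol`` (collapse in progress makes the
    estimate meaningless). The overall RMS is the quadratic mean of the
    windowed values with whole-record (``center="global"``) centering by
    default: on a drift-filtered stationary record this is an unbiased
    variance estimate, whereas per-window centering absorbs a few percent
    of the variance when the window is only tens of correlation times
    long. The standard error of the RMS uses the count of non-overlapping
    windows as the effective sample size and is propagated through the
    local derivative of the excursion relation.

    Raises
    ------
    NonStationaryError
        If the half-record RMS levels disagree beyond tolerance.
    NoSolutionError
        If the measured RMS is outside the invertible range.
    """
    series = windowed_rms(traj, window=window, center=center)
    rms = series.rms
    if len(rms) >= 2:
        half = len(rms) // 2
        m1, m2 = float(np.mean(rms[:half])), float(np.mean(rms[half:]))
        if abs(m1 - m2) > stationarity_tol * max(m1, m2):
            raise NonStationaryError(
                f"half-record RMS differ: {m1:.1f} vs {m2:.1f} nm "
                f"(> {stationarity_tol:.0%})"
            )
    r_mean = float(np.sqrt(np.mean(rms**2)))
    n_eff = max(int(traj.duration // window), 1)
    r_se = float(np.std(rms, ddof=1) / np.sqrt(n_eff)) if len(rms) > 1 else 0.0

    xi = persistence_from_rms(r_mean, contour_length, bead_radius)
    # propagate via d(xi)/d(R_RMS), central difference
    h = max(1e-3 * r_mean, 1e-3)
    try:
        dxi = (
            persistence_from_rms(r_mean + h, contour_length, bead_radius)
            - persistence_from_rms(r_mean - h, contour_length, bead_radius)
        ) / (2 * h)
        xi_se = abs(dxi) * r_se
    except NoSolutionError:
        xi_se = float("nan")
    return PersistenceEstimate(xi, xi_se, r_mean, r_se, n_eff)
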