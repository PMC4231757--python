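"""Collapse kinetics of protein-bound DNA tethers from release-aligned RMS traces.

After a brief stretch the bead is released from the trap at ``t = 0`` and
its windowed RMS excursion tracked. Under bridging-competent protein the
RMS relaxes exponentially to a condensed plateau; controls that were never
stretched stay flat. This module reproduces that analysis: 60 s running
smoothing, ensemble averaging, exponential-decay fitting (time constant in
minutes), Gaussian fits to late-time RMS histograms, the compaction ratio
R_inf/R_0, and a saturating-exponential interpolation of persistence
length versus protein concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lmfit import Model

from .tpm import RmsSeries

__all__ = [
    "AlignedEnsemble",
    "AveragedSeries",
    "DecayFitResult",
    "HistogramFit",
    "TrendFit",
    "smooth_running_window",
    "ensemble_average",
    "fit_exponential_decay",
    "histogram_gaussian_fit",
    "compaction_ratio",
    "concentration_trend",
    "fit_concentration_trend",
]


@dataclass
class AlignedEnsemble:
    """RMS series of one experimental condition, aligned so t = 0 is release."""

    series: list[RmsSeries]
    protein: str = ""
    concentration_nm: float = 0.0
    control: bool = False  # never stretched; expected to stay flat

    def __post_init__(self) -> None:
        if not self.series:
            raise ValueError("ensemble needs at least one series")


@dataclass
class AveragedSeries:
    """Pointwise ensemble mean with the per-point contributing-series count."""

    series: RmsSeries
    counts: np.ndarray


@dataclass
class DecayFitResult:
    """Exponential relaxation R(t) = R_inf + (R_0 - R_inf) exp(-t/tau)."""

    r0: float  # nm
    r_inf: float  # nm
    tau_min: float  # minutes
    tau_stderr_min: float | None
    rss: float
    n_points: int
    identifiable: bool
    message: str = ""


@dataclass
class HistogramFit:
    """Gaussian fit to the pooled late-time RMS distribution of a condition."""

    mean: float  # nm
    sigma: float  # nm
    from_time_min: float
    n_samples: int
    flagged: bool = False
    note: str = ""


@dataclass
class TrendFit:
    """Saturating exponential xi(c) = xi_inf - (xi_inf - xi_0) exp(-c/c0)."""

    xi0: float
    xi_inf: float
    c0: float  # nM
    identifiable: bool
    note: str = ""

    def __call__(self, c):
        c = np.asarray(c, dtype=float)
        return self.xi_inf - (self.xi_inf - self.xi0) * np.exp(-c / self.c0)


# ---------------------------------------------------------------- smoothing


def smooth_running_window(series: RmsSeries, window: float = 60.0) -> RmsSeries:
    """Centered running mean over ``window`` seconds; length preserved.

    Endpoint windows shrink so no samples are lost. NaN samples (masked
    stuck spans) are ignored within each window.
    """
    if not window > 0:
        raise ValueError("window must be > 0")
    dt = float(np.median(np.diff(series.t))) if len(series.t) > 1 else window
    span = max(int(round(window / dt)), 1)
    sm = (
        pd.Series(series.rms)
        .rolling(span, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return RmsSeries(series.t.copy(), sm, window=series.window)


def ensemble_average(ens: AlignedEnsemble) -> AveragedSeries:
    """Pointwise mean RMS over the ensemble.

    Series are interpolated onto the time grid of the longest member;
    each contributes only within its own time support, and the per-point
    count of contributing series is reported.
    """
    ref = max(ens.series, key=lambda s: len(s.t))
    grid = ref.t
    stack = np.full((len(ens.series), len(grid)), np.nan)
    for i, s in enumerate(ens.series):
        inside = (grid >= s.t[0]) & (grid <= s.t[-1])
        good = np.isfinite(s.rms)
        if good.sum() >= 2:
            stack[i, inside] = np.interp(grid[inside], s.t[good], s.rms[good])
        elif good.sum() == 1:
            stack[i, inside] = s.rms[good][0]
    counts = np.sum(np.isfinite(stack), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    keep = counts > 0
    return AveragedSeries(
        RmsSeries(grid[keep], mean[keep], window=ref.window), counts[keep]
    )


# ---------------------------------------------------------------- decay fit


def _decay(t, amp, r_inf, tau):
    # amp = R_0 - R_inf; fitting the amplitude directly gives it a stderr,
    # which the no-significant-decay flag needs
    return r_inf + amp * np.exp(-t / tau)


def fit_exponential_decay(
    series: RmsSeries,
    offset: bool = True,
    max_tau_factor: float = 5.0,
    max_rel_stderr: float = 0.5,
) -> DecayFitResult:
    """Fit a decaying exponential to an RMS trace; tau reported in minutes.

    ``offset=False`` forces the plateau ``R_inf`` to zero. The fit is
    flagged unidentifiable (``identifiable=False``) when the time
    constant's relative standard error exceeds ``max_rel_stderr``, when it
    exceeds ``max_tau_factor`` times the record length, when it cannot be
    estimated at all, or when the decay amplitude ``R_0 - R_inf`` is
    within two standard errors of zero — a flat control trace lands in one
    of these rather than yielding a spurious time constant.
    """
    good = np.isfinite(series.rms)
    t, r = series.t[good], series.rms[good]
    if len(t) < 10:
        raise ValueError("need >= 10 finite points")
    span = float(t[-1] - t[0])
    n_head = max(len(r) // 20, 1)
    n_tail = max(len(r) // 10, 1)
    r0_init = float(np.mean(r[:n_head]))
    rinf_init = float(np.mean(r[-n_tail:])) if offset else 0.0

    model = Model(_decay, independent_vars=["t"])
    params = model.make_params(
        amp=r0_init - rinf_init, r_inf=rinf_init, tau=max(span / 3.0, 1e-6)
    )
    params["tau"].min = 1e-9
    params["r_inf"].min = 0.0
    if not offset:
        params["r_inf"].value = 0.0
        params["r_inf"].vary = False
    try:
        out = model.fit(r, params, t=t)
    except Exception as exc:  # pragma: no cover - lmfit is robust here
        return DecayFitResult(
            r0_init, rinf_init, float("nan"), None, float("nan"), len(t),
            identifiable=False, message=f"fit failed: {exc}",
        )
    tau_s = float(out.params["tau"].value)
    tau_se = out.params["tau"].stderr
    amp = float(out.params["amp"].value)
    amp_se = out.params["amp"].stderr
    rss = float(np.sum(out.residual**2))
    # smoothed RMS traces are heavily autocorrelated; inflate the white-noise
    # errors by the AR(1) effective-sample-size factor sqrt((1+rho)/(1-rho))
    resid = np.asarray(out.residual)
    if len(resid) > 2 and np.std(resid) > 0:
        rho = float(np.corrcoef(resid[:-1], resid[1:])[0, 1])
        rho = min(max(rho, 0.0), 1.0 - 1e-9)
        inflate = np.sqrt((1.0 + rho) / (1.0 - rho))
        tau_se = None if tau_se is None else tau_se * inflate
        amp_se = None if amp_se is None else amp_se * inflate
    identifiable, msg = True, ""
    if tau_s > max_tau_factor * span:
        identifiable, msg = False, "tau exceeds the record length many-fold"
    elif tau_se is None or amp_se is None:
        identifiable, msg = False, "parameter uncertainties not estimable"
    elif tau_se > max_rel_stderr * tau_s:
        identifiable, msg = False, "tau relative stderr above threshold"
    elif amp <= 2.0 * amp_se:
        identifiable, msg = False, "no significant decay amplitude"
    return DecayFitResult(
        r0=float(amp + out.params["r_inf"].value),
        r_inf=float(out.params["r_inf"].value),
        tau_min=tau_s / 60.0,
        tau_stderr_min=None if tau_se is None else tau_se / 60.0,
        rss=rss,
        n_points=len(t),
        identifiable=identifiable,
        message=msg,
    )


def compaction_ratio(fit: DecayFitResult) -> float:
    """Final over initial RMS level, ``R_inf / R_0`` (1/2-1/3 for collapse)."""
    if not fit.identifiable:
        raise ValueError("compaction ratio undefined for an unidentifiable fit")
    return fit.r_inf / fit.r0


# ---------------------------------------------------------------- histograms


def histogram_gaussian_fit(
    ens: AlignedEnsemble, from_time_min: float = 15.0, min_samples: int = 30
) -> HistogramFit:
    """Gaussian (maximum-likelihood) fit to pooled RMS samples after a cutoff.

    Pools every finite windowed-RMS sample later than ``from_time_min``
    across the condition's trajectories; the Gaussian MLE is the sample
    mean and standard deviation. Too few samples, or a degenerate
    zero-width distribution, sets ``flagged``.
    """
    cutoff = from_time_min * 60.0
    pooled = np.concatenate(
        [s.rms[(s.t >= cutoff) & np.isfinite(s.rms)] for s in ens.series]
    )
    n = len(pooled)
    if n == 0:
        raise ValueError(f"no samples after {from_time_min} min")
    mean = float(np.mean(pooled))
    sigma = float(np.std(pooled, ddof=0))
    if n < min_samples:
        return HistogramFit(mean, sigma, from_time_min, n, True, "too few samples")
    if sigma <= 1e-12 * max(abs(mean), 1.0):
        return HistogramFit(mean, sigma, from_time_min, n, True, "degenerate width")
    return HistogramFit(mean, sigma, from_time_min, n)


# ---------------------------------------------------------------- trends


def _saturating(c, xi0, xi_inf, c0):
    return xi_inf - (xi_inf - xi0) * np.exp(-c / c0)


def fit_concentration_trend(
    concentrations: np.ndarray, xi: np.ndarray
) -> TrendFit:
    """Descriptive saturating-exponential interpolation of xi vs concentration."""
    c = np.asarray(concentrations, dtype=float)
    x = np.asarray(xi, dtype=float)
    if len(c) < 3 or len(c) != len(x):
        raise ValueError("need >= 3 (concentration, xi) points")
    if np.ptp(x) <= 1e-9 * max(abs(x).max(), 1.0):
        return TrendFit(
            float(x.mean()), float(x.mean()), float("inf"), False, "flat data"
        )
    model = Model(_saturating, independent_vars=["c"])
    c_scale = max(c[c > 0].min(), 1.0) if np.any(c > 0) else 1.0
    params = model.make_params(
        xi0=float(x[np.argmin(c)]), xi_inf=float(x[np.argmax(c)]),
        c0=float(max(np.median(c), c_scale)),
    )
    params["c0"].min = 1e-6
    try:
        out = model.fit(x, params, c=c)
    except Exception:
        return TrendFit(float(x[0]), float(x[-1]), float("nan"), False, "fit failed")
    c0 = float(out.params["c0"].value)
    c0_se = out.params["c0"].stderr
    ident = c0_se is None or c0_se <= abs(c0)  # exact 3-point fits have no stderr
    if c0 > 100 * max(c.max(), c_scale):
        ident = False
    return TrendFit(
        float(out.params["xi0"].value),
        float(out.params["xi_inf"].value),
        c0,
        ident,
        "" if ident else "c0 unidentifiable",
    )


def concentration_trend(
    points: list[tuple[float, float, str]]
) -> dict[str, TrendFit]:
    """Fit the saturating trend separately per condition label.

    ``points`` holds ``(concentration_nM, xi_nm, condition)`` triples, e.g.
    condition in {"pre_stretch_tpm", "post_stretch_tpm", "force_extension"}.
    """
    by_cond: dict[str, list[tuple[float, float]]] = {}
    for conc, xi, cond in points:
        by_cond.setdefault(cond, []).append((conc, xi))
    out = {}
    for cond, pts in by_cond.items():
        arr = np.array(sorted(pts))
        out[cond] = fit_concentration_trend(arr[:, 0], arr[:, 1])
    return out
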