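"""Synthetic TPM trajectories and force-extension sweeps.

The generator emulates the statistical structure the analysis assumes, so
every pipeline stage can be exercised without laboratory data:

* each in-plane axis of the tethered bead is a mean-reverting
  (Ornstein-Uhlenbeck) Gaussian process with a finite positional
  correlation time ``tau_c`` and stationary per-axis standard deviation
  ``R_RMS/sqrt(2)``, where ``R_RMS`` comes from the Gaussian-chain
  bead-excursion relation;
* protein-induced condensation is an exponential relaxation of the
  excursion amplitude toward a plateau — exactly the observable the
  kinetics analysis fits, not a mechanistic bridging model;
* slow stage drift (linear or random walk), discrete stuck-bead drops,
  per-axis anisotropy (multiple-tether mimic) and white tracking noise
  are superimposed on demand;
* force-extension sweeps are the worm-like-chain force law plus Gaussian
  force noise, optionally with a contour length that shrinks between
  sweeps.

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .forceext import ForceExtensionCurve
from .models import TetherModel, rms_from_persistence, wlc_force
from .tpm import Trajectory, write_trajectory

__all__ = [
    "DriftSpec",
    "CollapseSpec",
    "StuckSpec",
    "TpmSimConfig",
    "FxSimConfig",
    "simulate_tpm",
    "simulate_fx",
    "make_fixture_suite",
]


@dataclass(frozen=True)
class DriftSpec:
    """Slow stage drift: total displacement ``amplitude`` nm over the record."""

    amplitude: float
    kind: str = "linear"  # "linear" | "random-walk"

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "random-walk"):
            raise ValueError("drift kind must be 'linear' or 'random-walk'")


@dataclass(frozen=True)
class CollapseSpec:
    """Exponential amplitude collapse after force release.

    ``tau_min`` is the relaxation time in minutes; ``plateau_fraction`` the
    condensed RMS as a fraction of the pre-collapse RMS; ``start_time``
    (s) when the relaxation begins (release is t = 0).
    """

    tau_min: float
    plateau_fraction: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.tau_min > 0:
            raise ValueError("tau_min must be > 0")
        if not 0.0 < self.plateau_fraction <= 1.0:
            raise ValueError("plateau_fraction must be in (0, 1]")


@dataclass(frozen=True)
class StuckSpec:
    """Discrete sticking event: amplitude drops to ``residual_fraction`` at ``time``."""

    time: float
    residual_fraction: float


@dataclass(frozen=True)
class TpmSimConfig:
    """Everything needed to synthesize one tethered-bead trajectory."""

    model: TetherModel
    duration: float  # s
    sample_rate: float = 25.0  # Hz
    correlation_time: float = 0.1  # s, positional autocorrelation time
    drift: DriftSpec | None = None
    collapse: CollapseSpec | None = None
    stuck_event: StuckSpec | None = None
    anisotropy: tuple[float, float] = (1.0, 1.0)  # per-axis amplitude scales
    tracking_noise_nm: float = 0.0  # additive white position noise per axis
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.duration > 0 and self.sample_rate > 0):
            raise ValueError("duration and sample_rate must be > 0")
        if not self.correlation_time > 0:
            raise ValueError("correlation_time must be > 0")
        if min(self.anisotropy) < 0:
            raise ValueError("anisotropy scales must be >= 0")


def _rms_schedule(cfg: TpmSimConfig, t: np.ndarray) -> np.ndarray:
    r0 = rms_from_persistence(cfg.model)
    rms = np.full_like(t, r0)
    if cfg.collapse is not None:
        c = cfg.collapse
        r_inf = c.plateau_fraction * r0
        late = t >= c.start_time
        rms[late] = r_inf + (r0 - r_inf) * np.exp(
            -(t[late] - c.start_time) / (c.tau_min * 60.0)
        )
    return rms


def _ou_unit(n: int, a: float, rng: np.random.Generator) -> np.ndarray:
    # stationary AR(1) with unit variance: x[k] = a x[k-1] + sqrt(1-a^2) w[k]
    v = rng.standard_normal(n) * np.sqrt(1.0 - a * a)
    v[0] = rng.standard_normal()
    return lfilter([1.0], [1.0, -a], v)


def simulate_tpm(cfg: TpmSimConfig, bead_id: str = "sim") -> Trajectory:
    """Generate one TPM trajectory with the configured amplitude dynamics.

    The per-axis process is a unit-variance Ornstein-Uhlenbeck series
    scaled by the instantaneous target amplitude
    ``sigma_ax(t) = R_RMS(t)/sqrt(2)``, so the stationary in-plane RMS
    matches the bead-excursion relation exactly while the autocorrelation
    time stays ``correlation_time`` throughout the collapse.
    """
    n = int(round(cfg.duration * cfg.sample_rate))
    if n < 2:
        raise ValueError("duration too short for the sample rate")
    dt = 1.0 / cfg.sample_rate
    t = np.arange(n) * dt
    rng = np.random.default_rng(cfg.seed)
    a = np.exp(-dt / cfg.correlation_time)

    sigma = _rms_schedule(cfg, t) / np.sqrt(2.0)
    if cfg.stuck_event is not None:
        sigma = sigma.copy()
        sigma[t >= cfg.stuck_event.time] *= cfg.stuck_event.residual_fraction

    axes = []
    for scale in cfg.anisotropy:
        axes.append(scale * sigma * _ou_unit(n, a, rng))
    x, y = axes

    if cfg.drift is not None:
        amp = cfg.drift.amplitude / np.sqrt(2.0)  # split across the two axes
        if cfg.drift.kind == "linear":
            ramp = np.linspace(0.0, amp, n)
            x = x + ramp
            y = y + ramp
        else:
            step = amp / np.sqrt(n)
            x = x + np.cumsum(rng.standard_normal(n)) * step
            y = y + np.cumsum(rng.standard_normal(n)) * step

    if cfg.tracking_noise_nm > 0:
        x = x + rng.normal(0.0, cfg.tracking_noise_nm, n)
        y = y + rng.normal(0.0, cfg.tracking_noise_nm, n)

    return Trajectory(t=t, x=x, y=y, bead_id=bead_id)


@dataclass(frozen=True)
class FxSimConfig:
    """Forward model of a force-extension sweep (or a timed sequence).

    ``grid`` holds extensions as fractions of the current contour length
    (default 30 points on 0.1-0.85, the sub-full-extension pulling range);
    ``shrink_schedule`` maps acquisition times (s) to contour lengths (nm)
    and emits one sweep per entry, mimicking progressive compaction.
    """

    model: TetherModel
    grid: tuple[float, ...] = tuple(np.linspace(0.1, 0.85, 30))
    noise_sigma: float = 0.0  # pN
    shrink_schedule: tuple[tuple[float, float], ...] | None = None
    sweep: str = "down"  # "down" | "downup"
    seed: int = 0

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(g) <= 0) or g[0] <= 0 or g[-1] >= 1.0:
            raise ValueError("grid must be strictly increasing fractions in (0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.sweep not in ("down", "downup"):
            raise ValueError("sweep must be 'down' or 'downup'")
        if self.shrink_schedule is not None:
            for _, lc in self.shrink_schedule:
                if lc <= 0:
                    raise ValueError("scheduled contour lengths must be > 0")


def _one_sweep(
    cfg: FxSimConfig, lc: float, timestamp: float, rng: np.random.Generator
) -> ForceExtensionCurve:
    model = TetherModel(
        lc, cfg.model.persistence_length, cfg.model.thermal_energy,
        cfg.model.bead_radius,
    )
    frac = np.asarray(cfg.grid, dtype=float)
    if cfg.sweep == "downup":
        frac = np.concatenate([frac[::-1], frac])
        phase = np.array(["down"] * (len(frac) // 2) + ["up"] * (len(frac) // 2))
    else:
        phase = np.array(["down"] * len(frac))
    z = frac * lc
    f = wlc_force(z, model)
    if cfg.noise_sigma > 0:
        # additive detector noise; readings near zero tension may go negative
        f = f + rng.normal(0.0, cfg.noise_sigma, len(z))
    return ForceExtensionCurve(z=z, f=f, sweep_phase=phase, timestamp=timestamp)


def simulate_fx(cfg: FxSimConfig) -> ForceExtensionCurve | list[ForceExtensionCurve]:
    """Synthesize one sweep, or a timed sequence when a shrink schedule is set."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.shrink_schedule is None:
        return _one_sweep(cfg, cfg.model.contour_length, 0.0, rng)
    return [_one_sweep(cfg, lc, ts, rng) for ts, lc in cfg.shrink_schedule]


# ---------------------------------------------------------------- fixtures


def make_fixture_suite(
    out_dir: str | Path,
    seed: int = 0,
    duration: float = 1800.0,
    n_per_condition: int = 8,
) -> dict:
    """Write the canonical synthetic test-data suite with a ground-truth manifest.

    Conditions written (one trajectory CSV per bead): a no-protein control
    ensemble, 100 nM-like and 200 nM-like collapse ensembles (tau = 7.5
    and 7.3 min, plateaus 0.4 and 0.15), a bridging-incompetent-mutant
    ensemble (no collapse), an anisotropic multiple-tether case, a
    stuck-bead case, and a shrinking force-extension sweep sequence. The
    manifest (``manifest.json``) records every ground-truth parameter and
    file name; identical seeds give identical files.
    """
    out_dir = Path(out_dir)
    if str(out_dir) == "":
        raise ValueError("empty output directory path")
    out_dir.mkdir(parents=True, exist_ok=True)
    model = TetherModel(1731.3, 54.0, bead_radius=500.0)
    ss = np.random.SeedSequence(seed)
    sub = iter(ss.spawn(64))

    def next_seed() -> int:
        return int(next(sub).generate_state(1)[0] % (2**31))

    manifest: dict = {
        "seed": seed,
        "model": {
            "contour_length_nm": model.contour_length,
            "persistence_length_nm": model.persistence_length,
            "bead_radius_nm": model.bead_radius,
            "kbt_pn_nm": model.thermal_energy,
        },
        "duration_s": duration,
        "sample_rate_hz": 25.0,
        "conditions": {},
    }

    ensembles = {
        "control": dict(collapse=None, control=True),
        "collapse_100nM": dict(
            collapse=CollapseSpec(tau_min=7.5, plateau_fraction=0.4), control=False
        ),
        "collapse_200nM": dict(
            collapse=CollapseSpec(tau_min=7.3, plateau_fraction=0.15), control=False
        ),
        "mutant_no_collapse": dict(collapse=None, control=True),
    }
    for name, spec in ensembles.items():
        files = []
        for i in range(n_per_condition):
            cfg = TpmSimConfig(
                model=model, duration=duration, collapse=spec["collapse"],
                tracking_noise_nm=20.0, seed=next_seed(),
            )
            fname = f"{name}_{i:02d}.csv"
            write_trajectory(simulate_tpm(cfg, bead_id=f"{name}_{i:02d}"),
                             out_dir / fname)
            files.append(fname)
        collapse = spec["collapse"]
        manifest["conditions"][name] = {
            "files": files,
            "control": spec["control"],
            "tau_min": None if collapse is None else collapse.tau_min,
            "plateau_fraction": (
                None if collapse is None else collapse.plateau_fraction
            ),
        }

    screen_cases = {
        "anisotropic": dict(anisotropy=(1.2, 1.0)),
        "stuck_bead": dict(stuck_event=StuckSpec(time=duration / 3.0,
                                                 residual_fraction=0.2)),
    }
    for name, kw in screen_cases.items():
        cfg = TpmSimConfig(model=model, duration=min(duration, 600.0),
                           seed=next_seed(), **kw)
        fname = f"{name}.csv"
        write_trajectory(simulate_tpm(cfg, bead_id=name), out_dir / fname)
        manifest["conditions"][name] = {"files": [fname], **{
            k: (list(v) if isinstance(v, tuple) else
                {"time_s": v.time, "residual_fraction": v.residual_fraction})
            for k, v in kw.items()
        }}

    schedule = ((60.0, 1731.3), (120.0, 1386.0), (240.0, 1050.0))
    fx_cfg = FxSimConfig(model=model, noise_sigma=0.1,
                         shrink_schedule=schedule, seed=next_seed())
    from .forceext import write_force_extension

    fx_files = []
    for curve in simulate_fx(fx_cfg):
        fname = f"fx_t{int(curve.timestamp):04d}.csv"
        write_force_extension(curve, out_dir / fname)
        fx_files.append(fname)
    manifest["conditions"]["fx_shrinking"] = {
        "files": fx_files,
        "schedule": [list(pair) for pair in schedule],
        "persistence_length_nm": model.persistence_length,
        "noise_sigma_pn": fx_cfg.noise_sigma,
    }

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
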