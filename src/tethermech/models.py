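"""Closed-form polymer mechanics of a surface-tethered DNA molecule.

Two relations drive everything else in the package:

* the Gaussian-chain bead-excursion relation, which maps the contour length
  ``L_C``, persistence length ``xi`` and bead radius ``R`` of a tethered
  particle to the root-mean-square in-plane excursion of the bead center::

      R_RMS = sqrt( (L_C*xi/3) * (2 + 4*N_R / (sqrt(pi)*erf(N_R))) ),

  with the dimensionless excursion number ``N_R = R / sqrt(L_C*xi/3)``
  comparing the bead radius to the tether fluctuation scale;

* the Marko-Siggia worm-like-chain interpolation for the force needed to
  hold the molecule at end-to-end extension ``z``::

      f = (k_B*T/xi) * ( 1/(4*(1 - z/L_C)**2) - 1/4 + z/L_C ).

Units are nm, pN and seconds throughout; thermal energy defaults to
``k_B*T = 4.1 pN*nm`` (room temperature).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf

__all__ = [
    "TetherModel",
    "BasePairLength",
    "NoSolutionError",
    "contour_length_from_bp",
    "wlc_force",
    "wlc_extension",
    "rms_from_persistence",
    "persistence_from_rms",
]

KBT_ROOM = 4.1  # pN*nm


class NoSolutionError(ValueError):
    """Raised when a requested numeric inversion has no root in its bracket."""


@dataclass(frozen=True)
class TetherModel:
    """Geometry and energy scale of one DNA tether + reporter bead.

    Parameters
    ----------
    contour_length : float
        Fully stretched DNA length ``L_C`` in nm.
    persistence_length : float
        Bending persistence length ``xi`` in nm (bare B-DNA is ~50 nm).
    thermal_energy : float
        ``k_B*T`` in pN*nm. Defaults to 4.1 (room temperature); override
        for other temperatures.
    bead_radius : float
        Radius of the tethered microsphere in nm; 0 describes the bare
        polymer end point.
    """

    contour_length: float
    persistence_length: float
    thermal_energy: float = KBT_ROOM
    bead_radius: float = 0.0

    def __post_init__(self) -> None:
        if not self.contour_length > 0:
            raise ValueError(f"contour_length must be > 0, got {self.contour_length}")
        if not self.persistence_length > 0:
            raise ValueError(
                f"persistence_length must be > 0, got {self.persistence_length}"
            )
        if not self.thermal_energy > 0:
            raise ValueError(f"thermal_energy must be > 0, got {self.thermal_energy}")
        if self.bead_radius < 0:
            raise ValueError(f"bead_radius must be >= 0, got {self.bead_radius}")
        if not np.isfinite(self.excursion_number):
            raise ValueError("excursion number is not finite")

    @property
    def excursion_number(self) -> float:
        """Dimensionless bead-size parameter ``N_R = R / sqrt(L_C*xi/3)``."""
        return self.bead_radius / np.sqrt(
            self.contour_length * self.persistence_length / 3.0
        )

    def with_persistence(self, xi: float) -> "TetherModel":
        return replace(self, persistence_length=xi)


@dataclass(frozen=True)
class BasePairLength:
    """DNA length expressed in base pairs with a helical rise per bp."""

    n_bp: int
    rise_per_bp: float = 0.34  # nm/bp, canonical B-DNA

    def __post_init__(self) -> None:
        if not self.n_bp > 0:
            raise ValueError(f"n_bp must be > 0, got {self.n_bp}")
        if not self.rise_per_bp > 0:
            raise ValueError(f"rise_per_bp must be > 0, got {self.rise_per_bp}")


def contour_length_from_bp(bp: BasePairLength) -> float:
    """Contour length in nm of ``n_bp`` base pairs of B-form DNA."""
    return bp.n_bp * bp.rise_per_bp


def wlc_force(z, model: TetherModel):
    """Marko-Siggia worm-like-chain force at extension ``z``.

    Parameters
    ----------
    z : float or array
        End-to-end extension in nm; must satisfy ``0 <= z < L_C``.
    model : TetherModel
        Supplies ``xi``, ``L_C`` and ``k_B*T``.

    Returns
    -------
    float or ndarray
        Restoring force in pN. Strictly increasing in ``z`` and divergent
        as ``z -> L_C``.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("extension must be >= 0")
    if np.any(z >= model.contour_length):
        raise ValueError("extension must be below the contour length")
    x = z / model.contour_length
    f = (model.thermal_energy / model.persistence_length) * (
        0.25 / (1.0 - x) ** 2 - 0.25 + x
    )
    return float(f) if f.ndim == 0 else f


def wlc_extension(f: float, model: TetherModel, tol: float = 1e-6) -> float:
    """Numerically invert the worm-like chain: extension at force ``f``.

    Bisects the strictly monotone force law on ``[0, L_C)``; ``tol`` is the
    absolute tolerance on the returned extension in nm.
    """
    if f < 0:
        raise ValueError("force must be >= 0")
    if f == 0:
        return 0.0
    lc = model.contour_length
    hi = lc * (1.0 - 1e-12)  # force there is astronomically larger than any input
    z = brentq(lambda zz: wlc_force(zz, model) - f, 0.0, hi, xtol=tol * 1e-3)
    return float(z)


def _excursion_bracket(n_r: float) -> float:
    # 2 + 4*N/(sqrt(pi)*erf(N)); the N -> 0 limit of the second term is 2
    if n_r == 0.0:
        return 4.0
    return 2.0 + 4.0 * n_r / (np.sqrt(np.pi) * erf(n_r))


def rms_from_persistence(model: TetherModel) -> float:
    """RMS in-plane bead excursion predicted by the Gaussian-chain relation.

    Returns ``R_RMS`` in nm for the tether's ``(L_C, xi, R)``. The
    zero-bead-radius case uses the analytic limit of the excursion-number
    term (the bracket tends to 4, i.e. two in-plane axes of variance
    ``2*L_C*xi/3`` each).
    """
    s2 = model.contour_length * model.persistence_length / 3.0
    return float(np.sqrt(s2 * _excursion_bracket(model.excursion_number)))


def persistence_from_rms(
    r_rms: float,
    contour_length: float,
    bead_radius: float,
    xi_bounds: tuple[float, float] = (0.1, 1000.0),
    tol: float = 1e-4,
) -> float:
    """Invert the bead-excursion relation: persistence length from measured RMS.

    The map ``xi -> R_RMS`` is strictly increasing, so the unique root is
    found by bracketed bisection on ``xi_bounds`` (nm) to absolute
    tolerance ``tol`` nm.

    Raises
    ------
    NoSolutionError
        If ``r_rms`` lies outside the RMS range reachable within
        ``xi_bounds``; the message carries the reachable bounds as a
        diagnostic.
    """
    if not r_rms > 0:
        raise ValueError(f"r_rms must be > 0, got {r_rms}")

    def residual(xi: float) -> float:
        m = TetherModel(contour_length, xi, bead_radius=bead_radius)
        return rms_from_persistence(m) - r_rms

    lo, hi = xi_bounds
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo > 0 or r_hi < 0:
        rms_lo, rms_hi = r_lo + r_rms, r_hi + r_rms
        raise NoSolutionError(
            f"r_rms={r_rms:.6g} nm unreachable: xi in [{lo}, {hi}] nm spans "
            f"RMS [{rms_lo:.6g}, {rms_hi:.6g}] nm for L_C={contour_length} nm, "
            f"R={bead_radius} nm"
        )
    return float(brentq(residual, lo, hi, xtol=tol))
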