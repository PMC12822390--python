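"""Biphasic cell/ECM composition model and Brillouin mixture decomposition.

A spheroid is treated as a two-compartment material: cells, containing
water and dry mass in a fixed ratio (defaults 70% / 30% by volume), and
extracellular matrix (ECM), predominantly aqueous.  With volume fractions
Phi_cell + Phi_ECM = 1, the Raman OH band area is proportional to the total
water volume and the CH band area to the total dry-mass volume, linked by a
single scattering-efficiency constant kappa:

    R = A_CH / A_OH = kappa * d_cell * Phi_cell / (w_cell * Phi_cell + w_ecm * Phi_ECM)

which inverts in closed form to give Phi_ECM from a measured ratio.  kappa
is calibrated on a sample of known composition (typically a compressed
spheroid, whose interstitial spaces are negligible, Phi_ECM ~ 0), never
assumed.

Because the two components' Brillouin peaks sit much closer than their
linewidth, the measured spectrum shows a single merged peak whose position
is, to first order, the volume-fraction-weighted mixture

    omega_B = omega_ECM * Phi_ECM + omega_cell * Phi_cell

This linear mixing rule is applied forward (predict the composite shift)
and inverse (recover omega_ECM or omega_cell from the composite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import CalibrationError, IllConditionedError, ModelViolationError

__all__ = [
    "CompositionModel",
    "CompositionEstimate",
    "MixtureDecomposition",
    "calibrate_kappa",
    "estimate_phi",
    "forward_omega",
    "invert_omega_ecm",
    "invert_omega_cell",
]

#: Below this ECM fraction the compressed limit applies and mixture
#: inversion for omega_ECM is ill-conditioned.
DEFAULT_PHI_MIN = 0.02

#: Noise-driven slightly negative fractions are clamped to 0; anything
#: beyond this band violates the biphasic assumptions.
CLAMP_BAND = 0.05


@dataclass
class CompositionModel:
    """Fixed compartment parameters of the biphasic water model.

    w_cell: water volume fraction of cells (default 0.70); the dry-mass
    fraction is its exact complement.  w_ecm: ECM water fraction (default
    1.0, negligible dry mass).  kappa: CH-vs-OH scattering-efficiency
    calibration constant (dimensionless; set by :func:`calibrate_kappa`).
    """

    w_cell: float = 0.70
    w_ecm: float = 1.0
    kappa: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.w_cell < 1.0:
            raise ValueError("w_cell must be in (0, 1)")
        if not 0.0 < self.w_ecm <= 1.0:
            raise ValueError("w_ecm must be in (0, 1]")
        if self.kappa is not None and self.kappa <= 0:
            raise ValueError("kappa must be positive")

    @property
    def d_cell(self) -> float:
        """Dry-mass volume fraction of cells, exactly 1 - w_cell."""
        return 1.0 - self.w_cell

    def expected_ratio(self, phi_ecm: float) -> float:
        """Closed-form CH/OH ratio at a given ECM fraction (kappa required)."""
        if self.kappa is None:
            raise CalibrationError("kappa not calibrated")
        phi_cell = 1.0 - phi_ecm
        return self.kappa * self.d_cell * phi_cell / (self.w_cell * phi_cell + self.w_ecm * phi_ecm)


@dataclass
class CompositionEstimate:
    """ECM / cell volume fractions inferred from a CH/OH ratio."""

    phi_ecm: float
    se_phi: float = 0.0
    clamped: bool = False

    @property
    def phi_cell(self) -> float:
        """Exact complement of phi_ecm (conservation)."""
        return 1.0 - self.phi_ecm


@dataclass
class MixtureDecomposition:
    """Composite Brillouin shift and its two component shifts (GHz)."""

    omega_b: float
    omega_cell: float
    omega_ecm: float
    phi_ecm: float = field(default=0.0)

    def __post_init__(self) -> None:
        lo = min(self.omega_cell, self.omega_ecm) - 1e-9
        hi = max(self.omega_cell, self.omega_ecm) + 1e-9
        if 0.0 <= self.phi_ecm <= 1.0 and not (lo <= self.omega_b <= hi):
            warnings.warn(
                f"omega_b={self.omega_b:.3f} GHz outside [{lo:.3f}, {hi:.3f}] bracket",
                RuntimeWarning,
            )


def calibrate_kappa(r_ref: float, phi_ecm_ref: float, model: CompositionModel) -> float:
    """Solve for kappa from a reference ratio at known composition.

    kappa = r_ref * (w_cell*(1-Phi) + w_ecm*Phi) / (d_cell*(1-Phi)); at
    Phi = 0 (compressed spheroid) this reduces to r_ref * w_cell / d_cell.
    """
    if r_ref <= 0:
        raise CalibrationError("reference ratio must be positive")
    if phi_ecm_ref >= 1.0:
        raise CalibrationError("phi_ecm_ref = 1 has no CH signal; kappa undefined")
    phi_cell = 1.0 - phi_ecm_ref
    return r_ref * (model.w_cell * phi_cell + model.w_ecm * phi_ecm_ref) / (model.d_cell * phi_cell)


def estimate_phi(
    r: float, model: CompositionModel, r_se: float | None = None
) -> CompositionEstimate:
    """Invert the closed-form ratio relation for the ECM volume fraction.

    Phi_ECM = (kappa*d_cell - r*w_cell) / (kappa*d_cell - r*w_cell + r*w_ecm);
    for w_ecm = 1 this is the familiar (kappa*d - r*w) / (d*(r + kappa)).
    Values in [-0.05, 0) are clamped to 0 with a warning (noise); results
    outside [-0.05, 1.05] are model violations.
    """
    if model.kappa is None:
        raise CalibrationError("kappa not calibrated; run calibrate_kappa first")
    if r < 0:
        raise ModelViolationError("ratio must be non-negative")
    kd = model.kappa * model.d_cell
    num = kd - r * model.w_cell
    den = num + r * model.w_ecm
    if den == 0:
        raise ModelViolationError("degenerate ratio: denominator vanishes")
    phi = num / den
    clamped = False
    if phi < -CLAMP_BAND or phi > 1.0 + CLAMP_BAND:
        raise ModelViolationError(
            f"phi_ecm={phi:.3f} outside [-{CLAMP_BAND}, 1+{CLAMP_BAND}]: "
            "composition incompatible with the biphasic assumptions"
        )
    if phi < 0.0:
        warnings.warn(f"phi_ecm={phi:.4f} clamped to 0 (noise)", RuntimeWarning)
        phi, clamped = 0.0, True
    elif phi > 1.0:
        warnings.warn(f"phi_ecm={phi:.4f} clamped to 1 (noise)", RuntimeWarning)
        phi, clamped = 1.0, True
    se = 0.0
    if r_se is not None:
        # first-order propagation: dPhi/dR
        dnum = -model.w_cell
        dden = -model.w_cell + model.w_ecm
        dphi = (dnum * den - num * dden) / den**2
        se = abs(dphi) * r_se
    return CompositionEstimate(phi_ecm=float(phi), se_phi=float(se), clamped=clamped)


def forward_omega(omega_cell: float, omega_ecm: float, phi_ecm: float) -> float:
    """Linear mixture: omega_B = omega_ECM*Phi_ECM + omega_cell*(1 - Phi_ECM)."""
    if not 0.0 <= phi_ecm <= 1.0:
        raise ModelViolationError(f"phi_ecm={phi_ecm} outside [0, 1]")
    return omega_ecm * phi_ecm + omega_cell * (1.0 - phi_ecm)


def invert_omega_ecm(
    omega_b: float,
    omega_cell: float,
    phi_ecm: float,
    phi_min: float = DEFAULT_PHI_MIN,
    se_omega_b: float = 0.0,
    se_omega_cell: float = 0.0,
) -> tuple[float, float]:
    """Recover the ECM component shift from the composite and the cell shift.

    omega_ECM = (omega_B - (1 - Phi_ECM)*omega_cell) / Phi_ECM.  Returns
    ``(omega_ecm, se)`` with first-order uncertainty propagation from the
    two shifts when their standard errors are given.
    """
    if phi_ecm < phi_min:
        raise IllConditionedError(
            f"phi_ecm={phi_ecm:.4f} < phi_min={phi_min}: inversion divides by a vanishing fraction"
        )
    omega_ecm = (omega_b - (1.0 - phi_ecm) * omega_cell) / phi_ecm
    se = np.hypot(se_omega_b / phi_ecm, se_omega_cell * (1.0 - phi_ecm) / phi_ecm)
    return float(omega_ecm), float(se)


def invert_omega_cell(
    omega_b: float,
    omega_ecm: float,
    phi_ecm: float,
    phi_min: float = DEFAULT_PHI_MIN,
) -> float:
    """Recover the cell component shift: (omega_B - Phi_ECM*omega_ECM)/(1 - Phi_ECM)."""
    if phi_ecm > 1.0 - phi_min:
        raise IllConditionedError(
            f"phi_ecm={phi_ecm:.4f} > 1 - phi_min: inversion divides by a vanishing cell fraction"
        )
    return (omega_b - phi_ecm * omega_ecm) / (1.0 - phi_ecm)
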