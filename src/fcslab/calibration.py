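"""Reference-dye calibration: from fit parameters to D and concentration.

A dye of known diffusion coefficient D_ref measured on the same instrument
fixes the lateral waist via omega_xy = sqrt(4 D_ref tau_D_ref) and hence
the effective volume V_eff = pi^(3/2) omega_xy^2 (kappa omega_xy).  Each
color channel is calibrated with its own dye because chromatic focal-volume
mismatch is real on two-color instruments.  With a calibration in hand,

    D = omega_xy^2 / (4 tau_D)        and        c = N / (N_A V_eff).

Reference D values are user-supplied: dye literature values are typically
quoted at room temperature while live-cell work runs at 37 C, and any
temperature correction is the caller's explicit choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .fitting import DiffusionFit
from .synthetic import NM_PER_UM3

__all__ = ["Calibration", "calibrate", "to_diffusion", "to_concentration"]


@dataclass(frozen=True)
class Calibration:
    omega_xy: float           # um
    kappa: float
    v_eff: float              # fL (= um^3)
    D_ref: float              # um^2/s
    tau_D_ref: float          # s
    dye_name: str = ""

    def __post_init__(self):
        if self.omega_xy <= 0 or self.kappa < 1 or self.v_eff <= 0:
            raise ValueError("invalid calibration geometry")


def _volume(omega_xy: float, kappa: float) -> float:
    return math.pi ** 1.5 * omega_xy**2 * (kappa * omega_xy)


def calibrate(dye_fit: DiffusionFit, D_ref: float, kappa: float,
              dye_name: str = "") -> Calibration:
    """Derive the observation-volume geometry from a converged dye fit."""
    if not dye_fit.converged:
        raise ValueError("dye fit did not converge; cannot calibrate")
    if D_ref <= 0:
        raise ValueError("D_ref must be positive")
    omega_xy = math.sqrt(4.0 * D_ref * dye_fit.tau_D)
    return Calibration(omega_xy=omega_xy, kappa=kappa,
                       v_eff=_volume(omega_xy, kappa),
                       D_ref=D_ref, tau_D_ref=dye_fit.tau_D,
                       dye_name=dye_name)


def from_geometry(omega_xy: float, kappa: float, D_ref: float = float("nan"),
                  dye_name: str = "") -> Calibration:
    """Calibration object from known waist and structure parameter.

    Convenience for simulations where the instrument geometry is exact and
    no dye measurement is wanted; tau_D_ref follows from D_ref when given.
    """
    tau_ref = omega_xy**2 / (4.0 * D_ref) if D_ref and D_ref > 0 else float("nan")
    return Calibration(omega_xy=omega_xy, kappa=kappa,
                       v_eff=_volume(omega_xy, kappa),
                       D_ref=D_ref, tau_D_ref=tau_ref, dye_name=dye_name)


def to_diffusion(fit: DiffusionFit, calib: Calibration) -> float:
    """Diffusion coefficient (um^2/s) from a converged fit: omega_xy^2 / (4 tau_D)."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    return calib.omega_xy**2 / (4.0 * fit.tau_D)


def to_concentration(N_corrected: float, calib: Calibration) -> float:
    """Molar concentration (nM) from a corrected occupancy: c = N / (N_A V_eff)."""
    if N_corrected < 0:
        raise ValueError("N_corrected must be >= 0")
    return N_corrected / (NM_PER_UM3 * calib.v_eff)
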