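"""Self-consistency procedures used to assemble the recommended data set.

Transmission-measured total cross sections (TCS) systematically
undercount scattering because electrons scattered into the detector's
forward acceptance cone — the "missing angles" — are registered as
unscattered.  This module implements the corrections applied when
compiling the recommended set:

* the acceptance angle itself, either a fixed geometric aperture
  (a linear-beam spectrometer) or linked to the energy resolution of a
  magnetically confined apparatus, where a scattering event only
  registers once the axial-energy decrement exceeds the resolution;
* the missing-angle cross-section deficit, the integral of a channel's
  differential cross section over the acceptance cone;
* the closure rules that derive the vibrational-excitation channel as
  the remainder of the reference TCS, and split the total inelastic
  cross section into ionization and electronic excitation with a given
  ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

from scipy import integrate

__all__ = [
    "AcceptanceModel",
    "CorrectionResult",
    "acceptance_angle",
    "missing_angle_correction",
    "close_vibrational",
    "split_inelastic",
]

logger = logging.getLogger(__name__)

FULL_ACCEPTANCE = math.pi / 2.0


@dataclass(frozen=True)
class AcceptanceModel:
    """Detector angular acceptance.

    ``fixed_angle``: a geometric aperture ``theta_fixed`` (radians),
    e.g. ~5 degrees for a linear transmission beam.

    ``energy_resolution_linked``: in a magnetically confined apparatus
    the transverse energy of a scattered electron is conserved, so a
    scattering event is only resolved once its axial-energy decrement
    exceeds the energy resolution ``delta_E_res``; the acceptance angle
    grows as the resolution worsens relative to the beam energy.
    """

    kind: str = "fixed_angle"
    theta_fixed: float = math.radians(5.0)
    delta_E_res: float = 0.45  # eV

    def __post_init__(self) -> None:
        if self.kind not in ("fixed_angle", "energy_resolution_linked"):
            raise ValueError(f"unknown acceptance kind {self.kind!r}")
        if not 0.0 < self.theta_fixed <= math.pi / 2:
            raise ValueError("theta_fixed must be in (0, pi/2]")
        if self.delta_E_res <= 0:
            raise ValueError("delta_E_res must be > 0")


@dataclass(frozen=True)
class CorrectionResult:
    """A missing-angle-corrected TCS point."""

    energy: float  # eV
    delta_sigma_elastic: float  # 1e-20 m^2
    delta_sigma_rotational: float  # 1e-20 m^2
    corrected_tcs: float  # 1e-20 m^2


def acceptance_angle(model: AcceptanceModel, energy: float) -> float:
    """Acceptance half-angle (radians) at incident ``energy`` (eV).

    For the resolution-linked kind this is the pitch angle whose
    axial-energy decrement equals the resolution:
    ``theta = arccos(sqrt(1 - dE_res/E))``.  At energies at or below the
    resolution every scattering angle is unresolved and the
    full-acceptance sentinel pi/2 is returned.
    """
    if model.kind == "fixed_angle":
        return model.theta_fixed
    if energy <= model.delta_E_res:
        return FULL_ACCEPTANCE
    return math.acos(math.sqrt(1.0 - model.delta_E_res / energy))


def missing_angle_correction(
    dcs: Callable[[float], float],
    energy: float,
    theta_acc: float,
    rtol: float = 1e-8,
) -> float:
    """Cross section scattered into the acceptance cone, 1e-20 m^2.

    Evaluates ``2*pi * int_0^theta_acc dcs(theta) sin(theta) dtheta`` by
    adaptive quadrature.  ``dcs`` must be the channel's differential
    cross section at ``energy`` (1e-20 m^2/sr), normalized so that its
    full-sphere integral equals the channel's integral cross section.
    Forward-peaked integrands are handled by splitting the domain at
    ``theta_acc/10``.
    """
    if theta_acc < 0 or theta_acc > math.pi:
        raise ValueError("theta_acc must be in [0, pi]")
    if theta_acc == 0.0:
        return 0.0

    def integrand(theta: float) -> float:
        value = dcs(theta)
        if not math.isfinite(value):
            raise ValueError(f"non-finite DCS at theta={theta}")
        return value * math.sin(theta)

    split = theta_acc / 10.0
    part1, _ = integrate.quad(integrand, 0.0, split, epsrel=rtol, epsabs=0, limit=200)
    part2, _ = integrate.quad(
        integrand, split, theta_acc, epsrel=rtol, epsabs=0, limit=200
    )
    return 2.0 * math.pi * (part1 + part2)


def close_vibrational(
    tcs_ref: float,
    elastic: float,
    electronic: float,
    ionization: float,
    attachment: float,
) -> float:
    """Vibrational cross section as the closure remainder of the TCS.

    The reference TCS (rotational excitation excluded, by the convention
    of the corrected transmission measurements) minus the elastic,
    electronic-excitation, ionization and attachment channels is
    attributed to vibrational excitation.  A negative remainder signals
    an inconsistent input set; it is clipped to zero and logged rather
    than propagated.
    """
    parts = dict(
        tcs_ref=tcs_ref,
        elastic=elastic,
        electronic=electronic,
        ionization=ionization,
        attachment=attachment,
    )
    for name, value in parts.items():
        if value < 0:
            raise ValueError(f"{name} must be >= 0, got {value}")
    remainder = tcs_ref - (elastic + electronic + ionization + attachment)
    if remainder < 0:
        logger.warning(
            "closure remainder negative (%.4g): channel sum exceeds reference TCS; "
            "clipping vibrational cross section to 0",
            remainder,
        )
        return 0.0
    return remainder


def split_inelastic(
    total_inelastic: float, ratio_ion_over_elec: float
) -> tuple[float, float]:
    """Split a total inelastic cross section into (ionization, electronic).

    The split uses the ionization/electronic-excitation ratio (from the
    IAM-SCAR calculation at each energy, supplied by the caller):
    ``electronic = total/(1+r)``, ``ionization = total*r/(1+r)``.
    The parts sum to the input exactly.
    """
    if total_inelastic < 0 or ratio_ion_over_elec < 0:
        raise ValueError("inputs must be >= 0")
    electronic = total_inelastic / (1.0 + ratio_ion_over_elec)
    ionization = total_inelastic - electronic
    return ionization, electronic
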