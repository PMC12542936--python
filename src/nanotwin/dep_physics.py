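"""Dielectrophoretic trapping physics around a nanoelectrode tip.

The tip's electric field is represented by a one-parameter analytic power
law rather than a finite-element solution: the gradient of the squared RMS
field decays as ``(distance + tip_radius)**-7`` (point-dipole tip) and is
scaled so that a chosen reference particle at contact under a reference
drive feels a chosen calibration force.  This preserves the reported
scalings — force proportional to voltage squared, rapid decay away from the
apex, nanonewton-range contact force, micrometre-scale trapping region —
without solving any field equation.

Conventions used throughout:

* ``distance`` is measured from the tip apex to the particle *centre*
  along the tip axis; contact is ``distance == body.radius``.
* Drive voltages are peak-to-peak; the RMS conversion
  ``V_rms = V_pp / (2*sqrt(2))`` is internal to the field model and the
  calibration, so it never leaks into the public API.
* Signed forces are along the tip axis with negative meaning "toward the
  tip" (attraction).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .constants import EPS0, KB

__all__ = [
    "Medium",
    "Shell",
    "DielectricBody",
    "DepDrive",
    "TipFieldModel",
    "complex_permittivity",
    "clausius_mossotti",
    "grad_E2",
    "dep_force",
    "dep_potential",
    "calibrate_tip",
    "trapping_radius",
    "default_medium",
    "default_mitochondrion",
    "default_ps_bead",
    "default_drive",
    "default_tip",
]


class CalibrationError(RuntimeError):
    """Raised when a tip model cannot be (or has not been) calibrated."""


@dataclass(frozen=True)
class Medium:
    """Suspending medium: dielectric, conductive and viscous properties."""

    rel_permittivity: float = 80.0
    conductivity: float = 0.03       # S/m
    viscosity: float = 1.0e-3        # Pa s
    temperature: float = 298.15      # K

    def __post_init__(self) -> None:
        if self.rel_permittivity < 1:
            raise ValueError("rel_permittivity must be >= 1")
        if self.conductivity < 0:
            raise ValueError("conductivity must be >= 0")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass(frozen=True)
class Shell:
    """Thin outer shell (membrane) of a shelled dielectric sphere."""

    thickness: float                 # m
    rel_permittivity: float
    conductivity: float              # S/m


@dataclass(frozen=True)
class DielectricBody:
    """Homogeneous or single-shelled polarizable sphere."""

    radius: float                    # m
    rel_permittivity: float
    conductivity: float              # S/m
    shell: Optional[Shell] = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.shell is not None and not (0 < self.shell.thickness < self.radius):
            raise ValueError("shell thickness must be in (0, radius)")


@dataclass(frozen=True)
class DepDrive:
    """AC drive applied between the two tip electrodes."""

    voltage_pp: float = 7.0          # V, peak-to-peak
    frequency: float = 1.0e6         # Hz
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.voltage_pp < 0:
            raise ValueError("voltage_pp must be >= 0")
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")

    @property
    def v_rms(self) -> float:
        return self.voltage_pp / (2.0 * math.sqrt(2.0))


@dataclass(frozen=True)
class TipFieldModel:
    """Analytic tip-field surrogate, calibrated by a reference force.

    ``g0`` is the field-gradient prefactor solved for by :func:`calibrate_tip`
    so that the reference body at contact under the reference drive feels
    exactly ``force_calibration``.
    """

    tip_radius: float = 5.0e-8       # m, effective apex rounding
    gap: float = 1.0e-7              # m, electrode separation (descriptive)
    force_calibration: float = 1.0e-9  # N on reference body at contact
    reference_drive: DepDrive = field(default_factory=DepDrive)
    reference_body: "DielectricBody" = None  # type: ignore[assignment]
    g0: Optional[float] = None       # V^2/m^3 per V_pp^2, set by calibration

    def __post_init__(self) -> None:
        if self.tip_radius <= 0:
            raise ValueError("tip_radius must be > 0")
        if self.gap <= 0:
            raise ValueError("gap must be > 0")
        if self.force_calibration <= 0:
            raise ValueError("force_calibration must be > 0")
        if self.reference_body is None:
            object.__setattr__(self, "reference_body", default_mitochondrion())

    @property
    def calibrated(self) -> bool:
        return self.g0 is not None


def complex_permittivity(obj, frequency: float) -> complex:
    """Relative complex permittivity ``eps_r - j*sigma/(2*pi*f*eps0)``."""
    if frequency <= 0:
        raise ValueError("frequency must be > 0")
    return obj.rel_permittivity - 1j * obj.conductivity / (2.0 * math.pi * frequency * EPS0)


def _effective_shelled_permittivity(body: DielectricBody, frequency: float) -> complex:
    """Single-shell effective complex permittivity of a shelled sphere.

    Standard smeared-out sphere: with outer radius a, inner radius a - t,
    gamma = (a / (a - t))**3 and K the core/shell contrast factor,

        eps_eff = eps_shell * (gamma + 2 K) / (gamma - K)

    Converges to the core permittivity as t -> 0 and to the shell's when
    core and shell match.
    """
    shell = body.shell
    assert shell is not None
    eps_core = complex_permittivity(body, frequency)
    eps_shell = complex_permittivity(shell, frequency)
    gamma = (body.radius / (body.radius - shell.thickness)) ** 3
    k_cs = (eps_core - eps_shell) / (eps_core + 2.0 * eps_shell)
    return eps_shell * (gamma + 2.0 * k_cs) / (gamma - k_cs)


def clausius_mossotti(body: DielectricBody, medium: Medium, frequency: float) -> complex:
    """Complex Clausius-Mossotti factor ``(eps_p* - eps_m*)/(eps_p* + 2 eps_m*)``.

    For shelled bodies the particle permittivity is first replaced by the
    single-shell effective permittivity.  The real part lies in [-0.5, 1].
    """
    if body.shell is not None:
        eps_p = _effective_shelled_permittivity(body, frequency)
    else:
        eps_p = complex_permittivity(body, frequency)
    eps_m = complex_permittivity(medium, frequency)
    denom = eps_p + 2.0 * eps_m
    if denom == 0:
        raise ZeroDivisionError("degenerate Clausius-Mossotti denominator")
    return (eps_p - eps_m) / denom


def grad_E2(tip: TipFieldModel, drive: DepDrive, distance) -> np.ndarray | float:
    """Magnitude of the gradient of the squared RMS field, V^2/m^3.

    ``g0 * voltage_pp**2 / (distance + tip_radius)**7``, directed toward
    the apex.  ``distance`` may be a scalar or array (>= 0, apex to
    particle centre).
    """
    if not tip.calibrated:
        raise CalibrationError("tip model is not calibrated; call calibrate_tip first")
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    out = tip.g0 * drive.voltage_pp**2 / (d + tip.tip_radius) ** 7
    return out if out.ndim else float(out)


def _force_prefactor(body: DielectricBody, medium: Medium, frequency: float) -> float:
    """2*pi*eps0*eps_m*a^3*Re[K] — point-dipole DEP force prefactor."""
    re_k = clausius_mossotti(body, medium, frequency).real
    return 2.0 * math.pi * EPS0 * medium.rel_permittivity * body.radius**3 * re_k


def dep_force(body: DielectricBody, medium: Medium, tip: TipFieldModel,
              drive: DepDrive, distance) -> np.ndarray | float:
    """Signed axial DEP force in newtons; negative = toward the tip.

    Point-dipole law ``F = 2*pi*eps0*eps_m*a^3*Re[K]*grad|E_rms|^2``.
    A disabled drive yields zero force.
    """
    if not drive.enabled:
        warnings.warn("drive disabled: DEP force is zero", stacklevel=2)
        d = np.asarray(distance, dtype=float)
        z = np.zeros_like(d)
        return z if z.ndim else 0.0
    pref = _force_prefactor(body, medium, drive.frequency)
    # gradient points toward the apex, so positive Re[K] gives a negative
    # (attractive) signed force
    return -pref * grad_E2(tip, drive, distance)


def dep_potential(body: DielectricBody, medium: Medium, tip: TipFieldModel,
                  drive: DepDrive, distance) -> np.ndarray | float:
    """DEP interaction energy ``U = -pi*eps0*eps_m*a^3*Re[K]*|E_rms|^2`` in J.

    ``|E_rms|^2`` is the integral of :func:`grad_E2` so that
    ``force == -dU/ddistance`` holds identically:
    ``|E_rms|^2 = g0*V_pp^2 / (3*(distance + tip_radius)**6)``.
    """
    if not tip.calibrated:
        raise CalibrationError("tip model is not calibrated; call calibrate_tip first")
    if not drive.enabled:
        d = np.asarray(distance, dtype=float)
        z = np.zeros_like(d)
        return z if z.ndim else 0.0
    d = np.asarray(distance, dtype=float)
    e2 = tip.g0 * drive.voltage_pp**2 / (3.0 * (d + tip.tip_radius) ** 6)
    pref = _force_prefactor(body, medium, drive.frequency)
    out = -0.5 * pref * e2
    return out if out.ndim else float(out)


def calibrate_tip(tip: TipFieldModel, medium: Optional[Medium] = None) -> TipFieldModel:
    """Return a calibrated copy of ``tip`` with ``g0`` solved.

    ``g0`` is fixed so that the reference body at contact
    (``distance == reference_body.radius``) under the reference drive feels
    exactly ``force_calibration``.  Requires positive DEP (Re[K] > 0) for
    the reference configuration.
    """
    medium = medium if medium is not None else default_medium()
    body = tip.reference_body
    drive = tip.reference_drive
    pref = _force_prefactor(body, medium, drive.frequency)
    if pref <= 0:
        raise CalibrationError(
            "reference configuration is not attractive (Re[K] <= 0); cannot calibrate")
    contact = body.radius
    g0 = tip.force_calibration * (contact + tip.tip_radius) ** 7 / (pref * drive.voltage_pp**2)
    return replace(tip, g0=g0)


def trapping_radius(body: DielectricBody, medium: Medium, tip: TipFieldModel,
                    drive: DepDrive, threshold_kT: float = 1.0) -> float:
    """Distance where the trap depth equals ``threshold_kT * kB * T``.

    Solves ``|U(s)| = threshold_kT * kB * T`` in closed form from the
    ``(s + r0)**-6`` potential.  Returns 0.0 when the interaction is
    repulsive or too weak to reach the threshold anywhere.
    """
    if not tip.calibrated:
        raise CalibrationError("tip model is not calibrated; call calibrate_tip first")
    pref = _force_prefactor(body, medium, drive.frequency)
    if pref <= 0 or not drive.enabled:
        return 0.0
    u_target = threshold_kT * KB * medium.temperature
    # |U| = pref * g0 * Vpp^2 / (6 * (s+r0)^6)
    c = pref * tip.g0 * drive.voltage_pp**2 / 6.0
    s = (c / u_target) ** (1.0 / 6.0) - tip.tip_radius
    return max(s, 0.0)


# ---------------------------------------------------------------------------
# Paper-regime defaults (all overridable via config)

def default_medium() -> Medium:
    """Trapping medium: eps_r 80, 0.03 S/m, water viscosity at 298.15 K."""
    return Medium(rel_permittivity=80.0, conductivity=0.03,
                  viscosity=1.0e-3, temperature=298.15)


def default_mitochondrion() -> DielectricBody:
    """Single-shell organelle: 0.5 um radius, thin low-conductivity membrane.

    The lumped membrane (double membrane folded into one 5 nm shell of
    eps_r 12) and conductive matrix (0.8 S/m) put the Maxwell-Wagner
    crossover below 1 MHz, so the organelle shows positive DEP at the
    1 MHz drive in a 0.03 S/m medium.
    """
    return DielectricBody(
        radius=0.5e-6, rel_permittivity=60.0, conductivity=0.8,
        shell=Shell(thickness=5.0e-9, rel_permittivity=12.0, conductivity=1.0e-6),
    )


def default_ps_bead() -> DielectricBody:
    """0.3-um-diameter polystyrene bead.

    The bulk dielectric constant is 2.5; submicron beads in low-conductivity
    water additionally carry a surface conductance that makes their
    effective conductivity ~2*Ks/a (Ks ~ 1 nS), which is what gives them
    positive DEP at 1 MHz.
    """
    return DielectricBody(radius=0.15e-6, rel_permittivity=2.5, conductivity=0.013)


def default_bead_medium() -> Medium:
    """Low-conductivity water used for bead trapping runs."""
    return Medium(rel_permittivity=80.0, conductivity=1.0e-4,
                  viscosity=1.0e-3, temperature=298.15)


def default_drive() -> DepDrive:
    return DepDrive(voltage_pp=7.0, frequency=1.0e6, enabled=True)


def default_tip(body: Optional[DielectricBody] = None,
                medium: Optional[Medium] = None) -> TipFieldModel:
    """Calibrated default tip: 1 nN on the default mitochondrion at contact."""
    tip = TipFieldModel(reference_body=body or default_mitochondrion(),
                        reference_drive=default_drive())
    return calibrate_tip(tip, medium or default_medium())
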