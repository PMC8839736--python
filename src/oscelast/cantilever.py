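"""Driven-cantilever dynamics and the lock-in amplitude → stiffness conversion.

With interferometric (displacement, not slope) detection the cantilever is a
point mass m* on a spring kc with drag γc; a tethered molecule adds a parallel
Voigt element (ki, γi) so the effective stiffness is k = kc + ki.  Base
dithering at amplitude A0 drives

    m* z̈ + γ ż + k z = A0 kc cos(ωt),

whose steady state has amplitude A = A0·kc/√((k − m*ω²)² + (γω)²) and phase
lag δ = atan2(γω, k − m*ω²).  Far below resonance and for ki ≪ kc this
reduces to the working relation of off-resonance stiffness spectroscopy,

    A ≈ A0 (1 − ki/kc),   δ ≈ 0,

which is inverted per point as ki = kc(1 − R/A0) to turn a lock-in amplitude
trace into a stiffness–extension curve.  A near-zero, featureless phase trace
is the experimental self-check that dissipation is negligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .env import EnvParams, ROOM

__all__ = [
    "CantileverParams",
    "OscillatoryCurve",
    "StiffnessCurve",
    "sho_steady_state",
    "amplitude_to_stiffness",
    "phase_validity_check",
    "DegenerateCurveWarning",
]


class DegenerateCurveWarning(UserWarning):
    """Raised-as-warning signal: every point of a converted curve was clipped."""


@dataclass(frozen=True)
class CantileverParams:
    """Probe constants.

    Attributes
    ----------
    kc : float
        Cantilever stiffness, pN/nm (0.8 N/m = 800 pN/nm).
    f0 : float
        Resonance frequency, Hz.
    quality_factor : float
        Dimensionless Q encoding the cantilever drag γc = √(m*·kc)/Q;
        order a few in liquid.
    drive_freq : float
        Base-dither frequency, Hz (off resonance: ≪ f0).
    drive_amplitude_A0 : float
        Free-oscillation amplitude far from the surface, nm.
    """

    kc: float = 800.0
    f0: float = 13e3
    quality_factor: float = 2.0
    drive_freq: float = 500.0
    drive_amplitude_A0: float = 0.5

    def __post_init__(self) -> None:
        for name in ("kc", "f0", "quality_factor", "drive_freq", "drive_amplitude_A0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def effective_mass(self) -> float:
        """Point mass m* = kc/(2π f0)², in pN·s²/nm."""
        return self.kc / (2.0 * math.pi * self.f0) ** 2

    @property
    def gamma_c(self) -> float:
        """Cantilever drag coefficient γc = √(m*·kc)/Q, pN·s/nm."""
        return math.sqrt(self.effective_mass * self.kc) / self.quality_factor


@dataclass
class OscillatoryCurve:
    """Lock-in record of one oscillatory retraction.

    Arrays are per sample along the base–sample displacement axis:
    ``displacement_D`` (nm), ``amplitude_R`` (nm), ``phase_delta`` (degrees).
    """

    displacement_D: np.ndarray
    amplitude_R: np.ndarray
    phase_delta: np.ndarray
    cantilever: CantileverParams
    env: EnvParams = ROOM
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.displacement_D = np.asarray(self.displacement_D, dtype=float)
        self.amplitude_R = np.asarray(self.amplitude_R, dtype=float)
        self.phase_delta = np.asarray(self.phase_delta, dtype=float)
        n = len(self.displacement_D)
        if len(self.amplitude_R) != n or len(self.phase_delta) != n:
            raise ValueError("displacement, amplitude and phase arrays must match")

    def __len__(self) -> int:
        return len(self.displacement_D)


@dataclass
class StiffnessCurve:
    """Polymer stiffness ki vs extension, derived from a lock-in amplitude trace.

    ``stiffness_ki`` is clipped to ≥ 0; the raw (possibly negative) values are
    kept in ``metadata['stiffness_preclip']`` together with the clip mask and
    the A0 reference used, so estimators can avoid censoring bias.
    """

    extension_x: np.ndarray
    stiffness_ki: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.extension_x = np.asarray(self.extension_x, dtype=float)
        self.stiffness_ki = np.asarray(self.stiffness_ki, dtype=float)
        if len(self.extension_x) != len(self.stiffness_ki):
            raise ValueError("extension and stiffness arrays must match")

    def __len__(self) -> int:
        return len(self.extension_x)


def sho_steady_state(
    ki: float, gamma_i: float, c: CantileverParams
) -> tuple[float, float]:
    """Steady-state (amplitude nm, phase degrees) of the driven probe+molecule.

    Full point-mass solution at the drive frequency; no off-resonance
    approximation.  ``gamma_i`` is the molecular drag in pN·s/nm (0 for a
    purely elastic tether).
    """
    if ki < 0:
        raise ValueError("molecular stiffness ki must be >= 0")
    if gamma_i < 0:
        raise ValueError("molecular drag gamma_i must be >= 0")
    omega = 2.0 * math.pi * c.drive_freq
    k = c.kc + ki
    gamma = c.gamma_c + gamma_i
    elastic = k - c.effective_mass * omega**2
    amplitude = c.drive_amplitude_A0 * c.kc / math.hypot(elastic, gamma * omega)
    phase = math.degrees(math.atan2(gamma * omega, elastic))
    return amplitude, phase


def offresonance_amplitude(ki: float, c: CantileverParams) -> float:
    """First-order off-resonance amplitude A0·(1 − ki/kc) (the lock-in model)."""
    return c.drive_amplitude_A0 * (1.0 - ki / c.kc)


def amplitude_to_stiffness(
    curve: OscillatoryCurve,
    A0: float | None = None,
    deflection: str | float = "integrate",
) -> StiffnessCurve:
    """Convert a lock-in amplitude trace to a stiffness–extension curve.

    Per point, ki = kc·(1 − R/A0).  Points where R > A0 (free-cantilever noise)
    would give unphysical negative stiffness and are clipped to 0 with a flag;
    the pre-clip values are retained in metadata.

    Parameters
    ----------
    A0 : float, optional
        Free-oscillation reference amplitude, nm. Defaults to the cantilever's
        configured drive amplitude; the pipeline overrides it with the mean
        amplitude of the detached segment of the same curve.
    deflection : str or float
        How to map base displacement D to tether extension x = D − F/kc.
        ``"integrate"`` (default) reconstructs the static deflection from the
        stiffness trace itself — because dF/dD = ki·kc/(ki+kc), the force is
        the cumulative integral of that series combination along D.
        ``"none"`` leaves the axis uncorrected (the deflection is at most
        ~0.6 nm at kc = 800 pN/nm and 500 pN, but that still warps the steep
        part of the curve near the contour length).  A float subtracts a
        constant deflection, e.g. supplied by a paired pulling curve.
    """
    if A0 is None:
        A0 = curve.cantilever.drive_amplitude_A0
    if not A0 > 0:
        raise ValueError(f"A0 must be > 0, got {A0}")
    if len(curve) == 0:
        raise ValueError("cannot convert an empty curve")
    kc = curve.cantilever.kc
    raw = kc * (1.0 - curve.amplitude_R / A0)
    clipped = raw < 0.0
    ki = np.where(clipped, 0.0, raw)
    if bool(clipped.all()):
        import warnings

        warnings.warn(
            "every point clipped: amplitude never fell below A0",
            DegenerateCurveWarning,
            stacklevel=2,
        )
    D = curve.displacement_D
    if deflection == "integrate":
        from scipy.integrate import cumulative_trapezoid

        # pre-clip values keep the integrated noise zero-mean
        series = raw * kc / (raw + kc)
        force = cumulative_trapezoid(series, D, initial=0.0)
        defl = force / kc
    elif deflection == "none":
        defl = 0.0
    else:
        defl = float(deflection)
    meta = dict(curve.metadata)
    meta.update(
        A0_used=float(A0),
        stiffness_preclip=raw,
        clip_mask=clipped,
        n_clipped=int(clipped.sum()),
        deflection_mode=deflection if isinstance(deflection, str) else "constant",
    )
    return StiffnessCurve(D - defl, ki, meta)


def phase_validity_check(
    curve: OscillatoryCurve, tol_degrees: float = 5.0
) -> tuple[bool, dict[str, float]]:
    """Off-resonance sanity check: the phase trace must sit near zero.

    Returns ``(ok, diagnostics)`` where ``ok`` is true iff the median absolute
    phase is below ``tol_degrees`` and the phase spread (max − min) is below
    2·tol.  A phase excursion signals dissipative or inertial contributions
    that invalidate the amplitude → stiffness relation.
    """
    phase = curve.phase_delta
    if len(phase) == 0:
        raise ValueError("empty phase trace")
    median_abs = float(np.median(np.abs(phase)))
    spread = float(phase.max() - phase.min())
    ok = (median_abs < tol_degrees) and (spread < 2.0 * tol_degrees)
    return ok, {"median_abs_phase": median_abs, "phase_spread": spread}
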