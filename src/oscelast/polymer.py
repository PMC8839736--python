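"""Closed-form polymer elasticity models.

Two entropic-elasticity models used throughout the package:

* the worm-like chain (WLC) in the Marko–Siggia interpolation,
  F(x) = (kBT/lp) [ 1/(4(1−x/L)²) − 1/4 + x/L ],
  with persistence length lp and contour length L, together with its
  analytic stiffness dF/dx and free energy ∫F dx;

* the two-state freely jointed chain (FJC), in which each monomer
  switches between a short (gauche) and a long (trans) conformer with
  force-dependent Boltzmann populations, multiplied by the Langevin
  orientational factor of an ordinary FJC of Kuhn length b.

Forces are pN, lengths nm, energies pN·nm.  All functions accept scalars
or numpy arrays for the mechanical coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .env import EnvParams, ROOM

__all__ = [
    "WLCParams",
    "TwoStateFJCParams",
    "wlc_force",
    "wlc_stiffness",
    "wlc_free_energy",
    "two_state_extension",
    "two_state_extension_slope",
    "two_state_stiffness",
    "kuhn_to_persistence",
    "persistence_to_kuhn",
]


@dataclass(frozen=True)
class WLCParams:
    """Worm-like chain parameters: persistence length and contour length, nm."""

    lp: float
    L: float

    def __post_init__(self) -> None:
        if not self.lp > 0:
            raise ValueError(f"persistence length must be > 0, got {self.lp}")
        if not self.L > 0:
            raise ValueError(f"contour length must be > 0, got {self.L}")


@dataclass(frozen=True)
class TwoStateFJCParams:
    """Two-state FJC parameters.

    Attributes
    ----------
    delta_g0 : float
        Zero-force conformer free-energy gap G_trans − G_gauche, in kBT units.
    l_gauche, l_trans : float
        Monomer contributions of the short and long conformer, nm. The trans
        length defaults to 0.256 nm (two backbone C–C repeats).
    b_kuhn : float
        Kuhn length of the equivalent freely jointed chain, nm.
    n_monomers : int
        Number of monomers; the all-trans contour length is n_monomers·l_trans.
    """

    delta_g0: float = 3.0
    l_gauche: float = 0.2
    l_trans: float = 0.256
    b_kuhn: float = 0.24
    n_monomers: int = 250

    def __post_init__(self) -> None:
        if not (self.l_trans > self.l_gauche > 0):
            raise ValueError(
                f"require l_trans > l_gauche > 0, got l_trans={self.l_trans}, "
                f"l_gauche={self.l_gauche}"
            )
        if not self.b_kuhn > 0:
            raise ValueError(f"Kuhn length must be > 0, got {self.b_kuhn}")
        if not self.n_monomers >= 1:
            raise ValueError(f"n_monomers must be >= 1, got {self.n_monomers}")

    @property
    def contour_length(self) -> float:
        """All-trans contour length n_monomers · l_trans, nm."""
        return self.n_monomers * self.l_trans


def _check_extension(x, L: float):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("extension must be >= 0")
    if np.any(x >= L):
        raise ValueError(f"extension must be < contour length L={L}")
    return x


def wlc_force(x, p: WLCParams, env: EnvParams = ROOM):
    """Marko–Siggia WLC force at extension ``x`` (nm), in pN.

    F(x) = (kBT/lp) [ 1/(4(1−z)²) − 1/4 + z ],  z = x/L.

    Vanishes at x = 0, is strictly increasing, and diverges as x → L.
    """
    x = _check_extension(x, p.L)
    z = x / p.L
    out = (env.kBT / p.lp) * (0.25 / (1.0 - z) ** 2 - 0.25 + z)
    return out if out.ndim else float(out)


def wlc_stiffness(x, p: WLCParams, env: EnvParams = ROOM):
    """WLC stiffness dF/dx at extension ``x``, in pN/nm.

    k(x) = (kBT/(lp·L)) [ 1/(2(1−z)³) + 1 ].
    """
    x = _check_extension(x, p.L)
    z = x / p.L
    out = (env.kBT / (p.lp * p.L)) * (0.5 / (1.0 - z) ** 3 + 1.0)
    return out if out.ndim else float(out)


def wlc_free_energy(x, p: WLCParams, env: EnvParams = ROOM):
    """WLC stretching free energy ∫₀ˣ F dx', in pN·nm (zero at x = 0).

    (kBT·L/lp) [ z²/2 − z/4 + 1/(4(1−z)) − 1/4 ].
    """
    x = _check_extension(x, p.L)
    z = x / p.L
    out = (env.kBT * p.L / p.lp) * (
        0.5 * z**2 - 0.25 * z + 0.25 / (1.0 - z) - 0.25
    )
    return out if out.ndim else float(out)


def _langevin_factor(u):
    """coth(u) − 1/u, evaluated stably for u > 0 (series below u = 1e-4)."""
    u = np.asarray(u, dtype=float)
    small = u < 1e-4
    safe = np.where(small, 1.0, u)
    out = np.where(small, u / 3.0 - u**3 / 45.0, 1.0 / np.tanh(safe) - 1.0 / safe)
    return out


def _langevin_factor_slope(u):
    """d/du of (coth(u) − 1/u): 1/u² − csch²(u), stable for u > 0."""
    u = np.asarray(u, dtype=float)
    small = u < 1e-4
    safe = np.where(small, 1.0, u)
    # csch² overflows harmlessly to 0 for large u via sinh; cap the argument.
    s = np.sinh(np.minimum(safe, 350.0))
    out = np.where(small, 1.0 / 3.0 - u**2 / 15.0, 1.0 / safe**2 - 1.0 / s**2)
    return out


def _check_force(F):
    F = np.asarray(F, dtype=float)
    if np.any(F <= 0):
        raise ValueError("two-state FJC is defined for strictly positive force")
    return F


def _populations(F, p: TwoStateFJCParams, env: EnvParams):
    """Boltzmann populations (p_gauche, p_trans) at force F.

    The force-tilted gap is ΔG(F) = delta_g0·kBT − F·(l_trans − l_gauche);
    stretching favours the longer trans conformer.
    """
    u = p.delta_g0 - F * (p.l_trans - p.l_gauche) / env.kBT  # ΔG/kBT
    p_trans = 1.0 / (np.exp(np.clip(u, -500, 500)) + 1.0)
    return 1.0 - p_trans, p_trans


def two_state_extension(F, p: TwoStateFJCParams, env: EnvParams = ROOM):
    """Relative extension z ∈ (0, 1) of the two-state FJC at force F (pN).

    z = [ l_gauche·p_gauche + l_trans·p_trans ] · zfjc(F) / l_trans,
    where zfjc = coth(F·b/kBT) − kBT/(F·b) is the Langevin factor and the
    populations follow the force-tilted conformer gap.  Absolute extension
    is n_monomers · l_trans · z.
    """
    F = _check_force(F)
    pg, pt = _populations(F, p, env)
    ell = p.l_gauche * pg + p.l_trans * pt
    z = ell * _langevin_factor(F * p.b_kuhn / env.kBT) / p.l_trans
    return z if z.ndim else float(z)


def two_state_extension_slope(F, p: TwoStateFJCParams, env: EnvParams = ROOM):
    """Analytic dz/dF of :func:`two_state_extension`, in 1/pN."""
    F = _check_force(F)
    pg, pt = _populations(F, p, env)
    dl = p.l_trans - p.l_gauche
    ell = p.l_gauche * pg + p.l_trans * pt
    # d(ell)/dF = dl * d(p_trans)/dF, with dp_t/dF = p_t p_g dl / kBT
    dell = dl**2 * pt * pg / env.kBT
    a = p.b_kuhn / env.kBT
    u = F * a
    zf = _langevin_factor(u)
    dzf = a * _langevin_factor_slope(u)
    out = (dell * zf + ell * dzf) / p.l_trans
    return out if out.ndim else float(out)


def two_state_stiffness(F, p: TwoStateFJCParams, env: EnvParams = ROOM):
    """Chain stiffness dF/dX at force F, pN/nm, X = n_monomers·l_trans·z."""
    dz = two_state_extension_slope(F, p, env)
    out = 1.0 / (p.contour_length * np.asarray(dz))
    return out if out.ndim else float(out)


def kuhn_to_persistence(b_kuhn):
    """Persistence length lp = b/2 of the WLC equivalent to a Kuhn chain."""
    b = np.asarray(b_kuhn, dtype=float)
    if np.any(b < 0):
        raise ValueError("Kuhn length must be >= 0")
    out = b / 2.0
    return out if out.ndim else float(out)


def persistence_to_kuhn(lp):
    """Kuhn length b = 2·lp, the inverse of :func:`kuhn_to_persistence`."""
    lp = np.asarray(lp, dtype=float)
    if np.any(lp < 0):
        raise ValueError("persistence length must be >= 0")
    out = 2.0 * lp
    return out if out.ndim else float(out)
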