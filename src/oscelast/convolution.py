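"""Equilibrium statistics of the coupled cantilever–polymer system.

In a pulling experiment the probe and the molecule share one partition
function: the molecule contributes exp(−βF(x)) through its stretching free
energy F(x) and the harmonic probe contributes exp(−β·kc(D−x)²/2) through
its deflection D−x at base displacement D.  The measured force is
kc·(D − ⟨x⟩), a Boltzmann average over this *convolved* weight rather than a
point evaluation of the molecular force law — which is why constant-velocity
pulling can return biased elasticity parameters while a stiff probe
(delta-function deflection weight) or a zero-stiffness force clamp
(magnetic-tweezer limit) samples the intrinsic response.

Moments are computed by adaptive quadrature with a Metropolis Monte Carlo
sampler as an independent oracle.  A hydrophobic free-energy penalty of
scale εh (kBT units) models poor-solvent stretching cost; its profile along
the extension is pluggable ("linear" adds a constant force, "quadratic"
additionally contributes stiffness).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import IntegrationWarning, quad
from scipy.optimize import minimize_scalar

from .cantilever import CantileverParams
from .env import EnvParams, ROOM
from .polymer import (
    WLCParams,
    wlc_force,
    wlc_free_energy,
    wlc_stiffness,
    _langevin_factor,
)
from .synthetic import ForceCurve

__all__ = [
    "FreeEnergySpec",
    "ConvolutionResult",
    "NumericsError",
    "MCTuningWarning",
    "boltzmann_average",
    "mc_oracle",
    "MCResult",
    "simulate_convolved_fec",
    "force_clamp_average",
    "fluctuation_scaling",
]


class NumericsError(RuntimeError):
    """Quadrature failed to converge; the message carries diagnostics."""


class MCTuningWarning(UserWarning):
    """Metropolis acceptance rate left the [0.1, 0.9] band."""


#: Quadrature domain for the WLC stops just short of the contour length,
#: where the free energy has an integrable divergence.
_WLC_DOMAIN_MARGIN = 1e-6


@dataclass(frozen=True)
class FreeEnergySpec:
    """Molecular free-energy landscape F(x) entering the system weight.

    ``kind`` is "wlc" (Marko–Siggia free energy plus optional hydrophobic
    penalty) or "harmonic" (test molecule km·x²/2, closed-form reference).
    The hydrophobic penalty is εh·kBT·profile(x/L) with profile "linear"
    (x/L: constant extra force εh·kBT/L, zero extra stiffness) or
    "quadratic" ((x/L)²: extra force and extra stiffness 2εh·kBT/L²).
    """

    kind: str = "wlc"
    wlc: WLCParams | None = None
    km: float = 0.0  # harmonic spring constant, pN/nm
    eps_h: float = 0.0  # hydrophobic scale, kBT units
    profile: str = "linear"

    def __post_init__(self) -> None:
        if self.kind not in ("wlc", "harmonic"):
            raise ValueError(f"unknown free-energy kind {self.kind!r}")
        if self.kind == "wlc" and self.wlc is None:
            raise ValueError("kind='wlc' requires WLC parameters")
        if self.eps_h < 0:
            raise ValueError("hydrophobic scale eps_h must be >= 0")
        if self.profile not in ("linear", "quadratic"):
            raise ValueError(f"unknown hydrophobic profile {self.profile!r}")

    @classmethod
    def from_wlc(
        cls, p: WLCParams, eps_h: float = 0.0, profile: str = "linear"
    ) -> "FreeEnergySpec":
        return cls(kind="wlc", wlc=p, eps_h=eps_h, profile=profile)

    @classmethod
    def harmonic(cls, km: float) -> "FreeEnergySpec":
        return cls(kind="harmonic", km=km)

    def domain(self) -> tuple[float, float]:
        """Integration domain of x, nm."""
        if self.kind == "harmonic":
            return (-np.inf, np.inf)
        return (0.0, self.wlc.L * (1.0 - _WLC_DOMAIN_MARGIN))

    def free_energy(self, x, env: EnvParams = ROOM):
        """F(x) in pN·nm."""
        if self.kind == "harmonic":
            return 0.5 * self.km * np.asarray(x, dtype=float) ** 2
        base = wlc_free_energy(x, self.wlc, env)
        if self.eps_h:
            z = np.asarray(x, dtype=float) / self.wlc.L
            power = 1 if self.profile == "linear" else 2
            base = base + self.eps_h * env.kBT * z**power
        return base

    def force(self, x, env: EnvParams = ROOM):
        """Intrinsic force dF/dx in pN."""
        if self.kind == "harmonic":
            return self.km * np.asarray(x, dtype=float)
        f = wlc_force(x, self.wlc, env)
        if self.eps_h:
            z = np.asarray(x, dtype=float) / self.wlc.L
            if self.profile == "linear":
                f = f + self.eps_h * env.kBT / self.wlc.L
            else:
                f = f + 2.0 * self.eps_h * env.kBT * z / self.wlc.L
        return f

    def stiffness(self, x, env: EnvParams = ROOM):
        """Intrinsic stiffness d²F/dx² in pN/nm."""
        if self.kind == "harmonic":
            return np.full_like(np.asarray(x, dtype=float), self.km)
        k = wlc_stiffness(x, self.wlc, env)
        if self.eps_h and self.profile == "quadratic":
            k = k + 2.0 * self.eps_h * env.kBT / self.wlc.L**2
        return k


@dataclass
class ConvolutionResult:
    """Boltzmann-averaged pulling curve over a displacement grid."""

    displacement_D: np.ndarray
    mean_x: np.ndarray
    var_x: np.ndarray
    force: np.ndarray  # kc (D − ⟨x⟩), pN


def _system_energy(spec: FreeEnergySpec, kc: float, D: float, env: EnvParams):
    def E(x):
        return spec.free_energy(x, env) + 0.5 * kc * (D - x) ** 2

    return E


def _energy_minimum(E, lo: float, hi: float, D: float) -> float:
    span = 50.0 + abs(D)
    a = lo if np.isfinite(lo) else D - span
    b = hi if np.isfinite(hi) else D + span
    res = minimize_scalar(E, bounds=(a, b), method="bounded",
                          options={"xatol": 1e-10 * max(1.0, b - a)})
    return float(res.x)


def _integration_window(
    E, xstar: float, lo: float, hi: float, env: EnvParams
) -> tuple[float, float]:
    """Finite integration window spanning the Boltzmann weight's support.

    The weight is concentrated within a few local thermal widths
    σ = √(kBT/E''(x*)); a ±60σ window (clipped to the physical domain)
    carries truncation error far below the quadrature tolerance while
    keeping the peak resolvable by adaptive subdivision.
    """
    h = 1e-5 * max(1.0, abs(xstar))
    x_m = xstar - h if (not np.isfinite(lo) or xstar - h > lo) else xstar
    curv = (E(x_m) - 2.0 * E(xstar) + E(xstar + 2 * h if x_m == xstar else xstar + h)) / h**2
    sigma = math.sqrt(env.kBT / max(curv, 1e-9))
    a = max(lo, xstar - 60.0 * sigma) if np.isfinite(lo) else xstar - 60.0 * sigma
    b = min(hi, xstar + 60.0 * sigma) if np.isfinite(hi) else xstar + 60.0 * sigma
    return a, b


def boltzmann_average(
    D: float,
    spec: FreeEnergySpec,
    c: CantileverParams,
    env: EnvParams = ROOM,
) -> tuple[float, float, float]:
    """Boltzmann moments of the tether extension at base displacement D.

    Returns (⟨x⟩ nm, Var(x) nm², measured force kc·(D−⟨x⟩) pN) under the
    weight exp(−β[F(x) + kc(D−x)²/2]), by adaptive quadrature (relative
    tolerance 1e−8, shifted so the weight peaks at 1).
    """
    beta = env.beta
    kc = c.kc
    E = _system_energy(spec, kc, float(D), env)
    lo, hi = spec.domain()
    xstar = _energy_minimum(E, lo, hi, float(D))
    E0 = E(xstar)
    a, b = _integration_window(E, xstar, lo, hi, env)

    def w(x):
        return math.exp(-beta * min(E(x) - E0, 700.0 / beta))

    def integrate(f) -> float:
        with warnings.catch_warnings():
            # at 1e-10 relative tolerance scipy may flag its own roundoff
            # floor; the moment estimates are still far tighter than needed
            warnings.simplefilter("ignore", IntegrationWarning)
            val, err = quad(f, a, b, epsrel=1e-10, epsabs=1e-300, limit=400)
        if not np.isfinite(val):
            raise NumericsError(f"quadrature diverged at D={D}: value={val}")
        return val

    Z = integrate(w)
    if not (np.isfinite(Z) and Z > 0.0):
        raise NumericsError(f"partition integral not positive at D={D}: Z={Z}")
    m1 = integrate(lambda x: (x - xstar) * w(x)) / Z + xstar
    m2c = integrate(lambda x: (x - m1) ** 2 * w(x)) / Z
    return float(m1), float(m2c), float(kc * (D - m1))


@dataclass
class MCResult:
    """Metropolis estimate of the convolved extension moments."""

    mean_x: float
    var_x: float
    se_mean: float
    se_var: float
    acceptance: float
    n_samples: int


def mc_oracle(
    D: float,
    spec: FreeEnergySpec,
    c: CantileverParams,
    env: EnvParams = ROOM,
    n_samples: int = 20000,
    seed: int = 0,
) -> MCResult:
    """Independent Metropolis sampler for the same weight as boltzmann_average.

    Gaussian proposals with step 2.4·√(kBT/(kc + k(x*))) (the 1-D
    optimal-scaling rule, acceptance ≈ 0.45); standard errors by batch means
    (50 batches).  Deterministic for fixed seed.  Warns if the acceptance
    rate leaves [0.1, 0.9].
    """
    if n_samples < 10_000:
        raise ValueError("need n_samples >= 10^4")
    beta = env.beta
    kc = c.kc
    E = _system_energy(spec, kc, float(D), env)
    lo, hi = spec.domain()
    xstar = _energy_minimum(E, lo, hi, float(D))
    h = 1e-4 * max(1.0, abs(xstar))
    x_lo = max(xstar - h, lo + 0.25 * h) if np.isfinite(lo) else xstar - h
    # E'' at the minimum already contains kc plus the local molecular stiffness
    k_local = max((E(x_lo) - 2 * E(xstar) + E(xstar + h)) / h**2, 1e-12)
    step = 2.4 * math.sqrt(env.kBT / k_local)

    rng = np.random.default_rng(seed)
    burn = max(1000, n_samples // 10)
    x = xstar
    Ex = E(x)
    accepted = 0
    samples = np.empty(n_samples)
    steps = rng.normal(0.0, step, size=burn + n_samples)
    us = rng.random(burn + n_samples)
    for i in range(burn + n_samples):
        xp = x + steps[i]
        if xp <= lo or xp >= hi:
            pass  # reject: outside the physical domain
        else:
            Ep = E(xp)
            if Ep <= Ex or us[i] < math.exp(-beta * (Ep - Ex)):
                x, Ex = xp, Ep
                if i >= burn:
                    accepted += 1
            elif i >= burn:
                pass
        if i >= burn:
            samples[i - burn] = x
    acc = accepted / n_samples
    if not (0.1 <= acc <= 0.9):
        warnings.warn(
            f"Metropolis acceptance {acc:.2f} outside [0.1, 0.9]",
            MCTuningWarning,
            stacklevel=2,
        )
    mean = float(samples.mean())
    var = float(samples.var(ddof=1))
    nb = 50
    bs = samples[: (n_samples // nb) * nb].reshape(nb, -1)
    bmeans = bs.mean(axis=1)
    bvars = bs.var(axis=1, ddof=1)
    se_mean = float(bmeans.std(ddof=1) / math.sqrt(nb))
    se_var = float(bvars.std(ddof=1) / math.sqrt(nb))
    return MCResult(mean, var, se_mean, se_var, acc, n_samples)


def simulate_convolved_fec(
    D_grid: np.ndarray,
    spec: FreeEnergySpec,
    c: CantileverParams,
    env: EnvParams = ROOM,
) -> ForceCurve:
    """Equilibrium pulling curve: measured force kc(D−⟨x⟩) over a D grid.

    The returned ForceCurve's ``extension`` property equals ⟨x⟩ exactly
    (D − F/kc), so it flows into the WLC fitting path unchanged.
    """
    D_grid = np.asarray(D_grid, dtype=float)
    if np.any(np.diff(D_grid) <= 0):
        raise ValueError("D grid must be strictly increasing")
    means = np.empty_like(D_grid)
    variances = np.empty_like(D_grid)
    forces = np.empty_like(D_grid)
    for i, D in enumerate(D_grid):
        means[i], variances[i], forces[i] = boltzmann_average(D, spec, c, env)
    meta = {
        "convolved": True,
        "kind": spec.kind,
        "eps_h": spec.eps_h,
        "profile": spec.profile,
    }
    return ForceCurve(
        displacement_D=D_grid,
        force=forces,
        cantilever=c,
        env=env,
        velocity=0.0,
        metadata=meta,
    )


def force_clamp_average(F: float, spec: FreeEnergySpec, env: EnvParams = ROOM) -> float:
    """Mean extension in the constant-force (zero probe stiffness) ensemble.

    ⟨x⟩ under exp(−β[F(x) − F·x]): the magnetic-tweezer limit in which the
    probe's harmonic weight integrates out entirely.
    """
    if F < 0:
        raise ValueError("clamp force must be >= 0")
    beta = env.beta
    lo, hi = spec.domain()

    def E(x):
        return spec.free_energy(x, env) - F * x

    xstar = _energy_minimum(E, lo, hi, D=hi if np.isfinite(hi) else 0.0)
    E0 = E(xstar)
    a, b = _integration_window(E, xstar, lo, hi, env)

    def w(x):
        return math.exp(-beta * min(E(x) - E0, 700.0 / beta))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", IntegrationWarning)
        Z, _ = quad(w, a, b, epsrel=1e-10, epsabs=1e-300, limit=400)
        if not (np.isfinite(Z) and Z > 0.0):
            raise NumericsError(f"force-clamp partition integral not positive at F={F}")
        m1, _ = quad(lambda x: (x - xstar) * w(x), a, b, epsrel=1e-10,
                     epsabs=1e-300, limit=400)
    return float(m1 / Z + xstar)


def fluctuation_scaling(
    n_list, F: float, b: float, env: EnvParams = ROOM
) -> dict[int, float]:
    """Relative extension fluctuation of an N-segment chain under force F.

    Treats the chain as N independent Kuhn segments of length ``b`` in the
    force-tilted orientation ensemble: per-segment mean b·(coth u − 1/u) and
    variance b²·(⟨cos²⟩ − ⟨cos⟩²) with u = F·b/kBT, so the relative standard
    deviation of the total extension falls as 1/√N.  (Summed independent
    contributions give 1/√N for the *relative* fluctuation even though the
    variance itself is extensive, ∝ N.)
    """
    n_arr = np.asarray(list(n_list), dtype=int)
    if np.any(n_arr < 10):
        raise ValueError("all monomer counts must be >= 10")
    if not F > 0:
        raise ValueError("force must be > 0")
    u = F * b / env.kBT
    lang = float(_langevin_factor(u))
    mean_seg = b * lang
    cos2 = 1.0 - 2.0 * lang / u  # ⟨cos²θ⟩ in the tilted ensemble
    var_seg = b**2 * (cos2 - lang**2)
    if var_seg <= 0:
        raise NumericsError(f"degenerate segment variance at u={u}")
    return {
        int(N): float(math.sqrt(N * var_seg) / (N * mean_seg)) for N in n_arr
    }
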