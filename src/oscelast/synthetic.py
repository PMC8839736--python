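"""Synthetic AFM pulling and oscillatory curves, plus the curve file format.

This module stands in for the instrument: it generates constant-velocity
force–extension curves and off-resonance lock-in amplitude/phase curves with
the statistical structure the downstream analysis assumes — per-curve
contour-length heterogeneity (log-normal tether lengths), series coupling
between tether and cantilever (the base displacement D splits into polymer
extension x and cantilever deflection F/kc), additive Gaussian noise, a
zero-force approach segment, and a tether rupture followed by a detached
tail that provides the free-oscillation amplitude reference A0.

Three tether models are supported:

* ``wlc`` — Marko–Siggia worm-like chain;
* ``wlc_plus_transition`` — WLC whose stiffness is multiplied by a smooth
  raised-cosine dip over a configurable extension-fraction window, standing
  in for a force-induced conformational transition (the regime where a plain
  WLC fit fails on PEG in water);
* ``two_state_fjc`` — the explicit two-state freely jointed chain.

Curves serialize to a plain TSV format with ``# key<TAB>value`` header lines
so fixtures are inspectable and diff-able.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .cantilever import CantileverParams, OscillatoryCurve
from .env import EnvParams, ROOM
from .polymer import (
    TwoStateFJCParams,
    WLCParams,
    two_state_extension,
    two_state_extension_slope,
    wlc_force,
    wlc_stiffness,
)

__all__ = [
    "ForceCurve",
    "Preset",
    "GenerationError",
    "ParseError",
    "builtin_presets",
    "generate_pulling_curve",
    "generate_oscillatory_curve",
    "tether_model",
    "write_curve",
    "read_curve",
    "write_preset",
    "read_preset",
]


class GenerationError(RuntimeError):
    """The requested curve cannot be generated (e.g. unreachable rupture force)."""


class ParseError(ValueError):
    """A curve or preset file is malformed; the message names the offence."""


@dataclass
class ForceCurve:
    """One constant-velocity retraction: base displacement vs force.

    Force is kc × cantilever deflection, pN; the tether extension is
    x = D − F/kc (series coupling).
    """

    displacement_D: np.ndarray
    force: np.ndarray
    cantilever: CantileverParams
    env: EnvParams = ROOM
    velocity: float = 80.0
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.displacement_D = np.asarray(self.displacement_D, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if len(self.displacement_D) != len(self.force):
            raise ValueError("displacement and force arrays must match")

    def __len__(self) -> int:
        return len(self.displacement_D)

    @property
    def extension(self) -> np.ndarray:
        """Tether extension x = D − F/kc, nm."""
        return self.displacement_D - self.force / self.cantilever.kc


# ---------------------------------------------------------------------------
# Tether models


class _WLCModel:
    """Plain WLC tether: force/stiffness explicit in extension."""

    def __init__(self, lp: float, L: float, env: EnvParams):
        self.params = WLCParams(lp=lp, L=L)
        self.env = env
        self.L = L

    def force(self, x):
        return wlc_force(x, self.params, self.env)

    def stiffness(self, x):
        return wlc_stiffness(x, self.params, self.env)


class _WLCDipModel(_WLCModel):
    """WLC with a raised-cosine stiffness dip over an extension-fraction window.

    k(x) = k_wlc(x) · (1 − depth·bump(x/L)) with bump = ½(1 + cos) supported
    on ``window`` and peaking at its centre; force is the cumulative integral
    of the dipped stiffness, i.e. the plain WLC force minus a smooth deficit
    that saturates above the window.
    """

    def __init__(
        self,
        lp: float,
        L: float,
        env: EnvParams,
        window: tuple[float, float] = (0.5, 0.7),
        depth: float = 0.5,
    ):
        super().__init__(lp, L, env)
        lo, hi = window
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"transition window must satisfy 0 < lo < hi < 1, got {window}")
        if not (0.0 <= depth < 1.0):
            raise ValueError(f"dip depth must be in [0, 1), got {depth}")
        self.window = (float(lo), float(hi))
        self.depth = float(depth)
        # cumulative force deficit over the window, interpolated later
        zg = np.linspace(lo, hi, 801)
        integrand = self._bump(zg) * wlc_stiffness(zg * L, self.params, env)
        from scipy.integrate import cumulative_trapezoid

        self._z_grid = zg
        self._deficit = depth * L * cumulative_trapezoid(integrand, zg, initial=0.0)

    def _bump(self, z):
        lo, hi = self.window
        mid, width = 0.5 * (lo + hi), hi - lo
        inside = (z > lo) & (z < hi)
        out = np.zeros_like(np.asarray(z, dtype=float))
        out[inside] = 0.5 * (1.0 + np.cos(2.0 * np.pi * (np.asarray(z)[inside] - mid) / width))
        return out

    def stiffness(self, x):
        z = np.asarray(x, dtype=float) / self.L
        out = wlc_stiffness(x, self.params, self.env) * (1.0 - self.depth * self._bump(z))
        return out if out.ndim else float(out)

    def force(self, x):
        z = np.asarray(x, dtype=float) / self.L
        deficit = np.interp(z, self._z_grid, self._deficit)
        out = wlc_force(x, self.params, self.env) - deficit
        return out if out.ndim else float(out)


class _TwoStateModel:
    """Two-state FJC tether: extension explicit in force."""

    def __init__(self, params: TwoStateFJCParams, env: EnvParams):
        self.params = params
        self.env = env
        self.L = params.contour_length

    def extension_at(self, F):
        return self.L * two_state_extension(F, self.params, self.env)

    def slope_at(self, F):
        return self.L * two_state_extension_slope(F, self.params, self.env)


def tether_model(preset: "Preset", L_draw: float):
    """Instantiate the preset's tether model at a drawn contour length (nm)."""
    env = preset.env
    if preset.model == "wlc":
        return _WLCModel(preset.lp, L_draw, env)
    if preset.model == "wlc_plus_transition":
        return _WLCDipModel(
            preset.lp, L_draw, env, window=preset.transition_window, depth=preset.dip_depth
        )
    if preset.model == "two_state_fjc":
        fjc = replace(preset.fjc_params, n_monomers=max(10, round(L_draw / preset.fjc_params.l_trans)))
        return _TwoStateModel(fjc, env)
    raise ValueError(f"unknown tether model {preset.model!r}")


# ---------------------------------------------------------------------------
# Series-coupling solvers (safeguarded vectorized Newton)


def _solve_extension_from_D(model, kc: float, D: np.ndarray) -> np.ndarray:
    """Solve x + F(x)/kc = D per point for an extension-explicit model."""
    D = np.asarray(D, dtype=float)
    hi = np.minimum(D, model.L * (1.0 - 1e-9))
    lo = np.zeros_like(D)
    x = np.minimum(0.9 * D, model.L * 0.5)
    for _ in range(80):
        g = x + model.force(x) / kc - D
        lo = np.where(g < 0, x, lo)
        hi = np.where(g > 0, x, hi)
        step = g / (1.0 + model.stiffness(x) / kc)
        xn = x - step
        bad = (xn <= lo) | (xn >= hi)
        xn = np.where(bad, 0.5 * (lo + hi), xn)
        if np.max(np.abs(xn - x)) < 1e-13 * model.L:
            x = xn
            break
        x = xn
    return x


def _solve_force_from_D(model: _TwoStateModel, kc: float, D: np.ndarray) -> np.ndarray:
    """Solve L·z(F) + F/kc = D per point for a force-explicit model."""
    D = np.asarray(D, dtype=float)
    F = np.full_like(D, 10.0)
    lo = np.full_like(D, 1e-12)
    hi = np.full_like(D, 1e7)
    for _ in range(200):
        h = model.extension_at(F) + F / kc - D
        lo = np.where(h < 0, F, lo)
        hi = np.where(h > 0, F, hi)
        Fn = F - h / (model.slope_at(F) + 1.0 / kc)
        bad = (Fn <= lo) | (Fn >= hi)
        Fn = np.where(bad, 0.5 * (lo + hi), Fn)
        if np.max(np.abs(Fn - F) / np.maximum(F, 1e-6)) < 1e-14:
            F = Fn
            break
        F = Fn
    return F


def _rupture_displacement(model, kc: float, rupture_force: float) -> float:
    """Base displacement at which the noiseless force reaches the rupture force."""
    if isinstance(model, _TwoStateModel):
        return float(model.extension_at(rupture_force) + rupture_force / kc)
    from scipy.optimize import brentq

    xmax = model.L * (1.0 - 1e-9)
    if model.force(xmax) < rupture_force:
        raise GenerationError(
            f"rupture force {rupture_force} pN unreachable for model with L={model.L:.3g} nm"
        )
    x_rup = brentq(lambda x: model.force(x) - rupture_force, 0.0, xmax, xtol=1e-12)
    return float(x_rup + rupture_force / kc)


# ---------------------------------------------------------------------------
# Presets


@dataclass(frozen=True)
class Preset:
    """Named generation settings emulating one experimental condition.

    Contour lengths are drawn per curve from a log-normal distribution with
    the given median (nm) and log-scale shape; the tether model, probe
    constants, retraction velocity, noise magnitudes, rupture force and
    sampling rate complete the instrument description.
    """

    name: str
    model: str  # wlc | two_state_fjc | wlc_plus_transition
    lp: float = 0.5  # WLC persistence length, nm (wlc models)
    fjc_params: TwoStateFJCParams = TwoStateFJCParams()
    transition_window: tuple[float, float] = (0.5, 0.7)
    dip_depth: float = 0.5
    contour_median: float = 100.0
    contour_shape: float = 0.1
    n_curves: int = 25
    velocity: float = 80.0
    force_sigma: float = 5.0  # pN
    amplitude_sigma: float = 0.002  # nm (0.4% of the 0.5 nm drive amplitude)
    phase_sigma: float = 1.0  # degrees
    rupture_force: float = 500.0  # pN
    sampling_rate: float = 2000.0  # Hz
    seed: int = 2022
    cantilever: CantileverParams = CantileverParams()
    env: EnvParams = ROOM

    def __post_init__(self) -> None:
        if self.model not in ("wlc", "two_state_fjc", "wlc_plus_transition"):
            raise ValueError(f"unknown model {self.model!r}")
        for name in ("force_sigma", "amplitude_sigma", "phase_sigma", "contour_shape"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_curves < 1:
            raise ValueError("n_curves must be >= 1")


def builtin_presets() -> dict[str, Preset]:
    """The experimental conditions of the study, as generation presets.

    PEG (10 kDa) in water: 25 curves; pulling at 80 nm/s, oscillatory runs at
    70 nm/s with the conformational-transition dip over extension fractions
    0.5–0.7.  Polystyrene in water / 8M urea: 26 / 14 curves.  Ground-truth
    persistence lengths are the values the corresponding measurements report
    (pulling 0.12 nm and Kuhn 0.24 nm for PEG; oscillatory 0.5 nm PEG,
    0.26 nm PS/water, 0.88 nm PS/urea; pulling 0.23 nm PS/water).
    """
    presets = [
        Preset(
            name="peg_water_pull",
            model="wlc_plus_transition",
            lp=0.12,
            transition_window=(0.75, 0.83),  # maps to the 100-300 pN force band
            contour_median=30.0,
            n_curves=25,
            velocity=80.0,
        ),
        Preset(
            name="peg_water_osc",
            model="wlc_plus_transition",
            lp=0.5,
            transition_window=(0.5, 0.7),  # 50-70 nm at the 100 nm median tether
            contour_median=100.0,
            n_curves=25,
            velocity=70.0,
        ),
        Preset(
            name="peg_water_fjc2",
            model="two_state_fjc",
            fjc_params=TwoStateFJCParams(
                delta_g0=3.0, l_gauche=0.2, l_trans=0.256, b_kuhn=0.24
            ),
            contour_median=60.0,
            n_curves=25,
            velocity=80.0,
        ),
        Preset(
            name="ps_water_osc",
            model="wlc",
            lp=0.26,
            contour_median=150.0,
            n_curves=26,
            velocity=70.0,
        ),
        Preset(
            name="ps_water_pull",
            model="wlc",
            lp=0.23,
            contour_median=150.0,
            n_curves=26,
            velocity=80.0,
        ),
        Preset(
            name="ps_urea_osc",
            model="wlc",
            lp=0.88,
            contour_median=150.0,
            n_curves=14,
            velocity=70.0,
        ),
    ]
    return {p.name: p for p in presets}


# ---------------------------------------------------------------------------
# Generation


def _curve_rng(preset: Preset, curve_index: int, seed: int | None) -> np.random.Generator:
    root = preset.seed if seed is None else seed
    return np.random.default_rng(np.random.SeedSequence([int(root), int(curve_index)]))


def _layout(preset: Preset, model, rng) -> tuple[np.ndarray, int, int, float]:
    """Common displacement grid: approach, stretch, detached tail.

    Returns (D grid, contact_index, rupture_index, D_rupture).  Contact is at
    D = 0; the approach segment covers 10% of the stretch span, the detached
    tail 20%.
    """
    kc = preset.cantilever.kc
    D_rup = _rupture_displacement(model, kc, preset.rupture_force)
    dD = preset.velocity / preset.sampling_rate
    n_stretch = max(2, int(math.floor(D_rup / dD)))
    n_pre = max(10, int(round(0.1 * n_stretch)))
    n_tail = max(10, int(round(0.2 * n_stretch)))
    D = (np.arange(n_pre + n_stretch + n_tail) - n_pre + 1) * dD
    contact = n_pre - 1  # last zero-force sample sits just before D=0
    rupture = n_pre + n_stretch - 1
    return D, contact, rupture, D_rup


def _draw_contour(preset: Preset, rng) -> float:
    return float(preset.contour_median * np.exp(preset.contour_shape * rng.standard_normal()))


def generate_pulling_curve(
    preset: Preset, curve_index: int = 0, seed: int | None = None
) -> ForceCurve:
    """Generate one constant-velocity force–extension curve.

    Deterministic for fixed (seed, curve_index): the per-curve contour length
    draw and the noise stream both derive from that pair.  The curve has a
    zero-force approach segment, a stretch segment whose noiseless force
    follows the preset's tether model at the series-coupled extension, and a
    zero-force detached tail after rupture.
    """
    rng = _curve_rng(preset, curve_index, seed)
    L = _draw_contour(preset, rng)
    model = tether_model(preset, L)
    kc = preset.cantilever.kc
    D, contact, rupture, D_rup = _layout(preset, model, rng)

    force = np.zeros_like(D)
    stretch = slice(contact + 1, rupture + 1)
    Ds = np.minimum(D[stretch], D_rup)
    if isinstance(model, _TwoStateModel):
        force[stretch] = _solve_force_from_D(model, kc, Ds)
    else:
        x = _solve_extension_from_D(model, kc, Ds)
        force[stretch] = model.force(x)
    if preset.force_sigma > 0:
        force = force + rng.normal(0.0, preset.force_sigma, size=force.shape)

    meta = {
        "preset": preset.name,
        "model": preset.model,
        "curve_index": int(curve_index),
        "seed": int(preset.seed if seed is None else seed),
        "L_true": L,
        "contact_index": int(contact),
        "rupture_index": int(rupture),
        "rupture_force": preset.rupture_force,
        "force_sigma": preset.force_sigma,
    }
    return ForceCurve(
        displacement_D=D,
        force=force,
        cantilever=preset.cantilever,
        env=preset.env,
        velocity=preset.velocity,
        metadata=meta,
    )


def generate_oscillatory_curve(
    preset: Preset, curve_index: int = 0, seed: int | None = None
) -> OscillatoryCurve:
    """Generate one off-resonance lock-in curve (amplitude R, phase δ vs D).

    The amplitude follows the off-resonance relation R = A0·(1 − ki/kc) with
    ki the tether model's stiffness at the series-coupled extension; the
    phase sits at zero.  Both receive additive Gaussian noise.  Before
    contact and after rupture the cantilever oscillates freely at A0, which
    is what lets the analysis reference A0 from the detached segment.
    """
    rng = _curve_rng(preset, curve_index, seed)
    L = _draw_contour(preset, rng)
    model = tether_model(preset, L)
    c = preset.cantilever
    D, contact, rupture, D_rup = _layout(preset, model, rng)

    ki = np.zeros_like(D)
    stretch = slice(contact + 1, rupture + 1)
    Ds = np.minimum(D[stretch], D_rup)
    if isinstance(model, _TwoStateModel):
        F = _solve_force_from_D(model, c.kc, Ds)
        ki[stretch] = 1.0 / model.slope_at(F)
    else:
        x = _solve_extension_from_D(model, c.kc, Ds)
        ki[stretch] = model.stiffness(x)

    A0 = c.drive_amplitude_A0
    R = A0 * (1.0 - ki / c.kc)
    phase = np.zeros_like(D)
    if preset.amplitude_sigma > 0:
        R = R + rng.normal(0.0, preset.amplitude_sigma, size=R.shape)
    if preset.phase_sigma > 0:
        phase = phase + rng.normal(0.0, preset.phase_sigma, size=phase.shape)

    meta = {
        "preset": preset.name,
        "model": preset.model,
        "curve_index": int(curve_index),
        "seed": int(preset.seed if seed is None else seed),
        "L_true": L,
        "contact_index": int(contact),
        "rupture_index": int(rupture),
        "rupture_force": preset.rupture_force,
        "amplitude_sigma": preset.amplitude_sigma,
        "phase_sigma": preset.phase_sigma,
        "velocity": preset.velocity,
    }
    return OscillatoryCurve(
        displacement_D=D,
        amplitude_R=R,
        phase_delta=phase,
        cantilever=c,
        env=preset.env,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# Curve file format: TSV with "# key<TAB>value" headers

_REQUIRED_KEYS = ("kc", "f0", "drive_freq", "A0", "velocity", "temperature")


def _format_value(v) -> str:
    if isinstance(v, (bool, int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    return str(v)


def _serializable_meta(meta: dict[str, Any]) -> dict[str, Any]:
    return {
        k: v
        for k, v in meta.items()
        if isinstance(v, (bool, int, float, str, np.integer, np.floating))
    }


def write_curve(curve, path_or_file) -> None:
    """Write a ForceCurve or OscillatoryCurve to the TSV curve format.

    Arrays are written at full float precision (repr), so write → read is a
    lossless roundtrip.
    """
    if isinstance(curve, ForceCurve):
        ctype, columns = "force", ("displacement_D", "force")
        data = np.column_stack([curve.displacement_D, curve.force])
        velocity = curve.velocity
    elif isinstance(curve, OscillatoryCurve):
        ctype, columns = "oscillatory", ("displacement_D", "amplitude_R", "phase_delta")
        data = np.column_stack([curve.displacement_D, curve.amplitude_R, curve.phase_delta])
        velocity = curve.metadata.get("velocity", 0.0)
    else:
        raise TypeError(f"cannot serialize {type(curve).__name__}")

    c = curve.cantilever
    lines = [
        "# oscelast-curve\t1",
        f"# type\t{ctype}",
        f"# kc\t{c.kc!r}",
        f"# f0\t{c.f0!r}",
        f"# quality_factor\t{c.quality_factor!r}",
        f"# drive_freq\t{c.drive_freq!r}",
        f"# A0\t{c.drive_amplitude_A0!r}",
        f"# velocity\t{velocity!r}",
        f"# temperature\t{curve.env.temperature!r}",
    ]
    for k, v in sorted(_serializable_meta(curve.metadata).items()):
        lines.append(f"# meta:{k}\t{_format_value(v)}")
    lines.append("# columns\t" + "\t".join(columns))
    for row in data:
        lines.append("\t".join(repr(float(v)) for v in row))
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_file, "write"):
        path_or_file.write(text)
    else:
        with open(path_or_file, "w") as fh:
            fh.write(text)


def _parse_meta_value(s: str):
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            continue
    return s


def read_curve(path_or_file):
    """Read a curve file written by :func:`write_curve`.

    Raises :class:`ParseError` naming the offending line for malformed
    headers or missing required keys.
    """
    if hasattr(path_or_file, "read"):
        text = path_or_file.read()
    else:
        with open(path_or_file) as fh:
            text = fh.read()

    header: dict[str, str] = {}
    meta: dict[str, Any] = {}
    columns: list[str] | None = None
    rows: list[list[float]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            parts = line[1:].lstrip().split("\t")
            if len(parts) < 2:
                raise ParseError(f"line {lineno}: malformed header line {line!r}")
            key, value = parts[0], parts[1]
            if key == "columns":
                columns = parts[1:]
            elif key.startswith("meta:"):
                meta[key[5:]] = _parse_meta_value(value)
            else:
                header[key] = value
        else:
            if columns is None:
                raise ParseError(f"line {lineno}: data before '# columns' header")
            fields = line.split("\t")
            if len(fields) != len(columns):
                raise ParseError(
                    f"line {lineno}: expected {len(columns)} columns, got {len(fields)}"
                )
            try:
                rows.append([float(v) for v in fields])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-numeric data: {exc}") from exc

    for key in _REQUIRED_KEYS:
        if key not in header:
            raise ParseError(f"missing required header key {key!r}")
    if header.get("type") not in ("force", "oscillatory"):
        raise ParseError(f"missing or unknown curve type {header.get('type')!r}")
    if columns is None or not rows:
        raise ParseError("no data rows found")

    cant = CantileverParams(
        kc=float(header["kc"]),
        f0=float(header["f0"]),
        quality_factor=float(header.get("quality_factor", 2.0)),
        drive_freq=float(header["drive_freq"]),
        drive_amplitude_A0=float(header["A0"]),
    )
    env = EnvParams(temperature=float(header["temperature"]))
    data = np.asarray(rows, dtype=float)
    if header["type"] == "force":
        return ForceCurve(
            displacement_D=data[:, 0],
            force=data[:, 1],
            cantilever=cant,
            env=env,
            velocity=float(header["velocity"]),
            metadata=meta,
        )
    return OscillatoryCurve(
        displacement_D=data[:, 0],
        amplitude_R=data[:, 1],
        phase_delta=data[:, 2],
        cantilever=cant,
        env=env,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# Preset config files (plain key<TAB>value)


def write_preset(preset: Preset, path_or_file) -> None:
    """Serialize a preset to a plain key/value config file (TSV)."""
    c, f = preset.cantilever, preset.fjc_params
    pairs = [
        ("name", preset.name),
        ("model", preset.model),
        ("lp", repr(preset.lp)),
        ("fjc_delta_g0", repr(f.delta_g0)),
        ("fjc_l_gauche", repr(f.l_gauche)),
        ("fjc_l_trans", repr(f.l_trans)),
        ("fjc_b_kuhn", repr(f.b_kuhn)),
        ("fjc_n_monomers", str(f.n_monomers)),
        ("transition_lo", repr(preset.transition_window[0])),
        ("transition_hi", repr(preset.transition_window[1])),
        ("dip_depth", repr(preset.dip_depth)),
        ("contour_median", repr(preset.contour_median)),
        ("contour_shape", repr(preset.contour_shape)),
        ("n_curves", str(preset.n_curves)),
        ("velocity", repr(preset.velocity)),
        ("force_sigma", repr(preset.force_sigma)),
        ("amplitude_sigma", repr(preset.amplitude_sigma)),
        ("phase_sigma", repr(preset.phase_sigma)),
        ("rupture_force", repr(preset.rupture_force)),
        ("sampling_rate", repr(preset.sampling_rate)),
        ("seed", str(preset.seed)),
        ("kc", repr(c.kc)),
        ("f0", repr(c.f0)),
        ("quality_factor", repr(c.quality_factor)),
        ("drive_freq", repr(c.drive_freq)),
        ("A0", repr(c.drive_amplitude_A0)),
        ("temperature", repr(preset.env.temperature)),
    ]
    text = "\n".join(f"{k}\t{v}" for k, v in pairs) + "\n"
    if hasattr(path_or_file, "write"):
        path_or_file.write(text)
    else:
        with open(path_or_file, "w") as fh:
            fh.write(text)


def read_preset(path_or_file) -> Preset:
    """Read a preset config written by :func:`write_preset`."""
    if hasattr(path_or_file, "read"):
        text = path_or_file.read()
    else:
        with open(path_or_file) as fh:
            text = fh.read()
    kv: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"line {lineno}: expected 'key<TAB>value', got {line!r}")
        kv[parts[0]] = parts[1]
    try:
        return Preset(
            name=kv["name"],
            model=kv["model"],
            lp=float(kv["lp"]),
            fjc_params=TwoStateFJCParams(
                delta_g0=float(kv["fjc_delta_g0"]),
                l_gauche=float(kv["fjc_l_gauche"]),
                l_trans=float(kv["fjc_l_trans"]),
                b_kuhn=float(kv["fjc_b_kuhn"]),
                n_monomers=int(kv["fjc_n_monomers"]),
            ),
            transition_window=(float(kv["transition_lo"]), float(kv["transition_hi"])),
            dip_depth=float(kv["dip_depth"]),
            contour_median=float(kv["contour_median"]),
            contour_shape=float(kv["contour_shape"]),
            n_curves=int(kv["n_curves"]),
            velocity=float(kv["velocity"]),
            force_sigma=float(kv["force_sigma"]),
            amplitude_sigma=float(kv["amplitude_sigma"]),
            phase_sigma=float(kv["phase_sigma"]),
            rupture_force=float(kv["rupture_force"]),
            sampling_rate=float(kv["sampling_rate"]),
            seed=int(kv["seed"]),
            cantilever=CantileverParams(
                kc=float(kv["kc"]),
                f0=float(kv["f0"]),
                quality_factor=float(kv["quality_factor"]),
                drive_freq=float(kv["drive_freq"]),
                drive_amplitude_A0=float(kv["A0"]),
            ),
            env=EnvParams(temperature=float(kv["temperature"])),
        )
    except KeyError as exc:
        raise ParseError(f"missing required preset key {exc.args[0]!r}") from exc
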