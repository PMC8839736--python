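"""Exclusion-windowed nonlinear least-squares fitting of elasticity models.

The estimation workflow mirrors standard single-molecule practice: identify
the stretch segment of a curve, optionally exclude force or extension windows
where the model is known not to apply (a conformational-transition region),
fit by plain least squares, record the apparent contour length L_app, and
normalize extension axes by L_app so heterogeneous tethers collapse onto a
master curve.  The two-state FJC is fitted with extension as the response at
the measured force (the model is explicit in that direction); the WLC is
fitted as F(x) or k(x).

Parameter uncertainties come from the Gauss–Newton covariance; a residual
resampling bootstrap is available as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .cantilever import StiffnessCurve
from .env import EnvParams, ROOM
from .polymer import (
    TwoStateFJCParams,
    two_state_extension,
    wlc_force,
    wlc_stiffness,
    WLCParams,
)
from .synthetic import ForceCurve

__all__ = [
    "ExclusionWindow",
    "FitResult",
    "FittingError",
    "BootstrapResult",
    "fit_wlc_to_fec",
    "fit_wlc_to_stiffness",
    "fit_two_state_fjc",
    "normalize_by_contour",
    "bootstrap_uncertainty",
    "PEG_FORCE_WINDOW",
]


class FittingError(RuntimeError):
    """Fitting is impossible (too few points, empty stretch segment, ...)."""


@dataclass(frozen=True)
class ExclusionWindow:
    """Half-open interval [low, high) to exclude from the residual set.

    ``axis`` selects the coordinate the interval applies to: measured force
    (pN), extension (nm), or extension fraction x/L_app (dimensionless; the
    apparent contour length comes from a first-pass fit).
    """

    axis: str  # force | extension | extension_fraction
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.axis not in ("force", "extension", "extension_fraction"):
            raise ValueError(f"unknown exclusion axis {self.axis!r}")
        if not self.low < self.high:
            raise ValueError(f"require low < high, got [{self.low}, {self.high})")


#: The intermediate-force band where a plain WLC fails on PEG in water.
PEG_FORCE_WINDOW = ExclusionWindow("force", 100.0, 300.0)


@dataclass
class FitResult:
    """Converged (or flagged) least-squares estimate of one elasticity model."""

    model: str
    params: dict[str, float]
    stderr: dict[str, float]
    rss: float
    n_points: int
    windows: tuple[ExclusionWindow, ...]
    L_app: float
    converged: bool
    # internals for bootstrap / normalization (response-space data and model)
    x_data: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    y_data: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    y_fit: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    _refit: Callable[[np.ndarray], "FitResult"] | None = field(default=None, repr=False)

    def to_record(self) -> dict[str, Any]:
        """JSON-serializable per-curve fit record."""
        return {
            "model": self.model,
            "params": {k: float(v) for k, v in self.params.items()},
            "stderr": {k: float(v) for k, v in self.stderr.items()},
            "rss": float(self.rss),
            "n_points": int(self.n_points),
            "windows": [[w.axis, w.low, w.high] for w in self.windows],
            "L_app": float(self.L_app),
            "converged": bool(self.converged),
        }


def _stretch_indices(curve) -> np.ndarray:
    """Indices of the tethered stretch segment.

    Uses the generator/event-detector indices from metadata when present;
    otherwise falls back to every point with a positive response (suits
    monotone, rupture-free simulated curves).
    """
    meta = getattr(curve, "metadata", {})
    n = len(curve)
    if "contact_index" in meta and "rupture_index" in meta:
        lo, hi = int(meta["contact_index"]) + 1, int(meta["rupture_index"]) + 1
        return np.arange(max(lo, 0), min(hi, n))
    if isinstance(curve, ForceCurve):
        y = curve.force
    else:
        y = curve.stiffness_ki
    return np.nonzero(y > 0)[0]


def _apply_windows(
    mask: np.ndarray,
    windows: Sequence[ExclusionWindow],
    force: np.ndarray | None,
    extension: np.ndarray,
    L_app: float | None,
) -> np.ndarray:
    out = mask.copy()
    for w in windows:
        if w.axis == "force":
            if force is None:
                raise ValueError("force-axis exclusion needs a measured force")
            coord = force
        elif w.axis == "extension":
            coord = extension
        else:
            if L_app is None:
                continue  # applied on the second pass once L_app is known
            coord = extension / L_app
        out &= ~((coord >= w.low) & (coord < w.high))
    return out


def _lsq(
    model_fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
    x: np.ndarray,
    y: np.ndarray,
    p0: np.ndarray,
    bounds: tuple[np.ndarray, np.ndarray],
    names: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Bounded least squares with Gauss–Newton standard errors."""
    res = least_squares(
        lambda p: model_fn(p, x) - y,
        p0,
        bounds=bounds,
        xtol=1e-10,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=2000,
    )
    converged = bool(res.status > 0)
    rss = float(2.0 * res.cost)
    dof = max(len(y) - len(p0), 1)
    try:
        jtj_inv = np.linalg.pinv(res.jac.T @ res.jac)
        stderr = np.sqrt(np.clip(np.diag(jtj_inv) * rss / dof, 0.0, None))
    except np.linalg.LinAlgError:
        stderr = np.full(len(p0), np.nan)
        converged = False
    return res.x, stderr, rss, converged


def _fit_wlc_core(
    x: np.ndarray,
    y: np.ndarray,
    model: str,
    env: EnvParams,
    windows: tuple[ExclusionWindow, ...],
    force_coord: np.ndarray | None,
) -> FitResult:
    """Shared WLC fitting for force (model='wlc_fec') or stiffness responses."""
    fn = wlc_force if model == "wlc_fec" else wlc_stiffness

    def predict(p: np.ndarray, xx: np.ndarray) -> np.ndarray:
        lp, L = p
        xx = np.minimum(xx, L * (1.0 - 1e-12))
        return fn(xx, WLCParams(lp=lp, L=L), env)

    def run(xx: np.ndarray, yy: np.ndarray, used: tuple[ExclusionWindow, ...]) -> FitResult:
        if len(xx) < 10:
            raise FittingError(f"only {len(xx)} points after exclusion; need >= 10")
        xmax = float(xx.max())
        p0 = np.array([0.3, 1.1 * xmax])
        lb = np.array([0.01, xmax * (1.0 + 1e-6)])
        ub = np.array([10.0, 100.0 * xmax])
        popt, perr, rss, conv = _lsq(predict, xx, yy, p0, (lb, ub), ("lp", "L"))
        yfit = predict(popt, xx)
        result = FitResult(
            model=model,
            params={"lp": float(popt[0]), "L": float(popt[1])},
            stderr={"lp": float(perr[0]), "L": float(perr[1])},
            rss=rss,
            n_points=len(xx),
            windows=used,
            L_app=float(popt[1]),
            converged=conv,
        )
        result.x_data, result.y_data, result.y_fit = xx, yy, yfit
        result._refit = lambda ynew: run(xx, ynew, used)
        return result

    keep = np.isfinite(y) & (x > 0)
    keep = _apply_windows(keep, windows, force_coord, x, None)
    first = run(x[keep], y[keep], tuple(windows))
    frac_windows = [w for w in windows if w.axis == "extension_fraction"]
    if not frac_windows or not first.converged:
        return first
    keep2 = np.isfinite(y) & (x > 0)
    keep2 = _apply_windows(keep2, windows, force_coord, x, first.L_app)
    return run(x[keep2], y[keep2], tuple(windows))


def fit_wlc_to_fec(
    curve: ForceCurve,
    windows: Sequence[ExclusionWindow] = (),
    env: EnvParams | None = None,
) -> FitResult:
    """Fit the Marko–Siggia WLC to a force–extension curve.

    Free parameters (lp, L) with lp bounded to [0.01, 10] nm and L above the
    maximum observed extension.  Points inside any exclusion window are
    removed from the residual set (the model itself is unchanged).  A
    non-converged optimizer yields a flagged result, not an exception.
    """
    env = env or curve.env
    idx = _stretch_indices(curve)
    if len(idx) < 10:
        raise FittingError("stretch segment too short to fit")
    x = curve.extension[idx]
    F = curve.force[idx]
    return _fit_wlc_core(x, F, "wlc_fec", env, tuple(windows), force_coord=F)


def fit_wlc_to_stiffness(
    curve: StiffnessCurve,
    windows: Sequence[ExclusionWindow] = (),
    env: EnvParams = ROOM,
) -> FitResult:
    """Fit the WLC stiffness model k(x) to a stiffness–extension curve.

    Uses the retained pre-clip stiffness values when available: clipping
    negative-noise points to zero censors the noise distribution and would
    bias the low-extension part of the fit upward.
    """
    idx = _stretch_indices(curve)
    if len(idx) < 10:
        raise FittingError("stretch segment too short to fit")
    x = curve.extension_x[idx]
    k = curve.metadata.get("stiffness_preclip", curve.stiffness_ki)
    k = np.asarray(k)[idx]
    if any(w.axis == "force" for w in windows):
        raise ValueError("force-axis exclusion is undefined for stiffness curves")
    return _fit_wlc_core(x, k, "wlc_stiffness", env, tuple(windows), force_coord=None)


def fit_two_state_fjc(
    curve: ForceCurve,
    env: EnvParams | None = None,
    fixed_l_trans: float = 0.256,
    min_force: float = 25.0,
) -> FitResult:
    """Fit the two-state FJC with extension as the response at measured force.

    Free parameters: conformer gap delta_g0 (kBT), gauche length l_gauche
    (nm), Kuhn length b_kuhn (nm) and the apparent all-trans contour length
    L_app (which absorbs the monomer count); the trans monomer length is held
    fixed (default 0.256 nm).  Only points with force above ``min_force`` are
    used — the Langevin factor is singular at zero force and the approach
    region carries no conformational information.
    """
    env = env or curve.env
    idx = _stretch_indices(curve)
    F_all = curve.force[idx]
    x_all = curve.extension[idx]
    keep = F_all > min_force
    F, x = F_all[keep], x_all[keep]
    if len(F) < 10:
        raise FittingError("too few positive-force points to fit the two-state FJC")

    def predict(p: np.ndarray, FF: np.ndarray) -> np.ndarray:
        dg0, lg, bk, L_app = p
        tp = TwoStateFJCParams(
            delta_g0=dg0, l_gauche=lg, l_trans=fixed_l_trans, b_kuhn=bk, n_monomers=10
        )
        return L_app * two_state_extension(FF, tp, env)

    def run(FF: np.ndarray, xx: np.ndarray) -> FitResult:
        xmax = float(xx.max())
        p0 = np.array([3.0, 0.2, 0.24, xmax / 0.95])
        lb = np.array([-20.0, 0.02, 0.02, xmax * 0.5])
        ub = np.array([50.0, fixed_l_trans - 1e-3, 5.0, xmax * 5.0])
        names = ("delta_g0", "l_gauche", "b_kuhn", "L_app")
        popt, perr, rss, conv = _lsq(predict, FF, xx, p0, (lb, ub), names)
        result = FitResult(
            model="two_state_fjc",
            params=dict(zip(names, map(float, popt))),
            stderr=dict(zip(names, map(float, perr))),
            rss=rss,
            n_points=len(FF),
            windows=(),
            L_app=float(popt[3]),
            converged=conv,
        )
        result.params["l_trans"] = float(fixed_l_trans)
        result.stderr["l_trans"] = 0.0
        result.x_data, result.y_data, result.y_fit = FF, xx, predict(popt, FF)
        result._refit = lambda ynew: run(FF, ynew)
        return result

    return run(F, x)


def normalize_by_contour(
    curves: Sequence[Any], fits: Sequence[FitResult]
) -> tuple[list[Any], dict[int, str]]:
    """Rescale extension axes to x/L_app using each curve's fitted contour.

    Curves whose fit did not converge, or whose L_app is outside [0.5×, 2×]
    the maximum observed extension (the normalizability selection rule), are
    dropped; the report maps the curve's position to the drop reason.

    Returns (normalized curves, drop report).  Normalized copies carry
    ``metadata['normalized'] = True`` and ``metadata['L_app']``.
    """
    if len(curves) != len(fits):
        raise ValueError("curves and fits must align")
    out: list[Any] = []
    dropped: dict[int, str] = {}
    for i, (curve, fit) in enumerate(zip(curves, fits)):
        if not fit.converged:
            dropped[i] = "fit did not converge"
            continue
        if isinstance(curve, ForceCurve):
            ext = curve.extension
        elif isinstance(curve, StiffnessCurve):
            ext = curve.extension_x
        else:
            raise TypeError(f"cannot normalize {type(curve).__name__}")
        idx = _stretch_indices(curve)
        xmax = float(ext[idx].max()) if len(idx) else float(np.max(ext))
        if not (0.5 * xmax <= fit.L_app <= 2.0 * xmax) or fit.L_app <= xmax:
            dropped[i] = f"L_app={fit.L_app:.3g} outside [0.5, 2] x max extension {xmax:.3g}"
            continue
        meta = dict(getattr(curve, "metadata", {}))
        meta.update(normalized=True, L_app=fit.L_app)
        if isinstance(curve, ForceCurve):
            nc = ForceCurve(
                displacement_D=ext / fit.L_app,
                force=curve.force.copy(),
                cantilever=curve.cantilever,
                env=curve.env,
                velocity=curve.velocity,
                metadata=meta,
            )
        else:
            nc = StiffnessCurve(ext / fit.L_app, curve.stiffness_ki.copy(), meta)
        out.append(nc)
    if not out:
        raise FittingError("no curves survived contour-length normalization")
    return out, dropped


@dataclass
class BootstrapResult:
    """Residual-resampling bootstrap standard errors."""

    stderr: dict[str, float]
    n_replicates: int
    n_failed: int
    flagged: bool  # > 20% of refits failed


def bootstrap_uncertainty(
    curve: Any,
    fit_op: Callable[[Any], FitResult],
    B: int = 200,
    seed: int = 0,
) -> BootstrapResult:
    """Residual-resampling bootstrap of a fit's parameter uncertainties.

    Re-runs ``fit_op``'s least-squares core on ``B`` synthetic responses
    y_fit + resampled residuals.  Deterministic for fixed seed.
    """
    if B < 50:
        raise ValueError("need at least B=50 bootstrap replicates")
    base = fit_op(curve)
    if base._refit is None:
        raise FittingError("fit result does not support refitting")
    resid = base.y_data - base.y_fit
    rng = np.random.default_rng(seed)
    names = [k for k in base.params if k in base.stderr]
    draws: dict[str, list[float]] = {k: [] for k in names}
    n_failed = 0
    for _ in range(B):
        ystar = base.y_fit + rng.choice(resid, size=len(resid), replace=True)
        try:
            fit = base._refit(ystar)
        except (FittingError, ValueError):
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        for k in names:
            draws[k].append(fit.params[k])
    stderr = {
        k: float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
        for k, v in draws.items()
    }
    return BootstrapResult(
        stderr=stderr,
        n_replicates=B,
        n_failed=n_failed,
        flagged=n_failed > 0.2 * B,
    )
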