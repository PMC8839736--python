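"""Least-squares model fitting, exclusion windows, normalization, bootstrap."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import least_squares

from oscelast.cantilever import StiffnessCurve, amplitude_to_stiffness
from oscelast.env import ROOM
from oscelast.fitting import (
    ExclusionWindow,
    FitResult,
    FittingError,
    bootstrap_uncertainty,
    fit_two_state_fjc,
    fit_wlc_to_fec,
    fit_wlc_to_stiffness,
    normalize_by_contour,
)
from oscelast.polymer import WLCParams, wlc_force
from oscelast.synthetic import (
    ForceCurve,
    builtin_presets,
    generate_oscillatory_curve,
    generate_pulling_curve,
)

PRESETS = builtin_presets()


def noiseless(p, **kw):
    return dataclasses.replace(
        p, force_sigma=0.0, amplitude_sigma=0.0, phase_sigma=0.0,
        contour_shape=0.0, **kw
    )


class TestWLCFECFit:
    def test_noiseless_exact_recovery(self):
        p = noiseless(PRESETS["ps_water_pull"], lp=0.12, contour_median=30.0,
                      model="wlc")
        curve = generate_pulling_curve(p, 0)
        fit = fit_wlc_to_fec(curve)
        assert fit.converged
        assert fit.params["lp"] == pytest.approx(0.12, rel=1e-4)
        assert fit.params["L"] == pytest.approx(30.0, rel=1e-4)

    def test_force_window_filter_semantics(self):
        p = noiseless(PRESETS["ps_water_pull"], model="wlc")
        curve = generate_pulling_curve(p, 0)
        w = ExclusionWindow("force", 100.0, 300.0)
        fit = fit_wlc_to_fec(curve, windows=[w])
        i0, i1 = curve.metadata["contact_index"], curve.metadata["rupture_index"]
        F = curve.force[i0 + 1 : i1 + 1]
        x = curve.extension[i0 + 1 : i1 + 1]
        inside = (F >= 100.0) & (F < 300.0)
        expected_n = int(((x > 0) & ~inside).sum())
        assert fit.n_points == expected_n
        # the excluded forces are absent from the residual set
        assert not np.any((fit.y_data >= 100.0) & (fit.y_data < 300.0))

    def test_too_few_points_raises(self):
        curve = ForceCurve(
            displacement_D=np.linspace(0, 1, 5),
            force=np.linspace(0, 10, 5),
            cantilever=PRESETS["peg_water_pull"].cantilever,
        )
        with pytest.raises(FittingError):
            fit_wlc_to_fec(curve)

    def test_ensemble_recovers_ground_truth_with_dip_excluded(self):
        # the conformational-transition dip distorts 100-300 pN; excluding it
        # leaves the underlying lp = 0.12 nm recoverable
        p = PRESETS["peg_water_pull"]
        w = ExclusionWindow("force", 100.0, 300.0)
        lps = []
        for i in range(10):
            fit = fit_wlc_to_fec(generate_pulling_curve(p, i), windows=[w])
            assert fit.converged
            lps.append(fit.params["lp"])
        assert np.mean(lps) == pytest.approx(0.12, abs=0.02)


class TestWLCStiffnessFit:
    def test_noiseless_exact_recovery(self):
        p = noiseless(PRESETS["ps_water_osc"])
        curve = generate_oscillatory_curve(p, 0)
        fit = fit_wlc_to_stiffness(amplitude_to_stiffness(curve))
        assert fit.params["lp"] == pytest.approx(p.lp, rel=1e-4)
        assert fit.params["L"] == pytest.approx(p.contour_median, rel=1e-4)

    def test_force_window_rejected_for_stiffness_data(self):
        p = noiseless(PRESETS["ps_water_osc"])
        curve = amplitude_to_stiffness(generate_oscillatory_curve(p, 0))
        with pytest.raises(ValueError):
            fit_wlc_to_stiffness(curve, windows=[ExclusionWindow("force", 1, 2)])

    def test_extension_fraction_window_uses_two_pass_contour(self):
        p = noiseless(PRESETS["peg_water_osc"])
        curve = amplitude_to_stiffness(generate_oscillatory_curve(p, 0))
        w = ExclusionWindow("extension_fraction", 0.5, 0.7)
        fit = fit_wlc_to_stiffness(curve, windows=[w])
        assert fit.converged
        # with the dip removed the fit recovers the clean WLC parameters
        assert fit.params["lp"] == pytest.approx(0.5, rel=0.01)
        z = fit.x_data / fit.L_app
        assert not np.any((z >= 0.5) & (z < 0.7))


class TestTwoStateFJCFit:
    def test_noiseless_exact_recovery(self):
        p = noiseless(PRESETS["peg_water_fjc2"])
        curve = generate_pulling_curve(p, 0)
        fit = fit_two_state_fjc(curve)
        assert fit.converged
        assert fit.params["b_kuhn"] == pytest.approx(0.24, abs=1e-3)
        assert fit.params["l_gauche"] == pytest.approx(0.2, abs=5e-3)
        assert fit.params["delta_g0"] == pytest.approx(3.0, abs=0.05)
        assert fit.params["l_trans"] == 0.256

    def test_beats_single_state_fjc_on_transition_data(self):
        # a plain one-state FJC (no conformer switching) must fit worse
        p = PRESETS["peg_water_fjc2"]
        curve = generate_pulling_curve(p, 0)
        fit2 = fit_two_state_fjc(curve)

        i = np.nonzero(curve.force > 25.0)[0]
        idx = i[(i > curve.metadata["contact_index"])
                & (i <= curve.metadata["rupture_index"])]
        F, x = curve.force[idx], curve.extension[idx]

        def single_state(params):
            b, L = params
            u = F * b / ROOM.kBT
            return L * (1.0 / np.tanh(u) - 1.0 / u) - x

        res = least_squares(single_state, [0.24, x.max() / 0.95],
                            bounds=([0.01, x.max() * 0.5], [5.0, x.max() * 5]))
        rss_single = float(2 * res.cost)
        assert fit2.rss < rss_single

    def test_rejects_forceless_curve(self):
        curve = ForceCurve(
            displacement_D=np.linspace(0, 10, 100),
            force=np.zeros(100),
            cantilever=PRESETS["peg_water_fjc2"].cantilever,
        )
        with pytest.raises(FittingError):
            fit_two_state_fjc(curve)


class TestNormalization:
    def test_rescaling_arithmetic(self):
        c = PRESETS["peg_water_pull"].cantilever
        x = np.linspace(0.0, 27.0, 50)
        curve = ForceCurve(displacement_D=x, force=np.zeros(50), cantilever=c)
        fit = FitResult(
            model="wlc_fec", params={"lp": 0.12, "L": 30.0}, stderr={},
            rss=0.0, n_points=50, windows=(), L_app=30.0, converged=True,
        )
        out, dropped = normalize_by_contour([curve], [fit])
        assert not dropped
        assert out[0].displacement_D.max() == pytest.approx(0.9)
        assert out[0].metadata["L_app"] == 30.0

    def test_heterogeneous_ensemble_collapses(self):
        # normalized force at a fixed fractional extension varies far less
        # across tethers than raw force at a fixed absolute extension
        p = dataclasses.replace(PRESETS["ps_water_pull"], force_sigma=0.0,
                                contour_shape=0.15)
        curves = [generate_pulling_curve(p, i) for i in range(8)]
        fits = [fit_wlc_to_fec(c) for c in curves]
        normed, _ = normalize_by_contour(curves, fits)

        def spread(cs, grid_axis):
            vals = []
            for c in cs:
                i0, i1 = c.metadata["contact_index"], c.metadata["rupture_index"]
                x, F = c.displacement_D[i0 + 1:i1 + 1], c.force[i0 + 1:i1 + 1]
                vals.append(np.interp(grid_axis, x, F))
            return np.std(vals)

        raw_spread = spread(curves, 0.5 * p.contour_median)
        norm_spread = spread(normed, 0.5)
        assert norm_spread < 0.2 * raw_spread

    def test_non_converged_curve_dropped_with_reason(self):
        c = PRESETS["peg_water_pull"].cantilever
        x = np.linspace(0.0, 27.0, 50)
        curve = ForceCurve(displacement_D=x, force=np.zeros(50), cantilever=c)
        good = FitResult("wlc_fec", {"lp": 0.12, "L": 30.0}, {}, 0.0, 50, (),
                         30.0, True)
        bad = FitResult("wlc_fec", {"lp": 0.12, "L": 30.0}, {}, 0.0, 50, (),
                        30.0, False)
        out, dropped = normalize_by_contour([curve, curve], [good, bad])
        assert len(out) == 1
        assert dropped == {1: "fit did not converge"}

    def test_all_dropped_raises(self):
        c = PRESETS["peg_water_pull"].cantilever
        curve = ForceCurve(np.linspace(0, 27, 50), np.zeros(50), c)
        bad = FitResult("wlc_fec", {}, {}, 0.0, 50, (), 30.0, False)
        with pytest.raises(FittingError):
            normalize_by_contour([curve], [bad])


class TestBootstrap:
    def test_zero_noise_gives_negligible_errors(self):
        p = noiseless(PRESETS["ps_water_pull"], model="wlc")
        curve = generate_pulling_curve(p, 0)
        boot = bootstrap_uncertainty(curve, fit_wlc_to_fec, B=60, seed=1)
        assert boot.stderr["lp"] < 1e-6
        assert not boot.flagged

    def test_seed_reproducibility(self):
        curve = generate_pulling_curve(PRESETS["ps_water_pull"], 0)
        a = bootstrap_uncertainty(curve, fit_wlc_to_fec, B=60, seed=5)
        b = bootstrap_uncertainty(curve, fit_wlc_to_fec, B=60, seed=5)
        assert a.stderr == b.stderr

    def test_errors_shrink_with_point_density(self):
        # 4x the sampling rate → ~2x smaller parameter errors
        base = dataclasses.replace(PRESETS["ps_water_pull"], contour_shape=0.0)
        dense = dataclasses.replace(base, sampling_rate=4 * base.sampling_rate)
        b1 = bootstrap_uncertainty(
            generate_pulling_curve(base, 0), fit_wlc_to_fec, B=80, seed=2
        )
        b2 = bootstrap_uncertainty(
            generate_pulling_curve(dense, 0), fit_wlc_to_fec, B=80, seed=2
        )
        ratio = b1.stderr["lp"] / b2.stderr["lp"]
        assert 1.4 < ratio < 2.9

    def test_requires_minimum_replicates(self):
        curve = generate_pulling_curve(PRESETS["ps_water_pull"], 0)
        with pytest.raises(ValueError):
            bootstrap_uncertainty(curve, fit_wlc_to_fec, B=10, seed=0)
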