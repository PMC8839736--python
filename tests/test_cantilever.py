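"""Driven-cantilever response and lock-in amplitude → stiffness conversion."""

import numpy as np
import pytest

from oscelast.cantilever import (
    CantileverParams,
    DegenerateCurveWarning,
    OscillatoryCurve,
    StiffnessCurve,
    amplitude_to_stiffness,
    offresonance_amplitude,
    phase_validity_check,
    sho_steady_state,
)

C = CantileverParams()  # kc=800 pN/nm, f0=13 kHz, drive 500 Hz, A0=0.5 nm


def make_osc(R, phase=None, c=C, **meta):
    R = np.asarray(R, dtype=float)
    if phase is None:
        phase = np.zeros_like(R)
    D = np.arange(len(R), dtype=float)
    return OscillatoryCurve(D, R, np.asarray(phase, dtype=float), c, metadata=meta)


class TestSHOSteadyState:
    def test_static_free_limit(self):
        # ω → 0, γ → 0, no molecule: the tip follows the base at A0, in phase
        c = CantileverParams(drive_freq=1e-3, quality_factor=1e9)
        A, d = sho_steady_state(0.0, 0.0, c)
        assert A == pytest.approx(c.drive_amplitude_A0, rel=1e-9)
        assert d == pytest.approx(0.0, abs=1e-6)

    def test_resonance_phase_is_ninety_degrees(self):
        # driving exactly at ω² = k/m* zeroes the elastic term
        c = CantileverParams(drive_freq=13e3)
        A, d = sho_steady_state(0.0, 0.0, c)
        assert d == pytest.approx(90.0, abs=1e-9)

    def test_offresonance_negligible_damping_and_inertia(self):
        # at 500 Hz vs 13 kHz the full solution matches the static series
        # response kc/(kc+ki) to well under 1% of A0, for ki up to 0.2 kc
        for ki in np.linspace(0.0, 0.2 * C.kc, 9):
            A, _ = sho_steady_state(ki, 0.0, C)
            static = C.drive_amplitude_A0 * C.kc / (C.kc + ki)
            assert abs(A - static) / C.drive_amplitude_A0 < 0.01

    def test_linearized_amplitude_error_law(self):
        # the working relation A0(1 − ki/kc) differs from the static series
        # response by A0·r²/(1+r): ~1% of A0 at r = 0.1, 3.3% at r = 0.2
        for r in [0.02, 0.05, 0.1, 0.2]:
            ki = r * C.kc
            static = C.drive_amplitude_A0 * C.kc / (C.kc + ki)
            approx = offresonance_amplitude(ki, C)
            err = abs(static - approx) / C.drive_amplitude_A0
            assert err == pytest.approx(r**2 / (1 + r), rel=1e-9)
        A, _ = sho_steady_state(0.1 * C.kc, 0.0, C)
        assert abs(A - offresonance_amplitude(0.1 * C.kc, C)) / C.drive_amplitude_A0 < 0.011

    def test_amplitude_strictly_decreasing_in_stiffness(self):
        amps = [sho_steady_state(ki, 0.0, C)[0] for ki in np.linspace(0, 300, 30)]
        assert np.all(np.diff(amps) < 0)

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            sho_steady_state(-1.0, 0.0, C)
        with pytest.raises(ValueError):
            sho_steady_state(1.0, -1.0, C)


class TestAmplitudeToStiffness:
    def test_free_cantilever_gives_zero_stiffness(self):
        curve = make_osc(np.full(20, 0.5))
        out = amplitude_to_stiffness(curve, A0=0.5)
        assert np.allclose(out.stiffness_ki, 0.0)

    def test_worked_conversion(self):
        curve = make_osc([0.45, 0.45, 0.45])
        out = amplitude_to_stiffness(curve, A0=0.5)
        assert np.allclose(out.stiffness_ki, 80.0)

    def test_clipping_flags_and_preclip_retention(self):
        curve = make_osc([0.45, 0.52, 0.5])
        out = amplitude_to_stiffness(curve, A0=0.5, deflection="none")
        assert out.stiffness_ki[1] == 0.0
        assert out.metadata["stiffness_preclip"][1] == pytest.approx(-32.0)
        assert list(out.metadata["clip_mask"]) == [False, True, False]
        assert out.metadata["n_clipped"] == 1

    def test_all_clipped_warns_degenerate(self):
        curve = make_osc(np.full(10, 0.6))
        with pytest.warns(DegenerateCurveWarning):
            amplitude_to_stiffness(curve, A0=0.5)

    def test_invalid_reference_amplitude(self):
        curve = make_osc([0.4, 0.4])
        with pytest.raises(ValueError):
            amplitude_to_stiffness(curve, A0=0.0)

    def test_roundtrip_against_offresonance_forward_model(self):
        # the conversion is the exact inverse of the lock-in working relation
        ki = np.linspace(0.0, 160.0, 50)
        R = offresonance_amplitude(ki, C)
        out = amplitude_to_stiffness(make_osc(R), A0=C.drive_amplitude_A0,
                                     deflection="none")
        assert np.allclose(out.stiffness_ki, ki, rtol=1e-12, atol=1e-9)

    def test_full_sho_forward_model_residual_is_first_order(self):
        # generating the amplitude from the full SHO and inverting with the
        # linearized relation leaves a relative error ≈ ki/kc (plus a ~1 pN/nm
        # floor from the residual drag/inertia terms) — the accuracy budget
        # of the off-resonance approximation
        for r in [0.05, 0.1, 0.2]:
            ki = r * C.kc
            A, _ = sho_steady_state(ki, 0.0, C)
            out = amplitude_to_stiffness(make_osc(np.full(12, A)),
                                         A0=C.drive_amplitude_A0, deflection="none")
            rel_err = abs(out.stiffness_ki[0] - ki) / ki
            assert rel_err == pytest.approx(r / (1 + r), abs=0.03)

    def test_conversion_bounded_below_kc(self):
        rng = np.random.default_rng(7)
        R = np.clip(rng.normal(0.45, 0.03, 200), 0.05, None)
        out = amplitude_to_stiffness(make_osc(R), A0=0.5)
        assert np.all(out.stiffness_ki >= 0.0)
        assert np.all(out.stiffness_ki < C.kc)

    def test_integrated_deflection_correction(self):
        # constant ki over a span: deflection = force/kc accumulates linearly
        D = np.linspace(0.0, 10.0, 101)
        ki = 80.0
        R = np.full_like(D, offresonance_amplitude(ki, C))
        curve = OscillatoryCurve(D, R, np.zeros_like(D), C)
        out = amplitude_to_stiffness(curve, A0=C.drive_amplitude_A0)
        series = ki * C.kc / (ki + C.kc)
        expect = D - series * D / C.kc
        assert np.allclose(out.extension_x, expect, rtol=1e-9)


class TestPhaseValidity:
    def test_zero_phase_passes(self):
        ok, diag = phase_validity_check(make_osc(np.full(50, 0.5)))
        assert ok and diag["median_abs_phase"] == 0.0

    def test_resonant_phase_fails(self):
        c = CantileverParams(drive_freq=13e3, quality_factor=2.0)
        _, phase = sho_steady_state(0.0, 0.0, c)
        curve = make_osc(np.full(50, 0.5), phase=np.full(50, phase), c=c)
        ok, diag = phase_validity_check(curve, tol_degrees=5.0)
        assert not ok and diag["median_abs_phase"] > 80.0

    def test_small_gaussian_phase_noise_passes(self):
        rng = np.random.default_rng(11)
        curve = make_osc(np.full(500, 0.5), phase=rng.normal(0, 1.0, 500))
        ok, _ = phase_validity_check(curve, tol_degrees=5.0)
        assert ok


class TestContainers:
    def test_mismatched_arrays_rejected(self):
        with pytest.raises(ValueError):
            OscillatoryCurve(np.arange(3.0), np.arange(4.0), np.arange(3.0), C)
        with pytest.raises(ValueError):
            StiffnessCurve(np.arange(3.0), np.arange(4.0))

    def test_effective_mass_and_drag_derived(self):
        m = C.kc / (2 * np.pi * C.f0) ** 2
        assert C.effective_mass == pytest.approx(m)
        assert C.gamma_c == pytest.approx(np.sqrt(m * C.kc) / C.quality_factor)
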