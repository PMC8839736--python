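"""Synthetic instrument: determinism, noiseless limits, presets, file format."""

import dataclasses
import io

import numpy as np
import pytest

from oscelast.cantilever import amplitude_to_stiffness
from oscelast.polymer import WLCParams, wlc_force, wlc_stiffness
from oscelast.synthetic import (
    ForceCurve,
    GenerationError,
    ParseError,
    Preset,
    builtin_presets,
    generate_oscillatory_curve,
    generate_pulling_curve,
    read_curve,
    read_preset,
    write_curve,
    write_preset,
)


@pytest.fixture(scope="module")
def presets():
    return builtin_presets()


def noiseless(p: Preset, **overrides) -> Preset:
    return dataclasses.replace(
        p, force_sigma=0.0, amplitude_sigma=0.0, phase_sigma=0.0,
        contour_shape=0.0, **overrides
    )


class TestPullingGeneration:
    def test_identical_seed_bit_identical(self, presets):
        a = generate_pulling_curve(presets["peg_water_pull"], 3)
        b = generate_pulling_curve(presets["peg_water_pull"], 3)
        assert np.array_equal(a.force, b.force)
        assert np.array_equal(a.displacement_D, b.displacement_D)

    def test_different_index_different_noise(self, presets):
        a = generate_pulling_curve(presets["peg_water_pull"], 0)
        b = generate_pulling_curve(presets["peg_water_pull"], 1)
        assert not np.array_equal(a.force, b.force)

    def test_noiseless_wlc_matches_model_exactly(self, presets):
        p = noiseless(presets["ps_water_pull"])
        curve = generate_pulling_curve(p, 0)
        i0, i1 = curve.metadata["contact_index"], curve.metadata["rupture_index"]
        x = curve.extension[i0 + 1 : i1 + 1]
        F = curve.force[i0 + 1 : i1 + 1]
        model = WLCParams(lp=p.lp, L=curve.metadata["L_true"])
        assert np.allclose(F, wlc_force(x, model), rtol=1e-9, atol=1e-8)

    def test_layout_has_contact_stretch_and_tail(self, presets):
        p = noiseless(presets["ps_water_pull"])
        curve = generate_pulling_curve(p, 0)
        i0, i1 = curve.metadata["contact_index"], curve.metadata["rupture_index"]
        assert np.allclose(curve.force[: i0 + 1], 0.0)
        assert np.allclose(curve.force[i1 + 1 :], 0.0)
        assert curve.force[i1] == pytest.approx(p.rupture_force, rel=0.05)
        assert np.all(np.diff(curve.displacement_D) > 0)

    def test_contour_length_heterogeneity(self, presets):
        p = presets["peg_water_pull"]
        Ls = [
            generate_pulling_curve(p, i).metadata["L_true"]
            for i in range(p.n_curves)
        ]
        assert len(set(Ls)) == p.n_curves  # every draw distinct
        assert np.std(np.log(Ls)) == pytest.approx(p.contour_shape, rel=0.5)

    def test_unreachable_rupture_raises(self, presets):
        p = dataclasses.replace(presets["ps_water_pull"], rupture_force=1e30)
        with pytest.raises(GenerationError):
            generate_pulling_curve(p, 0)


class TestOscillatoryGeneration:
    def test_noiseless_roundtrip_recovers_model_stiffness(self, presets):
        p = noiseless(presets["ps_water_osc"])
        curve = generate_oscillatory_curve(p, 0)
        out = amplitude_to_stiffness(curve)
        i0, i1 = curve.metadata["contact_index"], curve.metadata["rupture_index"]
        x = out.extension_x[i0 + 1 : i1 + 1]
        ki = out.stiffness_ki[i0 + 1 : i1 + 1]
        model = WLCParams(lp=p.lp, L=curve.metadata["L_true"])
        assert np.allclose(ki, wlc_stiffness(x, model), rtol=1e-6)

    def test_amplitude_returns_to_A0_after_rupture(self, presets):
        p = presets["peg_water_osc"]
        curve = generate_oscillatory_curve(p, 0)
        i1 = curve.metadata["rupture_index"]
        tail = curve.amplitude_R[i1 + 1 :]
        A0 = p.cantilever.drive_amplitude_A0
        assert np.mean(tail) == pytest.approx(A0, abs=3 * p.amplitude_sigma)

    def test_phase_trace_near_zero(self, presets):
        from oscelast.cantilever import phase_validity_check

        curve = generate_oscillatory_curve(presets["peg_water_osc"], 0)
        ok, diag = phase_validity_check(curve, tol_degrees=5.0)
        assert ok
        assert abs(np.mean(curve.phase_delta)) < 0.2

    def test_seed_determinism(self, presets):
        a = generate_oscillatory_curve(presets["ps_urea_osc"], 5)
        b = generate_oscillatory_curve(presets["ps_urea_osc"], 5)
        assert np.array_equal(a.amplitude_R, b.amplitude_R)


class TestPresets:
    def test_study_conditions(self, presets):
        assert presets["peg_water_osc"].n_curves == 25
        assert presets["ps_water_osc"].n_curves == 26
        assert presets["ps_urea_osc"].n_curves == 14
        assert presets["peg_water_osc"].lp == 0.5
        assert presets["peg_water_pull"].lp == 0.12
        assert presets["ps_water_osc"].lp == 0.26
        assert presets["ps_water_pull"].lp == 0.23
        assert presets["ps_urea_osc"].lp == 0.88
        fjc = presets["peg_water_fjc2"].fjc_params
        assert fjc.b_kuhn == 0.24 and fjc.l_trans == 0.256

    def test_probe_constants(self, presets):
        for p in presets.values():
            assert p.cantilever.kc == 800.0
            assert p.cantilever.f0 == 13e3
            assert p.cantilever.drive_freq == 500.0
            assert p.env.temperature == pytest.approx(296.15)

    def test_every_preset_roundtrips_through_config_file(self, presets, tmp_path):
        for name, p in presets.items():
            path = tmp_path / f"{name}.conf"
            write_preset(p, path)
            assert read_preset(path) == p

    def test_contour_draws_follow_lognormal(self, presets):
        from scipy import stats

        p = dataclasses.replace(presets["peg_water_osc"], n_curves=1000)
        rng = np.random.default_rng(np.random.SeedSequence([p.seed, 0]))
        draws = p.contour_median * np.exp(p.contour_shape * rng.standard_normal(1000))
        ks = stats.kstest(
            np.log(draws / p.contour_median) / p.contour_shape, "norm"
        )
        assert ks.pvalue > 0.01


class TestCurveFileFormat:
    def test_force_curve_lossless_roundtrip(self, presets, tmp_path):
        curve = generate_pulling_curve(presets["peg_water_pull"], 0)
        path = tmp_path / "c.tsv"
        write_curve(curve, path)
        back = read_curve(path)
        assert np.array_equal(back.force, curve.force)
        assert np.array_equal(back.displacement_D, curve.displacement_D)
        assert back.cantilever == curve.cantilever
        assert back.metadata["L_true"] == curve.metadata["L_true"]

    def test_oscillatory_curve_lossless_roundtrip(self, presets, tmp_path):
        curve = generate_oscillatory_curve(presets["ps_urea_osc"], 2)
        path = tmp_path / "o.tsv"
        write_curve(curve, path)
        back = read_curve(path)
        assert np.array_equal(back.amplitude_R, curve.amplitude_R)
        assert np.array_equal(back.phase_delta, curve.phase_delta)

    def test_missing_kc_key_is_parse_error(self):
        text = (
            "# oscelast-curve\t1\n# type\tforce\n# f0\t13000.0\n"
            "# drive_freq\t500.0\n# A0\t0.5\n# velocity\t80.0\n"
            "# temperature\t296.15\n# columns\tdisplacement_D\tforce\n"
            "0.0\t0.0\n1.0\t2.0\n"
        )
        with pytest.raises(ParseError, match="kc"):
            read_curve(io.StringIO(text))

    def test_malformed_header_names_line(self):
        text = "# oscelast-curve\t1\n# badline\n"
        with pytest.raises(ParseError, match="line 2"):
            read_curve(io.StringIO(text))

    def test_hand_written_three_point_file(self):
        text = (
            "# oscelast-curve\t1\n# type\tforce\n# kc\t800.0\n# f0\t13000.0\n"
            "# quality_factor\t2.0\n# drive_freq\t500.0\n# A0\t0.5\n"
            "# velocity\t80.0\n# temperature\t296.15\n# meta:L_true\t30.0\n"
            "# columns\tdisplacement_D\tforce\n"
            "0.0\t0.0\n0.5\t5.0\n1.0\t12.5\n"
        )
        curve = read_curve(io.StringIO(text))
        assert isinstance(curve, ForceCurve)
        assert np.array_equal(curve.displacement_D, [0.0, 0.5, 1.0])
        assert np.array_equal(curve.force, [0.0, 5.0, 12.5])
        assert curve.metadata["L_true"] == 30.0
        assert curve.cantilever.kc == 800.0
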