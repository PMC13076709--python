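import numpy as np
import pytest

from adcphantom import (
    NominalADCModel,
    StudyDesign,
    VialSpec,
    build_phantom_layout,
    default_protocol,
    emulate_dl_reconstruction,
    nominal_adc,
    simulate_dwi_series,
    simulate_study,
)
from adcphantom.phantom import GeometryError, PVP_FRACTIONS


class TestLayout:
    def test_ffov_has_13_vials_6_concentrations(self):
        layout = build_phantom_layout("ffov")
        assert len(layout.vials) == 13
        assert len({v.pvp_fraction for v in layout.vials}) == 6

    def test_rfov_has_11_vials(self):
        layout = build_phantom_layout("rfov")
        assert len(layout.vials) == 11

    def test_single_vial_override(self):
        v = VialSpec(label="PVP0_C", pvp_fraction=0.0, ring="central", center_xy=(0, 0))
        layout = build_phantom_layout("ffov", vials=[v])
        assert layout.vials == (v,)

    def test_labels_follow_naming_scheme(self):
        layout = build_phantom_layout("ffov")
        rings = {"central": "C", "inner": "I", "outer": "O"}
        for v in layout.vials:
            pct = int(round(v.pvp_fraction * 100))
            assert v.label == f"PVP{pct}_{rings[v.ring]}"

    def test_overlapping_vials_rejected(self):
        a = VialSpec(label="a", pvp_fraction=0.0, ring="inner", center_xy=(0, 0))
        b = VialSpec(label="b", pvp_fraction=0.1, ring="inner", center_xy=(5, 0))
        with pytest.raises(GeometryError):
            build_phantom_layout("ffov", vials=[a, b])

    def test_duplicate_labels_rejected(self):
        a = VialSpec(label="x", pvp_fraction=0.0, ring="inner", center_xy=(0, 0))
        b = VialSpec(label="x", pvp_fraction=0.1, ring="inner", center_xy=(40, 0))
        with pytest.raises(ValueError):
            build_phantom_layout("ffov", vials=[a, b])

    def test_deterministic(self):
        assert build_phantom_layout("ffov") == build_phantom_layout("fFOV")


class TestNominalADC:
    def test_constant_polynomial(self):
        m = NominalADCModel(coefficients={0.0: (1.0e-3, 0.0, 0.0)})
        assert nominal_adc(m, 0.0, 22.0) == pytest.approx(1.0e-3, rel=1e-15)

    def test_linear_term_only(self):
        m = NominalADCModel(coefficients={0.0: (0.0, 1.0e-4, 0.0)})
        assert nominal_adc(m, 0.0, 20.0) == pytest.approx(2.0e-3, rel=1e-15)

    def test_default_model_anchors(self, model):
        assert nominal_adc(model, 0.0, 20.0) == pytest.approx(2.0e-3, abs=1e-6)
        assert nominal_adc(model, 0.5, 20.0) == pytest.approx(0.3e-3, abs=1e-6)

    def test_temperature_out_of_range(self, model):
        with pytest.raises(ValueError):
            nominal_adc(model, 0.0, 30.0)

    def test_unknown_concentration(self, model):
        with pytest.raises(KeyError):
            nominal_adc(model, 0.25, 20.0)

    @pytest.mark.parametrize("temp", [15.0, 18.0, 21.0, 24.0])
    def test_monotone_decreasing_in_concentration(self, model, temp):
        values = [nominal_adc(model, f, temp) for f in PVP_FRACTIONS]
        assert all(a > b > 0 for a, b in zip(values, values[1:]))


class TestSimulateSeries:
    def test_noiseless_is_exact_decay(self, noiseless_stack):
        proto = noiseless_stack.protocol
        b = np.asarray(proto.b_values)
        s0 = noiseless_stack.data[..., 0]
        nz = s0 > 0
        for bi in range(1, len(b)):
            adc_implied = -np.log(noiseless_stack.data[..., bi][nz] / s0[nz]) / b[bi]
            # every voxel's series follows a single mono-exponential
            adc0 = -np.log(noiseless_stack.data[..., 1][nz] / s0[nz]) / b[1]
            np.testing.assert_allclose(adc_implied, adc0, rtol=1e-9)

    def test_rayleigh_mean_in_signal_free_region(self, ffov_layout, model):
        from dataclasses import replace

        proto = default_protocol("ffov", matrix=128, n_slices=4, noise_sigma=10.0)
        proto = replace(proto, averages_per_b=(1, 1, 1, 1, 1))
        stack = simulate_dwi_series(ffov_layout, proto, model, 21.0, seed=3)
        xx, yy = np.meshgrid(*(2 * [(np.arange(128) + 0.5) * proto.pixel_mm - 128 * proto.pixel_mm / 2]), indexing="ij")
        outside = (xx**2 + yy**2) > (ffov_layout.bath_radius_mm + 2) ** 2
        vals = stack.data[..., 0][outside]
        assert vals.size >= 10_000
        expected = 10.0 * np.sqrt(np.pi / 2)
        assert vals.mean() == pytest.approx(expected, rel=0.02)

    def test_seeding_contract(self, ffov_layout, small_protocol, model):
        a = simulate_dwi_series(ffov_layout, small_protocol, model, 21.0, seed=11)
        b = simulate_dwi_series(ffov_layout, small_protocol, model, 21.0, seed=11)
        c = simulate_dwi_series(ffov_layout, small_protocol, model, 21.0, seed=12)
        np.testing.assert_array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            default_protocol("ffov", noise_sigma=-1.0)

    def test_rician_floor_at_high_b(self, ffov_layout, model):
        # non-negative magnitude bias in the free-water vial at b=2000
        proto = default_protocol("ffov", matrix=128, n_slices=4, noise_sigma=4.0)
        stack = simulate_dwi_series(ffov_layout, proto, model, 21.0, seed=7)
        n = proto.matrix
        coords = (np.arange(n) + 0.5) * proto.pixel_mm - n * proto.pixel_mm / 2
        xx, yy = np.meshgrid(coords, coords, indexing="ij")
        inside2d = (xx**2 + yy**2) < (ffov_layout.vial("PVP0_C").radius_mm - 1) ** 2
        sel = np.broadcast_to(inside2d[:, :, None], proto.shape[:3])
        noisy = stack.data[..., -1][sel]
        truth = proto.s0 * np.exp(-2000.0 * stack.ground_truth["PVP0_C"])
        assert noisy.size >= 1e3
        assert noisy.mean() >= truth


class TestDenoisingEmulation:
    def test_off_is_identity(self, noisy_stack):
        out = emulate_dl_reconstruction(noisy_stack, "OFF")
        np.testing.assert_array_equal(out.data, noisy_stack.data)

    def test_uniform_image_unchanged_interior(self, small_protocol):
        from adcphantom import DWIStack

        data = np.full(small_protocol.shape, 50.0)
        stack = DWIStack(data=data, protocol=small_protocol)
        out = emulate_dl_reconstruction(stack, "HIGH")
        inner = out.data[10:-10, 10:-10]
        np.testing.assert_allclose(inner, 50.0, atol=1e-10)

    def test_unknown_level_rejected(self, noisy_stack):
        with pytest.raises(ValueError):
            emulate_dl_reconstruction(noisy_stack, "EXTREME")

    def test_variance_shrinks_low_to_high(self, ffov_layout, model):
        # deep vial interior (>4 kernel sigmas from the wall) so the estimate
        # sees smoothed noise only, not the deterministic wall gradient
        proto = default_protocol("ffov", matrix=128, n_slices=10, noise_sigma=4.0)
        raw = simulate_dwi_series(ffov_layout, proto, model, 21.0, seed=5)
        low = emulate_dl_reconstruction(raw, "LOW")
        high = emulate_dl_reconstruction(raw, "HIGH")
        n = proto.matrix
        coords = (np.arange(n) + 0.5) * proto.pixel_mm - n * proto.pixel_mm / 2
        xx, yy = np.meshgrid(coords, coords, indexing="ij")
        inside2d = (xx**2 + yy**2) < (ffov_layout.vial("PVP0_C").radius_mm - 5.0) ** 2
        sel = np.broadcast_to(inside2d[:, :, None], proto.shape[:3])
        assert sel.sum() >= 1e3
        v_low = low.data[..., 0][sel].var()
        v_high = high.data[..., 0][sel].var()
        assert v_high < v_low

    def test_mean_preserved_in_vial_interior(self, ffov_layout, noisy_stack):
        high = emulate_dl_reconstruction(noisy_stack, "HIGH")
        proto = noisy_stack.protocol
        n = proto.matrix
        coords = (np.arange(n) + 0.5) * proto.pixel_mm - n * proto.pixel_mm / 2
        xx, yy = np.meshgrid(coords, coords, indexing="ij")
        # stay >3 kernel widths (3 * 1.2 mm) away from the vial wall
        inside2d = (xx**2 + yy**2) < (ffov_layout.vial("PVP0_C").radius_mm - 4.0) ** 2
        sel = np.broadcast_to(inside2d[:, :, None], proto.shape[:3])
        m0 = noisy_stack.data[..., 0][sel].mean()
        m1 = high.data[..., 0][sel].mean()
        assert abs(m1 - m0) / m0 < 1e-3


@pytest.fixture(scope="module")
def tiny_design():
    return StudyDesign(n_repeats=2, sessions=(("S1", 21.0), ("S2", 22.0)), base_seed=5)


@pytest.fixture(scope="module")
def tiny_study(tiny_design, small_protocol):
    return simulate_study(tiny_design, "ffov", protocol=small_protocol)


class TestSimulateStudy:
    def test_cardinality(self, tiny_study):
        assert len(tiny_study) == 2 * 2 * 4

    def test_repeats_differ_levels_share_raw(self, tiny_study):
        a = tiny_study[("S1", "r1", "OFF")].data
        b = tiny_study[("S1", "r2", "OFF")].data
        assert not np.array_equal(a, b)
        # OFF and HIGH of one repeat derive from the identical raw realisation:
        # smoothing HIGH's pre-image (the OFF data) reproduces HIGH exactly
        from adcphantom import emulate_dl_reconstruction

        high = tiny_study[("S1", "r1", "HIGH")]
        re_high = emulate_dl_reconstruction(tiny_study[("S1", "r1", "OFF")], "HIGH")
        np.testing.assert_array_equal(high.data, re_high.data)

    def test_rerun_bit_identical(self, tiny_design, small_protocol, tiny_study):
        again = simulate_study(tiny_design, "ffov", protocol=small_protocol)
        for key, stack in tiny_study.items():
            np.testing.assert_array_equal(stack.data, again[key].data)

    def test_design_validation(self):
        with pytest.raises(ValueError):
            StudyDesign(n_repeats=1)
        with pytest.raises(ValueError):
            StudyDesign(levels=(("OFF", 0.0), ("LOW", 0.8), ("MEDIUM", 0.4), ("HIGH", 1.2)))
        with pytest.raises(ValueError):
            StudyDesign(levels=(("OFF", 0.1), ("LOW", 0.4), ("MEDIUM", 0.8), ("HIGH", 1.2)))
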