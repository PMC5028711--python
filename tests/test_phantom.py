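"""Phantom geometry, forward optics and rendering."""

import numpy as np
import pytest

from asoct.core import RefractiveModel
from asoct.normative import LOCATIONS_UM, location_means, location_sds
from asoct.phantom import (
    PhantomSpec,
    forward_distort,
    make_phantom_spec,
    render_bscan,
    true_thickness_profile,
)


class TestMakePhantomSpec:
    def test_deterministic_for_a_seed(self):
        a = make_phantom_spec(1, "nasal")
        b = make_phantom_spec(1, "nasal")
        np.testing.assert_array_equal(a.psb_knots, b.psb_knots)
        np.testing.assert_array_equal(a.acb_knots, b.acb_knots)
        assert a.spur_x == b.spur_x

    def test_seed_changes_geometry(self):
        a = make_phantom_spec(1, "nasal")
        b = make_phantom_spec(2, "nasal")
        assert not np.allclose(a.psb_knots, b.psb_knots)

    def test_unknown_override_rejected_by_name(self):
        with pytest.raises(ValueError, match="band_thicknes"):
            make_phantom_spec(1, "nasal", {"band_thicknes": 3})

    @pytest.mark.parametrize("meridian", ["nasal", "temporal"])
    def test_spur_thickness_within_normative_window(self, meridian):
        """Sampled geometry stays within +/-3 SD of the normative cell
        at the spur (e.g. nasal sclera 606 +/- 42 um)."""
        for seed in range(10):
            spec = make_phantom_spec(seed, meridian)
            prof = true_thickness_profile(spec)
            m = location_means("sclera", meridian)[0]
            s = location_sds("sclera", meridian)[0]
            assert m - 3 * s <= prof.scleral_um[0] <= m + 3 * s

    def test_profile_shape_matches_anatomy(self):
        """Scleral maximum and conjunctival minimum at the spur."""
        for seed in range(5):
            prof = true_thickness_profile(make_phantom_spec(seed, "temporal"))
            assert prof.scleral_um[0] == prof.scleral_um.max()
            assert prof.conjunctival_um[0] == prof.conjunctival_um.min()

    def test_ordering_invariant_enforced(self, flat_spec_factory):
        with pytest.raises(ValueError, match="ordering"):
            flat_spec_factory(acb=500.0, asb=400.0)


class TestTrueThicknessProfile:
    def test_flat_slabs_translation_invariant(self, flat_spec_factory):
        spec = flat_spec_factory(acb=300, asb=520, psb=1020)
        prof = true_thickness_profile(spec)
        np.testing.assert_allclose(prof.conjunctival_um, 220.0, atol=1e-9)
        np.testing.assert_allclose(prof.scleral_um, 500.0, atol=1e-9)

    def test_matches_dense_polyline_oracle(self, nasal_spec):
        """Arc-location thickness equals an independent brute-force
        polyline computation at 0.1 um."""
        spec = nasal_spec
        xs = np.arange(spec.spur_x, 16000.0, 0.25)
        zs = spec.psb_curve(xs)
        arc = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(xs), np.diff(zs)))])
        x_loc = np.interp(LOCATIONS_UM, arc, xs)
        expect_scl = spec.psb_curve(x_loc) - spec.asb_curve(x_loc)
        expect_conj = spec.asb_curve(x_loc) - spec.acb_curve(x_loc)
        prof = true_thickness_profile(spec)
        np.testing.assert_allclose(prof.scleral_um, expect_scl, atol=0.1)
        np.testing.assert_allclose(prof.conjunctival_um, expect_conj, atol=0.1)

    def test_axial_equals_normal_on_flat_slabs(self, flat_spec_factory):
        spec = flat_spec_factory()
        ax = true_thickness_profile(spec, metric="axial")
        nm = true_thickness_profile(spec, metric="normal")
        np.testing.assert_allclose(ax.scleral_um, nm.scleral_um, atol=1e-6)

    def test_distance_beyond_arc_raises(self, nasal_spec):
        with pytest.raises(ValueError, match="beyond available arc"):
            true_thickness_profile(nasal_spec, distances=(0.0, 20000.0))


class TestForwardDistort:
    def test_flat_conjunctiva_index_scaling(self, flat_spec_factory, device):
        """Horizontal interfaces: image separation = physical x n/n_dev."""
        spec = flat_spec_factory(acb=300.0, asb=438.0, psb=1143.0)
        tr = forward_distort(spec, device)
        conj_sep = tr["ASB"].depth - tr["ACB"].depth
        scl_sep = tr["PSB"].depth - tr["ASB"].depth
        np.testing.assert_allclose(conj_sep, 138.0 * 1.38 / 1.40, atol=1e-6)
        np.testing.assert_allclose(scl_sep, 705.0 * 1.41 / 1.40, atol=1e-6)

    def test_tilted_acb_matches_hand_ray_trace(self, flat_spec_factory, device):
        """ACB tilted 10 deg over flat deeper slabs: closed-form
        trigonometric solution to 0.01 um."""
        theta = np.radians(10.0)
        knots = np.linspace(0.0, 4000.0, 9)
        spec = PhantomSpec(
            seed=0, meridian="nasal", knots_x=knots,
            acb_knots=300.0 + np.tan(theta) * knots,
            asb_knots=np.full_like(knots, 1500.0),
            psb_knots=np.full_like(knots, 2200.0),
            spur_x=2500.0,
        )
        tr = forward_distort(spec, device, columns=np.arange(40, 340))
        x0 = tr["ACB"].x
        z_acb = 300.0 + np.tan(theta) * x0
        t1 = np.arcsin(np.sin(theta) / 1.38)       # angle from ACB normal
        a1 = theta - t1                            # refracted, from vertical
        s1 = (1500.0 - z_acb) / np.cos(a1)
        a2 = np.arcsin(1.38 * np.sin(a1) / 1.41)   # flat ASB: normal vertical
        s2 = (2200.0 - 1500.0) / np.cos(a2)
        asb_img = z_acb + 1.38 * s1 / 1.40
        psb_img = z_acb + (1.38 * s1 + 1.41 * s2) / 1.40
        np.testing.assert_allclose(tr["ACB"].depth, z_acb, atol=0.01)
        np.testing.assert_allclose(tr["ASB"].depth, asb_img, atol=0.01)
        np.testing.assert_allclose(tr["PSB"].depth, psb_img, atol=0.01)

    def test_uniform_indices_give_pure_geometry(self, nasal_spec, device):
        """With every index equal to n_device the forward model reduces
        to geometric imaging: image depth = physical depth."""
        spec = nasal_spec
        uniform = RefractiveModel(n_air=1.40, n_conjunctiva=1.40,
                                  n_sclera=1.40, n_device=1.40)
        spec2 = PhantomSpec(
            seed=spec.seed, meridian=spec.meridian, knots_x=spec.knots_x,
            acb_knots=spec.acb_knots, asb_knots=spec.asb_knots,
            psb_knots=spec.psb_knots, spur_x=spec.spur_x,
            refractive_model=uniform,
        )
        tr = forward_distort(spec2, device)
        for name, curve in (("ACB", spec.acb_curve), ("ASB", spec.asb_curve),
                            ("PSB", spec.psb_curve)):
            np.testing.assert_allclose(tr[name].depth, curve(tr[name].x),
                                       atol=1e-6)


class TestRenderBScan:
    def test_same_seed_bit_identical(self, nasal_spec, device):
        a, _ = render_bscan(nasal_spec, device)
        b, _ = render_bscan(nasal_spec, device)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_noise_free_steps_at_distorted_boundaries(self, flat_spec_factory,
                                                      device):
        spec = flat_spec_factory(speckle_sigma=0.0)
        image, truth = render_bscan(spec, device)
        grad = np.gradient(image.pixels, axis=0)
        # strongest dark-to-light edge per column should sit on the ACB
        rows = np.argmax(grad, axis=0) * device.axial_scale
        np.testing.assert_allclose(rows, truth["ACB"].depth,
                                   atol=device.axial_scale)

    def test_frame_averaging_raises_quality_index(self, nasal_spec, device):
        few = PhantomSpec(
            seed=nasal_spec.seed, meridian="nasal", knots_x=nasal_spec.knots_x,
            acb_knots=nasal_spec.acb_knots, asb_knots=nasal_spec.asb_knots,
            psb_knots=nasal_spec.psb_knots, spur_x=nasal_spec.spur_x,
            n_frame_averages=1,
        )
        img_many, _ = render_bscan(nasal_spec, device)
        img_few, _ = render_bscan(few, device)
        assert img_many.quality_index > img_few.quality_index

    def test_spec_json_roundtrip(self, nasal_spec):
        restored = PhantomSpec.from_json(nasal_spec.to_json())
        np.testing.assert_allclose(restored.psb_knots, nasal_spec.psb_knots)
        assert restored.refractive_model == nasal_spec.refractive_model
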