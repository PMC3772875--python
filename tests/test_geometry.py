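"""Geometry module: lumen surfaces, stenosis warp, waveform synthesis."""

import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

from graftflow import geometry as geo


# ---------------------------------------------------------------------------
# waveform
# ---------------------------------------------------------------------------

class TestWaveform:
    def test_constant_when_amplitudes_zero(self):
        w = geo.synthesize_inlet_waveform(10.0, 0.8, (), ())
        assert np.allclose(w.sample_velocities, 10.0)
        st = geo.waveform_stats(w)
        assert st == {"mean": pytest.approx(10.0), "peak": pytest.approx(10.0),
                      "peak_to_mean": pytest.approx(1.0)}

    def test_single_harmonic_peak_to_mean(self):
        w = geo.synthesize_inlet_waveform(10.0, 0.8, (0.5,), (0.0,),
                                          n_samples=512)
        st = geo.waveform_stats(w)
        assert st["peak_to_mean"] == pytest.approx(1.5, rel=1e-4)

    def test_default_stats_match_dense_evaluation(self):
        w = geo.default_waveform()
        st = geo.waveform_stats(w)
        dense = geo.synthesize_inlet_waveform(n_samples=4096)
        st_dense = geo.waveform_stats(dense)
        assert st["mean"] == pytest.approx(st_dense["mean"], rel=1e-6)
        assert st["peak"] == pytest.approx(st_dense["peak"], rel=1e-3)

    def test_default_period_is_121_steps_of_reference_dt(self):
        w = geo.default_waveform()
        assert w.period == pytest.approx(121 * 0.00695)

    def test_mean_invariant_and_nonnegativity(self):
        w = geo.default_waveform()
        assert np.all(w.sample_velocities >= 0.0)
        assert abs(w.sample_velocities.mean() - w.mean_velocity) \
            <= 1e-10 * w.mean_velocity

    def test_negative_excursion_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            geo.synthesize_inlet_waveform(10.0, 0.8, (1.5,), (math.pi,))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            geo.synthesize_inlet_waveform(n_samples=8)

    def test_velocity_at_matches_samples(self):
        w = geo.default_waveform()
        vals = w.velocity_at(w.sample_times)
        assert np.allclose(vals, w.sample_velocities, atol=1e-12)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

class TestSpecs:
    def test_graft_radius_from_csa_ratio(self):
        spec = geo.AnastomosisSpec(host_radius=0.15, csa_ratio=0.5)
        assert spec.graft_radius == pytest.approx(0.15 * math.sqrt(0.5))

    @pytest.mark.parametrize("kw", [
        {"host_radius": -0.1}, {"csa_ratio": 0.0},
        {"graft_angle_deg": 0.0}, {"graft_angle_deg": 120.0},
        {"graft_length": 0.1}, {"host_distal_length": 0.2},
    ])
    def test_invalid_specs_rejected(self, kw):
        with pytest.raises(ValueError):
            geo.AnastomosisSpec(**kw)

    def test_stenosis_spec_bounds(self):
        with pytest.raises(ValueError):
            geo.StenosisSpec(100.0)
        with pytest.raises(ValueError):
            geo.StenosisSpec(50.0, axial_extent=0.0)

    def test_fluid_properties(self):
        f = geo.default_fluid()
        assert (f.mu, f.rho) == (0.04, 1.06)
        with pytest.raises(ValueError):
            geo.FluidProperties(mu=-1.0)


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------

class TestTubeSurface:
    def test_watertight_and_areas(self, tube_surface):
        s = tube_surface
        assert s.is_watertight()
        # faceted cylinder areas approach the analytic ones from below
        assert s.patch_area(geo.PATCH_WALL) == pytest.approx(
            2 * math.pi * 0.15 * 1.5, rel=0.03)
        assert s.patch_area(geo.PATCH_INLET) == pytest.approx(
            math.pi * 0.15 ** 2, rel=0.03)

    def test_resolution_guard(self):
        with pytest.raises(ValueError):
            geo.build_tube_surface(0.15, 1.0, 0.10)


class TestAnastomosisSurface:
    def test_perpendicular_equal_radii_orifice(self):
        spec = geo.AnastomosisSpec(graft_angle_deg=90.0, csa_ratio=1.0)
        surf = geo.build_anastomosis_surface(spec, 0.04)
        assert surf.is_watertight()
        curve = surf.metadata["orifice_curve"]
        # orifice of perpendicular equal cylinders projects to a circle of
        # the common radius in the graft section plane (here x = const)
        proj = np.hypot(curve[:, 1], curve[:, 2])
        assert np.allclose(proj, 0.15, atol=1e-9)
        rho = np.hypot(curve[:, 0], curve[:, 1])
        assert np.allclose(rho, 0.15, atol=1e-9)

    def test_volume_against_voxel_oracle(self):
        spec = geo.default_anastomosis_spec()
        surf = geo.build_anastomosis_surface(spec, 0.04)
        rng = np.random.default_rng(0)
        lo = surf.vertices.min(axis=0)
        hi = surf.vertices.max(axis=0)
        pts = rng.uniform(lo, hi, (200_000, 3))
        ra = rg = 0.15
        a_g = spec.graft_axis
        in_host = (np.hypot(pts[:, 0], pts[:, 1]) <= ra) \
            & (pts[:, 2] >= -spec.host_proximal_stub_length) \
            & (pts[:, 2] <= spec.host_distal_length)
        s = pts @ a_g
        d = np.linalg.norm(pts - np.outer(s, a_g), axis=1)
        in_graft = (d <= rg) & (s >= 0) & (s <= spec.graft_length)
        vol_mc = (in_host | in_graft).mean() * np.prod(hi - lo)
        assert surf.enclosed_volume() == pytest.approx(vol_mc, rel=0.02)

    def test_inlet_outlet_area_ratio_equals_csa_ratio(self):
        spec = geo.AnastomosisSpec(csa_ratio=0.5)
        surf = geo.build_anastomosis_surface(spec, 0.04)
        ratio = surf.patch_area(geo.PATCH_INLET) \
            / surf.patch_area(geo.PATCH_OUTLET)
        assert ratio == pytest.approx(0.5, rel=0.02)

    def test_mirror_symmetry(self, anastomosis_surface):
        v = anastomosis_surface.vertices
        mirrored = v * np.array([1.0, -1.0, 1.0])
        d, _ = cKDTree(v).query(mirrored)
        assert d.max() < 0.04  # within mesh resolution

    def test_scale_covariance(self):
        a = geo.build_anastomosis_surface(geo.AnastomosisSpec(), 0.05)
        b = geo.build_anastomosis_surface(geo.AnastomosisSpec(
            host_radius=0.30, graft_length=1.4, host_distal_length=1.8,
            host_proximal_stub_length=1.2), 0.10)
        la = a.metadata["landmarks"]
        lb = b.metadata["landmarks"]
        for key in ("toe_artery", "heel", "floor_center"):
            assert np.allclose(2.0 * np.asarray(la[key]),
                               np.asarray(lb[key]), atol=1e-9)

    def test_self_intersecting_configuration_rejected(self):
        spec = geo.AnastomosisSpec(graft_angle_deg=5.0, graft_length=0.6)
        with pytest.raises(ValueError):
            geo.build_anastomosis_surface(spec, 0.04)


# ---------------------------------------------------------------------------
# stenosis
# ---------------------------------------------------------------------------

class TestStenosis:
    def test_zero_percent_is_identity(self, tube_surface):
        out = geo.apply_stenosis(tube_surface, None, geo.StenosisSpec(0.0))
        assert np.array_equal(out.vertices, tube_surface.vertices)

    def test_fifty_percent_throat_radius(self, tube_surface):
        sten = geo.StenosisSpec(50.0, axial_center=0.75, axial_extent=0.3)
        out = geo.apply_stenosis(tube_surface, None, sten)
        wall = np.unique(out.triangles[out.patch_tags == geo.PATCH_WALL])
        at_throat = wall[np.abs(out.vertices[wall, 2] - 0.75) < 1e-9]
        rho = np.hypot(out.vertices[at_throat, 0], out.vertices[at_throat, 1])
        assert rho == pytest.approx(0.15 / math.sqrt(2), rel=1e-9)

    @pytest.mark.parametrize("pct", [10, 20, 30, 43, 50, 60, 70, 80, 90])
    def test_measurement_round_trip(self, tube_surface, pct):
        sten = geo.StenosisSpec(float(pct), axial_center=0.75,
                                axial_extent=0.3)
        out = geo.apply_stenosis(tube_surface, None, sten)
        assert geo.measure_area_stenosis(out) == pytest.approx(pct, abs=1.0)

    def test_unstenosed_measures_zero(self, tube_surface):
        assert geo.measure_area_stenosis(tube_surface) == pytest.approx(
            0.0, abs=0.5)

    def test_throat_radius_maps_to_area_percent(self, tube_surface):
        # throat radius 0.774 r <-> 1 - 0.774^2 ~ 40% area stenosis
        pct = 100.0 * (1.0 - 0.774 ** 2)
        sten = geo.StenosisSpec(pct, axial_center=0.75, axial_extent=0.3)
        out = geo.apply_stenosis(tube_surface, None, sten)
        assert geo.measure_area_stenosis(out) == pytest.approx(40.0, abs=1.0)

    def test_band_overlapping_end_planes_rejected(self, tube_surface):
        with pytest.raises(ValueError, match="overlap"):
            geo.apply_stenosis(tube_surface, None,
                               geo.StenosisSpec(50.0, axial_center=0.05,
                                                axial_extent=0.3))

    def test_patches_untouched(self, tube_surface):
        sten = geo.StenosisSpec(50.0, axial_center=0.75, axial_extent=0.3)
        out = geo.apply_stenosis(tube_surface, None, sten)
        for tag in (geo.PATCH_INLET, geo.PATCH_OUTLET):
            ids = np.unique(out.triangles[out.patch_tags == tag])
            assert np.array_equal(out.vertices[ids],
                                  tube_surface.vertices[ids])
        assert out.is_watertight()

    def test_unwarp_inverts_warp(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform([-0.3, -0.3, 0.0], [0.3, 0.3, 1.5], (500, 3))
        sten = geo.StenosisSpec(60.0, axial_center=0.75, axial_extent=0.3)
        fwd = geo.stenosis_warp(pts, 0.15, sten)
        back = geo.stenosis_unwarp(fwd, 0.15, sten)
        assert np.allclose(back, pts, atol=1e-6)


class TestClassify:
    @pytest.mark.parametrize("pct,label", [
        (15.0, "small"), (0.0, "small"), (19.9, "small"),
        (20.0, "moderate_gap"), (39.9, "moderate_gap"),
        (40.0, "mild"), (50.0, "mild"), (60.0, "mild"),
        (60.1, "severe"), (99.0, "severe"),
    ])
    def test_severity_classes(self, pct, label):
        assert geo.classify_stenosis(pct) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            geo.classify_stenosis(100.0)
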