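"""Generator correctness: analytic fields, vortex rings, phantoms, cohorts."""

import numpy as np
import pytest

import flow4d as f4
from flow4d import GridSpec, PhantomSubject, VentricleMask
from flow4d.core import GeometryError, ResolutionError
from flow4d.phantom import (
    DEFAULT_DESIGN,
    GroupDesign,
    analytic_strain_sq,
    analytic_vorticity,
    gen_cohort,
    gen_vortex_ring_field,
    ring_unit_velocity,
    volume_waveform,
    wrap_aliased,
)


class TestAnalyticFields:
    def test_unknown_kind_lists_options(self, small_grid):
        with pytest.raises(ValueError, match="solid_body"):
            f4.gen_analytic_field("vortex_sheet", 1.0, small_grid)

    def test_steady_replication(self, small_grid):
        fld = f4.gen_analytic_field("shear", 2.0, small_grid)
        assert np.array_equal(fld.values[0], fld.values[-1])

    @pytest.mark.parametrize("kind", ["solid_body", "shear", "extensional"])
    def test_exact_linear_samples(self, kind, small_grid):
        """Linear fields are sampled exactly; closed forms are exact too."""
        a = 1.7
        fld = f4.gen_analytic_field(kind, a, small_grid)
        grad = f4.velocity_gradient(fld, None)
        w = f4.vorticity(grad)
        s2 = f4.strain_sq(grad)
        w_true = analytic_vorticity(kind, a, small_grid)
        s2_true = analytic_strain_sq(kind, a, small_grid)
        # centred and one-sided differences are exact for linear fields
        assert np.allclose(w[0], w_true, atol=1e-10)
        assert np.allclose(s2[0], s2_true, atol=1e-10)

    def test_solid_body_pure_rotation(self, small_grid):
        fld = f4.gen_analytic_field("solid_body", 1.0, small_grid)
        grad = f4.velocity_gradient(fld, None)
        w = f4.vorticity(grad)
        assert np.allclose(w[0, 2], 2.0, atol=1e-12)
        assert np.allclose(f4.strain_sq(grad), 0.0, atol=1e-12)

    def test_taylor_green_mean_identity_is_discretely_exact(self):
        """Equal x/y wavenumbers make the discrete divergence vanish, so the
        periodic-grid enstrophy/strain identity holds to round-off."""
        g = GridSpec((32, 32, 8), (7.5, 7.5, 10.0), n_frames=2)
        fld = f4.gen_analytic_field("taylor_green", 1.0, g)
        grad = f4.velocity_gradient(fld, None, boundary="periodic")
        curves = f4.reduce_over_mask(fld, grad)
        assert curves.enstrophy_sum[0] == pytest.approx(curves.strain_sq_sum[0], rel=1e-12)

    def test_taylor_green_closed_form_vorticity(self):
        g = GridSpec((48, 48, 8), (5.0, 5.0, 10.0), n_frames=2)
        fld = f4.gen_analytic_field("taylor_green", 1.0, g)
        w_true = analytic_vorticity("taylor_green", 1.0, g)
        grad = f4.velocity_gradient(fld, None, boundary="periodic")
        w = f4.vorticity(grad)
        # discrete curl of sampled sinusoids: second-order accurate
        assert np.abs(w[0] - w_true).max() < 4e-2 * np.abs(w_true).max()


class TestVortexRing:
    def test_zero_circulation_zero_field(self, small_grid):
        g = GridSpec((40, 40, 40), (1.0, 1.0, 1.0), n_frames=2)
        fld = gen_vortex_ring_field(0.0, 1.0, 0.3, g)
        assert np.all(fld.values == 0)

    def test_linearity_in_circulation(self):
        g = GridSpec((48, 48, 48), (1.0, 1.0, 1.0), n_frames=2)
        f1 = gen_vortex_ring_field(10.0, 1.0, 0.25, g)
        f2 = gen_vortex_ring_field(20.0, 1.0, 0.25, g)
        assert np.allclose(f2.values, 2.0 * f1.values, rtol=1e-12)

    def test_divergence_free_to_discretization(self):
        g = GridSpec((100, 100, 100), (0.8, 0.8, 0.8), n_frames=2)
        u = ring_unit_velocity(g, 1.25, 0.4)
        fld = f4.VelocityField4D(np.broadcast_to(u[None], (2, 3, *g.shape)).copy(), g)
        grad = f4.velocity_gradient(fld, None)
        div = grad.values[0, 0, 0] + grad.values[0, 1, 1] + grad.values[0, 2, 2]
        assert np.abs(div).max() <= 1e-2 * np.abs(grad.values[0]).max()

    def test_geometry_and_resolution_guards(self):
        g = GridSpec((32, 32, 32), (1.0, 1.0, 1.0), n_frames=2)
        with pytest.raises(GeometryError):
            ring_unit_velocity(g, ring_radius=1.4, core_radius=0.5)  # reach > box
        with pytest.raises(GeometryError):
            ring_unit_velocity(g, ring_radius=0.3, core_radius=0.5)  # core > ring
        with pytest.raises(ResolutionError):
            ring_unit_velocity(g, ring_radius=1.0, core_radius=0.15)


class TestVentriclePhantom:
    def test_volume_waveform_endpoints(self):
        v = volume_waveform(100.0, 60.0, 20, 0.35)
        assert v[0] == 100.0
        assert v.min() == 60.0
        assert v[7] == 60.0  # systole end snapped to frame 7 of 20

    def test_static_chamber_is_flow_free(self, phantom_grid):
        s = PhantomSubject(edv=80.0, esv=80.0, flow_scale=0.0)
        fld, mask, series = f4.gen_ventricle_phantom(s, phantom_grid)
        assert np.all(fld.values == 0)
        assert np.all(series == 80.0)
        curves = f4.compute_flow_curves(fld, mask)
        assert np.all(curves.ke_total == 0)
        assert np.all(curves.vorticity_mean == 0)
        assert np.all(curves.dissipation_rate_total == 0)

    def test_volumetrics_recovered(self, beating_phantom):
        _, _, series = beating_phantom
        vol = f4.volumetrics_from_series(series, hr=80.0, weight=55.0)
        assert vol.sv == pytest.approx(40.0)
        assert vol.ef == pytest.approx(40.0)

    def test_mask_is_end_diastolic_and_static(self, beating_phantom):
        fld, mask, series = beating_phantom
        assert isinstance(mask, VentricleMask)
        assert series.argmax() == 0

    def test_does_not_fit_raises(self):
        g = GridSpec((16, 16, 16), (2.0, 2.0, 2.0), n_frames=4)
        with pytest.raises(GeometryError):
            f4.gen_ventricle_phantom(PhantomSubject(edv=200.0, esv=100.0), g)

    def test_base_flow_is_irrotational(self, phantom_grid):
        """All phantom vorticity comes from the inflow ring."""
        s = PhantomSubject(edv=100.0, esv=60.0, flow_scale=0.0)
        fld, mask, _ = f4.gen_ventricle_phantom(s, phantom_grid)
        curves = f4.compute_flow_curves(fld, mask)
        assert np.all(curves.vorticity_mean < 1e-10)
        assert curves.ke_total.max() > 0

    def test_vorticity_linear_in_flow_scale(self, phantom_grid):
        recs = []
        for fs in (1.0, 2.0):
            s = PhantomSubject(edv=100.0, esv=60.0, flow_scale=fs)
            fld, mask, _ = f4.gen_ventricle_phantom(s, phantom_grid)
            curves = f4.compute_flow_curves(fld, mask)
            recs.append(curves.vorticity_mean.mean())
        assert recs[1] == pytest.approx(2.0 * recs[0], rel=1e-12)

    def test_grid_convergence_of_dimensionless_vorticity(self):
        """Halving the spacing moves omega* by < 5%."""
        s = PhantomSubject(edv=100.0, esv=60.0, hr=80.0, weight=55.0)
        stars = []
        for n, sp in ((40, 2.5), (80, 1.25)):
            g = GridSpec((n,) * 3, (sp,) * 3, n_frames=8)
            fld, mask, series = f4.gen_ventricle_phantom(s, g)
            curves = f4.compute_flow_curves(fld, mask)
            rec = f4.compute_biomarker_record(curves, series, hr=s.hr, weight=s.weight)
            stars.append(rec.dimensionless.vorticity_star)
        assert abs(stars[0] / stars[1] - 1) < 0.05


class TestVelocityNoise:
    def test_infinite_snr_is_identity(self, small_grid):
        fld = f4.gen_analytic_field("shear", 1.0, small_grid)
        out = f4.add_velocity_noise(fld, np.inf, seed=1)
        assert np.array_equal(out.values, fld.values)

    def test_fixed_seed_bit_identical(self, small_grid):
        fld = f4.gen_analytic_field("shear", 1.0, small_grid)
        a = f4.add_velocity_noise(fld, 10.0, seed=7)
        b = f4.add_velocity_noise(fld, 10.0, seed=7)
        assert np.array_equal(a.values, b.values)

    def test_noise_sd_matches_venc_relation(self):
        """Empirical SD within 2% of VENC*sqrt(2)/(pi*SNR) over > 1e6 samples."""
        g = GridSpec((48, 48, 48), n_frames=4)
        zero = f4.VelocityField4D(np.zeros((4, 3, 48, 48, 48)), g, venc=150.0)
        noisy = f4.add_velocity_noise(zero, 10.0, seed=3)
        target = 150.0 * np.sqrt(2.0) / (10.0 * np.pi)
        assert noisy.values.std() == pytest.approx(target, rel=0.02)

    def test_aliasing_wrap_is_opt_in(self, small_grid):
        fld = f4.gen_analytic_field("shear", 1.0, small_grid)
        fld = f4.VelocityField4D(fld.values + 200.0, small_grid, venc=150.0)
        wrapped = wrap_aliased(fld)
        assert wrapped.aliased
        assert np.abs(wrapped.values).max() <= 150.0


class TestCohort:
    def test_reproducible_under_seed(self):
        a, _ = gen_cohort(seed=5)
        b, _ = gen_cohort(seed=5)
        assert a.equals(b)

    def test_group_sizes_match_design(self):
        table, _ = gen_cohort(seed=0)
        counts = table.groupby("group").size()
        assert counts["sham"] == 4 and counts["PAS"] == 4 and counts["intervention"] == 10

    def test_sham_rv_vorticity_mean_near_published(self):
        """Generated sham RV n.d. vorticity mean within 2 SE of the 82 target."""
        design = {"sham": GroupDesign(400, DEFAULT_DESIGN["sham"].targets)}
        table, _ = gen_cohort(design, seed=11)
        vals = table["rv_vorticity_star"]
        se = 47.0 / np.sqrt(len(vals))
        assert abs(vals.mean() - 82.0) < 2.0 * se

    def test_invalid_design_rejected(self):
        with pytest.raises(Exception):
            gen_cohort({"sham": GroupDesign(1, {"m": (1.0, 0.0)})}, seed=0)
        with pytest.raises(Exception):
            GroupDesign(4, {"m": (1.0, -2.0)})

    def test_field_mode_calibrates_vorticity_star(self):
        """Computed omega* reproduces the drawn per-subject target."""
        design = {
            "sham": GroupDesign(
                2,
                {
                    "lv_vorticity_star": (40.0, 5.0),
                    "hr_bpm": (80.0, 0.0),
                    "weight_kg": (55.0, 0.0),
                    "lv_edv_i": (90.0, 0.0),
                    "lv_esv_i": (55.0, 0.0),
                },
            )
        }
        grid = GridSpec((48, 48, 48), (2.5, 2.5, 2.5), n_frames=8)
        table, phantoms = gen_cohort(design, seed=2, mode="fields", grid=grid)
        for _, row in table.iterrows():
            fld, mask, series = phantoms[row["subject_id"]]
            curves = f4.compute_flow_curves(fld, mask)
            rec = f4.compute_biomarker_record(
                curves, series, hr=row["hr_bpm"], weight=row["weight_kg"]
            )
            assert rec.dimensionless.vorticity_star == pytest.approx(
                row["lv_vorticity_star"], rel=1e-6
            )
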