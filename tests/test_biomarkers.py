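"""Volumetrics, dimensional/dimensionless indices and derived metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flow4d as f4
from flow4d import FluidConstants, GridSpec, VelocityField4D
from flow4d.biomarkers import (
    CharacteristicScales,
    dimensional_indices,
    dimensionless_indices,
    lung_perfusion_split,
    pct_dissipation_from_vorticity,
    septal_curvature_index,
    systole_frames,
    volumetrics_from_series,
)
from flow4d.fields import FlowTimeCurves


def _curves(**overrides) -> FlowTimeCurves:
    n = overrides.pop("n", 8)
    base = dict(
        times=np.arange(n) / n,
        ke_total=np.zeros(n),
        ke_mean_density=np.zeros(n),
        vorticity_mean=np.zeros(n),
        enstrophy_sum=np.zeros(n),
        strain_sq_sum=np.ones(n),
        dissipation_rate_total=np.zeros(n),
        masked_volume=np.ones(n),
        valid_volume=np.ones(n),
        rr_interval=1.0,
    )
    base.update(overrides)
    return FlowTimeCurves(**base)


class TestVolumetrics:
    def test_basic_arithmetic(self):
        vol = volumetrics_from_series([100.0, 80.0, 60.0, 75.0], hr=60.0, weight=55.0)
        assert vol.sv == 40.0
        assert vol.ef == pytest.approx(40.0)
        assert vol.co == pytest.approx(2.4)
        assert vol.ci == pytest.approx(2.4 / vol.bsa)

    def test_published_rv_indexed_volumes_give_printed_ef(self):
        """RV EDV/BSA 83, ESV/BSA 50 -> EF 100*33/83, printed as 40%."""
        vol = volumetrics_from_series([83.0, 50.0], hr=88.0, weight=56.0)
        assert vol.ef == pytest.approx(100.0 * 33.0 / 83.0)
        assert round(vol.ef) == 40

    def test_constant_series_zero_ef_with_warning(self):
        with pytest.warns(UserWarning, match="EDV == ESV"):
            vol = volumetrics_from_series([70.0, 70.0], hr=60.0, weight=55.0)
        assert vol.sv == 0.0 and vol.ef == 0.0

    def test_swine_bsa_formula(self):
        assert f4.swine_bsa(55.0) == pytest.approx(0.0734 * 55.0**0.656)


class TestDimensionalIndices:
    def test_single_systolic_peak(self):
        ke = np.zeros(8)
        ke[2] = 50.0
        systole = np.arange(8) < 4
        c = _curves(ke_total=ke)
        d = dimensional_indices(c, sv=25.0, systole=systole)
        assert d.ke_sys_per_sv == pytest.approx(2.0)
        assert d.ke_dia_per_sv == 0.0

    def test_constant_dissipation_rectangle_rule(self):
        c = _curves(dissipation_rate_total=np.full(8, 3.0), rr_interval=0.8)
        d = dimensional_indices(c, sv=2.0, systole=np.arange(8) < 3)
        assert d.dissipation_total == pytest.approx(3.0 * 0.8)
        assert d.dissipation_total_per_sv == pytest.approx(1.2)

    def test_nonpositive_sv_rejected(self):
        with pytest.raises(ValueError, match="stroke volume"):
            dimensional_indices(_curves(), sv=0.0, systole=np.arange(8) < 3)

    def test_diastolic_ke_peak_in_inflow_window(self, beating_phantom):
        """The phantom's KE maximum during diastole coincides with ring inflow."""
        fld, mask, series = beating_phantom
        curves = f4.compute_flow_curves(fld, mask)
        systole = systole_frames(series)
        dia_frames = np.flatnonzero(~systole)
        peak = dia_frames[np.argmax(curves.ke_total[~systole])]
        vdot = np.roll(series, -1) - np.roll(series, 1)
        inflow = np.flatnonzero(vdot > 0)
        assert peak in inflow

    @given(c=st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=20, deadline=None)
    def test_homogeneity_under_velocity_rescaling(self, c):
        """u -> c*u implies KE x c^2, vorticity x c, dissipation x c^2."""
        ke = np.array([1.0, 4.0, 2.0, 0.5])
        vort = np.array([1.0, 2.0, 3.0, 1.0])
        diss = np.array([0.2, 0.4, 0.1, 0.3])
        base = _curves(n=4, ke_total=ke, vorticity_mean=vort, dissipation_rate_total=diss)
        scaled = _curves(
            n=4,
            ke_total=c**2 * ke,
            vorticity_mean=c * vort,
            dissipation_rate_total=c**2 * diss,
        )
        sys_w = np.array([True, True, False, False])
        d0 = dimensional_indices(base, 10.0, sys_w)
        d1 = dimensional_indices(scaled, 10.0, sys_w)
        assert d1.ke_sys_per_sv == pytest.approx(c**2 * d0.ke_sys_per_sv)
        assert d1.vorticity_avg == pytest.approx(c * d0.vorticity_avg)
        assert d1.dissipation_total == pytest.approx(c**2 * d0.dissipation_total)


class TestDimensionlessIndices:
    def test_similarity_scaling_leaves_stars_unchanged(self):
        """Velocities x2 with heart rate x2 (CO x2, geometry fixed) leave
        KE*, omega*, eps* exactly unchanged."""
        g = GridSpec((40, 40, 40), (2.5, 2.5, 2.5), n_frames=10)
        stars = []
        for hr in (80.0, 160.0):
            s = f4.PhantomSubject(edv=100.0, esv=60.0, hr=hr, weight=55.0)
            fld, mask, series = f4.gen_ventricle_phantom(s, g)
            curves = f4.compute_flow_curves(fld, mask)
            rec = f4.compute_biomarker_record(curves, series, hr=hr, weight=55.0)
            stars.append(rec.dimensionless)
        for name in ("ke_sys_star", "ke_dia_star", "vorticity_star", "dissipation_star"):
            assert getattr(stars[0], name) == pytest.approx(
                getattr(stars[1], name), rel=1e-6
            )

    def test_unit_system_invariance(self):
        """The same phantom evaluated in CGS and SI gives identical stars."""
        g = GridSpec((40, 40, 40), (2.5, 2.5, 2.5), n_frames=10)
        s = f4.PhantomSubject(edv=100.0, esv=60.0, hr=80.0, weight=55.0)
        fld, mask, series = f4.gen_ventricle_phantom(s, g)
        curves = f4.compute_flow_curves(fld, mask)
        vol = volumetrics_from_series(series, s.hr, s.weight)
        star_cgs = dimensionless_indices(
            curves, CharacteristicScales.from_volumetrics(vol), systole_frames(series)
        )
        # SI re-run: metres, m/s, kg/m^3, Pa s; the spacing slot carries the
        # length unit, so the numerical grid just shrinks by 100.
        g_si = GridSpec((40, 40, 40), (2.5e-2,) * 3, n_frames=10)
        fld_si = VelocityField4D(fld.values / 100.0, g_si, venc=1.5)
        const_si = FluidConstants(rho=1060.0, mu=0.004)
        curves_si = f4.compute_flow_curves(fld_si, mask.voxels, const_si)
        co_si = vol.co / 6e4  # L/min -> m^3/s
        edv_si = vol.edv * 1e-6
        scales_si = CharacteristicScales(
            length=edv_si ** (1 / 3),
            velocity=co_si / edv_si ** (2 / 3),
            ke_scale=1060.0 * co_si**2 * edv_si ** (-4 / 3),
            vorticity_scale=co_si / edv_si,
            dissipation_scale=0.004 * co_si**2 * edv_si**-2,
        )
        star_si = dimensionless_indices(curves_si, scales_si, systole_frames(series))
        for name in ("ke_sys_star", "ke_dia_star", "vorticity_star", "dissipation_star"):
            assert getattr(star_si, name) == pytest.approx(
                getattr(star_cgs, name), rel=1e-10
            )

    def test_zero_cardiac_output_flagged(self):
        with pytest.raises(ValueError, match="positive CO"):
            CharacteristicScales.from_co_edv(0.0, 100.0)


class TestDissipationMechanism:
    def test_shear_is_all_vorticity(self, small_grid):
        fld = f4.gen_analytic_field("shear", 2.0, small_grid)
        curves = f4.compute_flow_curves(fld, None)
        assert pct_dissipation_from_vorticity(curves) == pytest.approx(100.0, abs=1e-9)
        assert pct_dissipation_from_vorticity(curves, "integral") == pytest.approx(100.0)

    def test_extensional_is_no_vorticity(self, small_grid):
        fld = f4.gen_analytic_field("extensional", 1.0, small_grid)
        curves = f4.compute_flow_curves(fld, None)
        assert pct_dissipation_from_vorticity(curves) == pytest.approx(0.0, abs=1e-9)

    def test_solid_body_limit_is_explicit_error(self, small_grid):
        fld = f4.gen_analytic_field("solid_body", 1.0, small_grid)
        curves = f4.compute_flow_curves(fld, None)
        with pytest.raises(ValueError, match="solid-body"):
            pct_dissipation_from_vorticity(curves)

    def test_ring_on_oracle_domain_near_published_value(self):
        from flow4d.ring import RingModel, ring_pct_dissipation

        pct = ring_pct_dissipation(RingModel(voxels_per_core_radius=4))
        assert pct == pytest.approx(25.0, abs=5.0)

    @pytest.mark.parametrize("extensional_amp", [0.0, 0.5, 1.0, 2.0])
    def test_monotone_decrease_with_added_irrotational_strain(
        self, small_grid, extensional_amp
    ):
        """Superposing extensional strain on a shear flow adds dissipation
        without vorticity: the percentage must fall from 100% accordingly."""
        shear = f4.gen_analytic_field("shear", 2.0, small_grid)
        ext = f4.gen_analytic_field("extensional", extensional_amp, small_grid)
        mix = VelocityField4D(shear.values + ext.values, small_grid)
        curves = f4.compute_flow_curves(mix, None)
        pct = pct_dissipation_from_vorticity(curves)
        expected = 100.0 * 4.0 / (4.0 + 4.0 * extensional_amp**2)
        assert pct == pytest.approx(expected, rel=1e-9)
        assert 0.0 <= pct <= 100.0


class TestLungPerfusionAndSeptum:
    @pytest.mark.parametrize(
        "mpa,rpa,expected",
        [(100.0, 48.0, 52.0), (100.0, 100.0, 0.0), (100.0, 0.0, 100.0)],
    )
    def test_split_percentages(self, mpa, rpa, expected):
        lpa, pct = lung_perfusion_split(np.full(10, mpa), np.full(10, rpa))
        assert pct == pytest.approx(expected)
        assert np.allclose(lpa, mpa - rpa)

    def test_nonpositive_mpa_rejected(self):
        with pytest.raises(ValueError, match="MPA"):
            lung_perfusion_split(np.zeros(4), np.zeros(4))

    @given(
        r=st.floats(min_value=0.5, max_value=10.0),
        edv=st.floats(min_value=20.0, max_value=300.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_septal_index_scaling(self, r, edv):
        idx = septal_curvature_index(r, edv)
        assert idx == pytest.approx(edv ** (1 / 3) / r)
        assert septal_curvature_index(2 * r, edv) == pytest.approx(idx / 2)
        assert septal_curvature_index(r, 8 * edv) == pytest.approx(2 * idx)

    def test_flat_septum_convention(self):
        assert septal_curvature_index(np.inf, 100.0) == 0.0
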