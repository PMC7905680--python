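"""Dimensional and dimensionless ventricular flow biomarkers.

The dimensional report follows common 4D-flow practice: kinetic energy at
peak systole and peak diastole and cycle-summed energy dissipation, both
normalised by stroke volume, plus cycle-averaged vorticity magnitude.

The dimensionless indices divide each quantity by a scale built from
cardiac output and end-diastolic volume (characteristic length
L = EDV^(1/3), velocity U = CO / EDV^(2/3)):

    KE*    = <KE> / (rho CO^2 EDV^(-4/3))
    omega* = <|omega|> / (CO EDV^(-1))
    eps*   = <eps> / (mu CO^2 EDV^(-2))

so that subjects of different size and heart rate become comparable.  The
angle brackets are mask means: the KE scale is an energy *density*, so the
starred KE uses the mask-mean density, while the stroke-volume-indexed
report uses the mask-total KE; both are emitted and labelled.

The dissipation-mechanism metric is the percentage of viscous energy
dissipation attributable to vorticity.  Its default convention is the
ratio of the reported biomarkers,

    pct = 100 * <|omega|>^2 / <2 S^2>,

with the means taken over mask and cycle.  (The ratio of mask *integrals*
100 * sum(omega^2) / sum(2S^2), available as ``convention="integral"``, is
pinned near 100% for any isolated vortex by the vector identity
int |omega|^2 = int 2S^2 for decaying divergence-free fields, and is kept
only as a diagnostic.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .core import FluidConstants
from .fields import FlowTimeCurves

CM3_PER_S_PER_L_MIN = 1000.0 / 60.0


@dataclass(frozen=True)
class Volumetrics:
    """Cine volumetrics for one chamber (mL, %, bpm, L/min, m^2)."""

    edv: float
    esv: float
    sv: float
    ef: float
    hr: float
    co: float
    bsa: float
    ci: float
    edv_i: float
    esv_i: float
    sv_i: float


def volumetrics_from_series(
    volume_series: Sequence[float], hr: float, weight: float
) -> Volumetrics:
    """EDV/ESV/SV/EF/CO/CI from a ventricular volume-vs-frame series.

    BSA uses the Kelley allometric formula for swine,
    BSA(m^2) = 0.0734 * kg^0.656.
    """
    series = np.asarray(volume_series, dtype=float)
    if series.size == 0:
        raise ValueError("volume series is empty")
    if hr <= 0 or weight <= 0:
        raise ValueError("heart rate and weight must be positive")
    from .phantom import swine_bsa

    edv = float(series.max())
    esv = float(series.min())
    sv = edv - esv
    if sv == 0:
        warnings.warn("EDV == ESV: ejection fraction defined as 0", stacklevel=2)
        ef = 0.0
    else:
        ef = 100.0 * sv / edv
    co = hr * sv / 1000.0  # L/min
    bsa = swine_bsa(weight)
    return Volumetrics(
        edv=edv,
        esv=esv,
        sv=sv,
        ef=ef,
        hr=hr,
        co=co,
        bsa=bsa,
        ci=co / bsa,
        edv_i=edv / bsa,
        esv_i=esv / bsa,
        sv_i=sv / bsa,
    )


@dataclass(frozen=True)
class CharacteristicScales:
    """Similarity scales built from cardiac output and end-diastolic volume.

    All values are CGS: length cm, velocity cm/s, KE scale erg/cm^3,
    vorticity scale 1/s, dissipation scale erg/(cm^3 s).
    """

    length: float
    velocity: float
    ke_scale: float
    vorticity_scale: float
    dissipation_scale: float

    @classmethod
    def from_co_edv(
        cls, co_l_min: float, edv_ml: float, constants: FluidConstants = FluidConstants()
    ) -> "CharacteristicScales":
        if co_l_min <= 0 or edv_ml <= 0:
            raise ValueError("characteristic scales need positive CO and EDV")
        co = co_l_min * CM3_PER_S_PER_L_MIN  # cm^3/s
        edv = edv_ml  # mL == cm^3
        return cls(
            length=edv ** (1.0 / 3.0),
            velocity=co / edv ** (2.0 / 3.0),
            ke_scale=constants.rho * co**2 * edv ** (-4.0 / 3.0),
            vorticity_scale=co / edv,
            dissipation_scale=constants.mu * co**2 * edv**-2.0,
        )

    @classmethod
    def from_volumetrics(
        cls, vol: Volumetrics, constants: FluidConstants = FluidConstants()
    ) -> "CharacteristicScales":
        return cls.from_co_edv(vol.co, vol.edv, constants)


def systole_frames(volume_series: Sequence[float]) -> np.ndarray:
    """Boolean per-frame systole flag: frames where volume is decreasing.

    Frame k is systolic when the periodic forward difference
    ``V[k+1] - V[k]`` is negative.
    """
    series = np.asarray(volume_series, dtype=float)
    return np.roll(series, -1) - series < 0


@dataclass(frozen=True)
class DimensionalIndices:
    """Stroke-volume-indexed report (erg/mL, 1/s, erg/mL)."""

    ke_sys_per_sv: float
    ke_dia_per_sv: float
    vorticity_avg: float
    dissipation_total: float  # erg, cycle-summed
    dissipation_total_per_sv: float


def dimensional_indices(
    curves: FlowTimeCurves, sv: float, systole: np.ndarray
) -> DimensionalIndices:
    """Peak systolic/diastolic KE per SV, mean |omega|, cycle-summed dissipation.

    The time integral uses the rectangle rule (frame value times frame
    duration), matching a per-frame sum over the cycle.
    """
    if sv <= 0:
        raise ValueError("stroke volume must be positive for SV-indexed biomarkers")
    systole = np.asarray(systole, dtype=bool)
    if systole.shape != curves.times.shape:
        raise ValueError("systole window must have one flag per frame")
    if not systole.any() or systole.all():
        raise ValueError("systole window must be a strict subset of the cycle")
    ke_sys = float(curves.ke_total[systole].max())
    ke_dia = float(curves.ke_total[~systole].max())
    diss_total = float((curves.dissipation_rate_total * curves.dt).sum())
    return DimensionalIndices(
        ke_sys_per_sv=ke_sys / sv,
        ke_dia_per_sv=ke_dia / sv,
        vorticity_avg=float(curves.vorticity_mean.mean()),
        dissipation_total=diss_total,
        dissipation_total_per_sv=diss_total / sv,
    )


@dataclass(frozen=True)
class DimensionlessIndices:
    ke_sys_star: float
    ke_dia_star: float
    vorticity_star: float
    dissipation_star: float


def dimensionless_indices(
    curves: FlowTimeCurves, scales: CharacteristicScales, systole: np.ndarray
) -> DimensionlessIndices:
    """Starred indices: peak systolic/diastolic KE*, cycle-mean omega*, eps*."""
    systole = np.asarray(systole, dtype=bool)
    if not systole.any() or systole.all():
        raise ValueError("systole window must be a strict subset of the cycle")
    ke_star = curves.ke_mean_density / scales.ke_scale
    eps_star = curves.dissipation_mean_density / scales.dissipation_scale
    return DimensionlessIndices(
        ke_sys_star=float(ke_star[systole].max()),
        ke_dia_star=float(ke_star[~systole].max()),
        vorticity_star=float(curves.vorticity_mean.mean() / scales.vorticity_scale),
        dissipation_star=float(eps_star.mean()),
    )


def pct_dissipation_from_vorticity(
    curves: FlowTimeCurves, convention: str = "biomarker"
) -> float:
    """Percentage of viscous energy dissipation attributable to vorticity.

    ``convention="biomarker"`` (default): 100 * (cycle-mean mask-mean
    |omega|)^2 / (cycle-mean mask-mean 2S^2) — the ratio of the reported
    vorticity biomarker squared to the strain biomarker.

    ``convention="integral"``: 100 * (cycle- and mask-summed |omega|^2) /
    (cycle- and mask-summed 2S^2), a diagnostic pinned near 100% for
    isolated vortices.
    """
    strain_cycle = float(curves.strain_sq_mean.mean())
    if strain_cycle <= 0 or float(curves.strain_sq_sum.sum()) <= 0:
        raise ValueError(
            "dissipation-mechanism percentage undefined for strain-free flow "
            "(solid-body limit)"
        )
    if convention == "biomarker":
        vort_cycle = float(curves.vorticity_mean.mean())
        return 100.0 * vort_cycle**2 / strain_cycle
    if convention == "integral":
        return 100.0 * float(curves.enstrophy_sum.sum()) / float(curves.strain_sq_sum.sum())
    raise ValueError(f"unknown convention {convention!r}; use 'biomarker' or 'integral'")


def lung_perfusion_split(
    mpa_flow: Sequence[float], rpa_flow: Sequence[float]
) -> Tuple[np.ndarray, float]:
    """Left-lung flow curve and percentage from MPA and RPA flow curves.

    LPA flow is MPA minus RPA per frame (signal is lost inside a metal
    stent, so the left side is measured by subtraction); the split is the
    ratio of cycle integrals.
    """
    mpa = np.asarray(mpa_flow, dtype=float)
    rpa = np.asarray(rpa_flow, dtype=float)
    if mpa.shape != rpa.shape:
        raise ValueError("MPA and RPA flow curves must share frame count")
    lpa = mpa - rpa
    total = mpa.sum()
    if total <= 0:
        raise ValueError("non-positive MPA cycle integral: perfusion split undefined")
    return lpa, 100.0 * lpa.sum() / total


def septal_curvature_index(ivs_radius: float, lv_edv: float) -> float:
    """Septal curvature 1/r made dimensionless by L = EDV^(1/3).

    Larger values mean a more curved septum; a flat septum (infinite
    radius) maps to 0 by convention.
    """
    if lv_edv <= 0:
        raise ValueError("LV EDV must be positive")
    if np.isinf(ivs_radius):
        return 0.0
    if ivs_radius <= 0:
        raise ValueError("IVS radius must be positive")
    return lv_edv ** (1.0 / 3.0) / ivs_radius


@dataclass(frozen=True)
class BiomarkerRecord:
    """One subject-chamber row of the biomarker table."""

    chamber: str
    volumetrics: Volumetrics
    dimensional: DimensionalIndices
    dimensionless: DimensionlessIndices
    pct_dissipation_from_vorticity: float

    def to_dict(self) -> dict:
        v, d, s = self.volumetrics, self.dimensional, self.dimensionless
        return {
            "chamber": self.chamber,
            "edv_ml": v.edv,
            "esv_ml": v.esv,
            "sv_ml": v.sv,
            "ef_pct": v.ef,
            "hr_bpm": v.hr,
            "co_l_min": v.co,
            "bsa_m2": v.bsa,
            "ci_l_min_m2": v.ci,
            "edv_i_ml_m2": v.edv_i,
            "esv_i_ml_m2": v.esv_i,
            "sv_i_ml_m2": v.sv_i,
            "ke_sys_per_sv_erg_ml": d.ke_sys_per_sv,
            "ke_dia_per_sv_erg_ml": d.ke_dia_per_sv,
            "vorticity_avg_1_s": d.vorticity_avg,
            "dissipation_total_per_sv_erg_ml": d.dissipation_total_per_sv,
            "ke_sys_star": s.ke_sys_star,
            "ke_dia_star": s.ke_dia_star,
            "vorticity_star": s.vorticity_star,
            "dissipation_star": s.dissipation_star,
            "pct_dissipation_from_vorticity": self.pct_dissipation_from_vorticity,
        }


def compute_biomarker_record(
    curves: FlowTimeCurves,
    volume_series: Sequence[float],
    hr: float,
    weight: float,
    chamber: str = "LV",
    constants: FluidConstants = FluidConstants(),
    systole: Optional[np.ndarray] = None,
) -> BiomarkerRecord:
    """Full per-subject biomarker record from curves plus volumetrics inputs.

    The systole window defaults to the frames where the volume series is
    decreasing; pass ``systole`` explicitly for field data without volumes.
    """
    vol = volumetrics_from_series(volume_series, hr, weight)
    scales = CharacteristicScales.from_volumetrics(vol, constants)
    if systole is None:
        systole = systole_frames(volume_series)
    dim = dimensional_indices(curves, vol.sv, systole)
    star = dimensionless_indices(curves, scales, systole)
    pct = pct_dissipation_from_vorticity(curves)
    return BiomarkerRecord(
        chamber=chamber,
        volumetrics=vol,
        dimensional=dim,
        dimensionless=star,
        pct_dissipation_from_vorticity=pct,
    )
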