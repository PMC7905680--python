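"""Synthetic flow generators standing in for scanner acquisitions.

Four tiers, each a pure function of its parameters (and seed):

* analytic velocity fields with closed-form vorticity and strain (oracle
  inputs for the finite-difference operators);
* divergence-free Gaussian-core vortex-ring fields built from an azimuthal
  vorticity distribution through a spectral vector-potential solve;
* a beating ellipsoidal ventricle whose volume follows a raised-cosine
  systole/diastole waveform, with a wall-motion-consistent base flow plus a
  diastolic inflow vortex ring;
* multi-subject cohorts whose group means and spreads default to the swine
  pulmonary-artery-stenosis study structure (sham / PAS / stent
  intervention) that the statistics stage assumes.

The phantom emulates the gross energetics of ventricular flow, not its
anatomy: no valves, no trabeculation, no turbulence, no k-space simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .core import (
    DesignError,
    GeometryError,
    GridSpec,
    ResolutionError,
    VelocityField4D,
    VentricleMask,
)

ANALYTIC_KINDS = ("solid_body", "shear", "extensional", "taylor_green")


# ---------------------------------------------------------------------------
# Analytic fields
# ---------------------------------------------------------------------------

def _analytic_velocity(kind: str, amplitude: float, grid: GridSpec) -> np.ndarray:
    X, Y, Z = grid.meshgrid_cm()
    a = amplitude
    if kind == "solid_body":
        # u = Omega x r with Omega = (0, 0, A): rigid rotation about z.
        u = np.stack([-a * Y, a * X, np.zeros_like(X)])
    elif kind == "shear":
        u = np.stack([a * Y, np.zeros_like(X), np.zeros_like(X)])
    elif kind == "extensional":
        u = np.stack([a * X, -a * Y, np.zeros_like(X)])
    elif kind == "taylor_green":
        # One full period across the grid along x and y.  Velocity amplitude
        # A/k keeps the vorticity amplitude at 2A (1/s) for cubic cells.
        kx = 2.0 * np.pi / (grid.shape[0] * grid.spacing_cm[0])
        ky = 2.0 * np.pi / (grid.shape[1] * grid.spacing_cm[1])
        xp = kx * (np.arange(grid.shape[0]) * grid.spacing_cm[0])
        yp = ky * (np.arange(grid.shape[1]) * grid.spacing_cm[1])
        XP, YP = np.meshgrid(xp, yp, indexing="ij")
        ux = (a / kx) * np.sin(XP) * np.cos(YP)
        uy = -(a / ky) * np.cos(XP) * np.sin(YP)
        u = np.stack(
            [
                np.repeat(ux[:, :, None], grid.shape[2], axis=2),
                np.repeat(uy[:, :, None], grid.shape[2], axis=2),
                np.zeros(grid.shape),
            ]
        )
    else:
        raise ValueError(f"unknown analytic kind {kind!r}; options are {ANALYTIC_KINDS}")
    return u


def gen_analytic_field(kind: str, amplitude: float, grid: GridSpec) -> VelocityField4D:
    """Steady analytic velocity field replicated over all frames.

    ``amplitude`` has units 1/s for every kind (it is a velocity gradient
    scale); samples are exact closed-form values at voxel centres.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    u = _analytic_velocity(kind, amplitude, grid)
    values = np.broadcast_to(u[None], (grid.n_frames, 3, *grid.shape)).copy()
    return VelocityField4D(values, grid)


def analytic_vorticity(kind: str, amplitude: float, grid: GridSpec) -> np.ndarray:
    """Closed-form vorticity vector ``[3, x, y, z]`` (1/s) for an analytic kind."""
    a = amplitude
    zeros = np.zeros(grid.shape)
    if kind == "solid_body":
        return np.stack([zeros, zeros, np.full(grid.shape, 2.0 * a)])
    if kind == "shear":
        return np.stack([zeros, zeros, np.full(grid.shape, -a)])
    if kind == "extensional":
        return np.stack([zeros, zeros, zeros])
    if kind == "taylor_green":
        kx = 2.0 * np.pi / (grid.shape[0] * grid.spacing_cm[0])
        ky = 2.0 * np.pi / (grid.shape[1] * grid.spacing_cm[1])
        xp = kx * (np.arange(grid.shape[0]) * grid.spacing_cm[0])
        yp = ky * (np.arange(grid.shape[1]) * grid.spacing_cm[1])
        XP, YP = np.meshgrid(xp, yp, indexing="ij")
        wz = a * (kx / ky + ky / kx) * np.sin(XP) * np.sin(YP)
        return np.stack([zeros, zeros, np.repeat(wz[:, :, None], grid.shape[2], axis=2)])
    raise ValueError(f"unknown analytic kind {kind!r}; options are {ANALYTIC_KINDS}")


def analytic_strain_sq(kind: str, amplitude: float, grid: GridSpec) -> np.ndarray:
    """Closed-form 2 S_ij S_ij ``[x, y, z]`` (1/s^2) for an analytic kind."""
    a = amplitude
    if kind == "solid_body":
        return np.zeros(grid.shape)
    if kind == "shear":
        return np.full(grid.shape, a * a)
    if kind == "extensional":
        return np.full(grid.shape, 4.0 * a * a)
    if kind == "taylor_green":
        kx = 2.0 * np.pi / (grid.shape[0] * grid.spacing_cm[0])
        ky = 2.0 * np.pi / (grid.shape[1] * grid.spacing_cm[1])
        xp = kx * (np.arange(grid.shape[0]) * grid.spacing_cm[0])
        yp = ky * (np.arange(grid.shape[1]) * grid.spacing_cm[1])
        XP, YP = np.meshgrid(xp, yp, indexing="ij")
        s = 4.0 * a * a * (np.cos(XP) * np.cos(YP)) ** 2 + a * a * (
            kx / ky - ky / kx
        ) ** 2 * (np.sin(XP) * np.sin(YP)) ** 2
        return np.repeat(s[:, :, None], grid.shape[2], axis=2)
    raise ValueError(f"unknown analytic kind {kind!r}; options are {ANALYTIC_KINDS}")


# ---------------------------------------------------------------------------
# Gaussian-core vortex ring
# ---------------------------------------------------------------------------

def _unit_vectors(axis: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("ring axis must be non-zero")
    n = n / norm
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2, n


def ring_vorticity_components(
    grid: GridSpec,
    circulation: float,
    ring_radius: float,
    core_radius: float,
    center: Tuple[float, float, float] = (0.0, 0.0, 0.0),
    axis: Tuple[float, float, float] = (0.0, 0.0, 1.0),
) -> np.ndarray:
    """Azimuthal Gaussian-core ring vorticity sampled on the grid, ``[3,x,y,z]``.

    omega_phi(d) = Gamma / (pi a^2) * exp(-d^2 / a^2) where d is the
    distance from the ring centreline in the meridional plane; the profile
    integrates to the circulation Gamma over a core cross-section.
    """
    e1, e2, n = _unit_vectors(np.asarray(axis))
    X, Y, Z = grid.meshgrid_cm()
    rx = X - center[0]
    ry = Y - center[1]
    rz = Z - center[2]
    zc = rx * n[0] + ry * n[1] + rz * n[2]
    px = rx - zc * n[0]
    py = ry - zc * n[1]
    pz = rz - zc * n[2]
    rho = np.sqrt(px**2 + py**2 + pz**2)
    d2 = (rho - ring_radius) ** 2 + zc**2
    om = circulation / (np.pi * core_radius**2) * np.exp(-d2 / core_radius**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        inv = np.where(rho > 0, 1.0 / np.maximum(rho, 1e-300), 0.0)
    # phi-hat = n x rho-hat
    phix = (n[1] * pz - n[2] * py) * inv
    phiy = (n[2] * px - n[0] * pz) * inv
    phiz = (n[0] * py - n[1] * px) * inv
    return np.stack([om * phix, om * phiy, om * phiz])


def _biot_savart_spectral(w: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Velocity from vorticity: solve lap A = -w, u = curl A, spectrally.

    The construction is divergence-free by gauge (k . u_hat = 0); the grid
    is treated as one periodic box, so the vorticity must be compactly
    supported well inside it.
    """
    shape = grid.shape
    ks = [2.0 * np.pi * np.fft.fftfreq(n, d=h) for n, h in zip(shape, grid.spacing_cm)]
    ks[2] = 2.0 * np.pi * np.fft.rfftfreq(shape[2], d=grid.spacing_cm[2])
    KX, KY, KZ = np.meshgrid(*ks, indexing="ij")
    K2 = KX**2 + KY**2 + KZ**2
    K2[0, 0, 0] = 1.0
    A = [np.fft.rfftn(w[c]) / K2 for c in range(3)]
    for a in A:
        a[0, 0, 0] = 0.0
    axes = [0, 1, 2]
    ux = np.fft.irfftn(1j * (KY * A[2] - KZ * A[1]), s=shape, axes=axes)
    uy = np.fft.irfftn(1j * (KZ * A[0] - KX * A[2]), s=shape, axes=axes)
    uz = np.fft.irfftn(1j * (KX * A[1] - KY * A[0]), s=shape, axes=axes)
    return np.stack([ux, uy, uz])


def ring_unit_velocity(
    grid: GridSpec,
    ring_radius: float,
    core_radius: float,
    center: Tuple[float, float, float] = (0.0, 0.0, 0.0),
    axis: Tuple[float, float, float] = (0.0, 0.0, 1.0),
) -> np.ndarray:
    """Velocity ``[3, x, y, z]`` of a unit-circulation Gaussian-core ring.

    The field is exactly linear in the circulation, so callers scale this
    once-computed template instead of re-solving.
    """
    if core_radius >= ring_radius:
        raise GeometryError(
            f"core radius {core_radius} must be smaller than ring radius {ring_radius}"
        )
    if 2.0 * core_radius < 4.0 * min(grid.spacing_cm):
        raise ResolutionError(
            f"core diameter {2 * core_radius:.3f} cm spans fewer than 4 voxels at "
            f"spacing {min(grid.spacing_cm):.3f} cm"
        )
    # The padded torus (3 core radii of clearance) must fit inside the grid.
    half = [n * h / 2.0 for n, h in zip(grid.shape, grid.spacing_cm)]
    reach = ring_radius + 3.0 * core_radius
    c = np.asarray(center, dtype=float)
    if any(abs(c[i]) + reach > half[i] for i in range(3)):
        raise GeometryError(
            f"ring of reach {reach:.2f} cm at centre {tuple(c)} does not fit the grid "
            f"(half-extents {tuple(round(h, 2) for h in half)} cm)"
        )
    w = ring_vorticity_components(grid, 1.0, ring_radius, core_radius, center, axis)
    return _biot_savart_spectral(w, grid)


def gen_vortex_ring_field(
    circulation: float,
    ring_radius: float,
    core_radius: float,
    grid: GridSpec,
    center: Tuple[float, float, float] = (0.0, 0.0, 0.0),
    axis: Tuple[float, float, float] = (0.0, 0.0, 1.0),
) -> VelocityField4D:
    """Steady Gaussian-core vortex-ring field replicated over all frames."""
    if circulation == 0:
        return VelocityField4D(np.zeros((grid.n_frames, 3, *grid.shape)), grid)
    u = circulation * ring_unit_velocity(grid, ring_radius, core_radius, center, axis)
    values = np.broadcast_to(u[None], (grid.n_frames, 3, *grid.shape)).copy()
    return VelocityField4D(values, grid)


# ---------------------------------------------------------------------------
# Beating-ventricle phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSubject:
    """Parameter vector for one synthetic subject."""

    group: str = "sham"
    edv: float = 100.0  # mL
    esv: float = 60.0  # mL
    hr: float = 90.0  # bpm
    weight: float = 55.0  # kg
    flow_scale: float = 1.0  # dimensionless inflow-jet strength
    seed: int = 0
    chamber: str = "LV"

    def __post_init__(self) -> None:
        if not (0 < self.esv <= self.edv):
            raise ValueError(f"need 0 < esv <= edv, got esv={self.esv}, edv={self.edv}")
        if self.hr <= 0 or self.weight <= 0:
            raise ValueError("heart rate and weight must be positive")

    @property
    def rr_interval(self) -> float:
        return 60.0 / self.hr


def volume_waveform(
    edv: float, esv: float, n_frames: int, systolic_fraction: float = 0.35
) -> np.ndarray:
    """Raised-cosine systole/diastole volume series (mL), frame 0 = EDV.

    The end of systole is snapped to the nearest frame so that
    ``min(series) == esv`` holds exactly on the sampled series; the series
    is periodic (the wrap-around value is EDV again).
    """
    if not (0 < systolic_fraction < 1):
        raise ValueError("systolic fraction must be in (0, 1)")
    ks = int(round(systolic_fraction * n_frames))
    ks = min(max(ks, 1), n_frames - 1)
    k = np.arange(n_frames)
    w = np.empty(n_frames)
    w[: ks + 1] = 0.5 * (1.0 + np.cos(np.pi * k[: ks + 1] / ks))
    w[ks:] = 0.5 * (1.0 - np.cos(np.pi * (k[ks:] - ks) / (n_frames - ks)))
    return esv + (edv - esv) * w


def _volume_rate(series_ml: np.ndarray, rr_interval: float) -> np.ndarray:
    """dV/dt (mL/s) at frame times from the periodic raised-cosine series.

    A periodic centred difference of the sampled series keeps the base flow
    exactly consistent with the emitted volume series.
    """
    n = len(series_ml)
    dt = rr_interval / n
    return (np.roll(series_ml, -1) - np.roll(series_ml, 1)) / (2.0 * dt)


_CHAMBER_ASPECT = 1.6  # long-axis / short-axis ratio of the ellipsoid


def _chamber_axes(volume_ml: float) -> Tuple[float, float]:
    """Semi-axes (b, c) in cm of a prolate ellipsoid (b, b, c) of given volume."""
    b = (3.0 * volume_ml / (4.0 * np.pi * _CHAMBER_ASPECT)) ** (1.0 / 3.0)
    return b, _CHAMBER_ASPECT * b


def gen_ventricle_phantom(
    subject: PhantomSubject,
    grid: GridSpec,
    systolic_fraction: float = 0.35,
    time_resolved_masks: bool = False,
):
    """Beating ellipsoidal chamber with diastolic vortex-ring inflow.

    Returns ``(field, mask, volume_series)`` — and additionally a
    ``[frame, x, y, z]`` stack of per-frame chamber masks when
    ``time_resolved_masks`` is set.

    The interior velocity is the sum of a wall-motion-consistent linear
    base flow ``u = (dV/dt / 3V) (x - centre)`` (zero vorticity, pure
    strain) and a Gaussian-core vortex ring near the base of the chamber
    whose circulation follows the diastolic filling rate, scaled by
    ``subject.flow_scale``.  The mask is the frame-0 (end-diastolic)
    chamber; because all vorticity comes from the ring, downstream
    vorticity biomarkers are exactly linear in ``flow_scale``.
    """
    grid = replace(grid, rr_interval=subject.rr_interval)
    series = volume_waveform(subject.edv, subject.esv, grid.n_frames, systolic_fraction)
    b_ed, c_ed = _chamber_axes(subject.edv)
    half = [n * h / 2.0 for n, h in zip(grid.shape, grid.spacing_cm)]
    margin = 2.0 * max(grid.spacing_cm)
    if b_ed + margin > min(half[0], half[1]) or c_ed + margin > half[2]:
        raise GeometryError(
            f"chamber semi-axes ({b_ed:.2f}, {c_ed:.2f}) cm do not fit grid "
            f"half-extents {tuple(round(h, 2) for h in half)} cm"
        )

    X, Y, Z = grid.meshgrid_cm()
    scale = (series / subject.edv) ** (1.0 / 3.0)
    ed_mask = (X / b_ed) ** 2 + (Y / b_ed) ** 2 + (Z / c_ed) ** 2 <= 1.0
    mask = VentricleMask(ed_mask, subject.chamber)

    vdot = _volume_rate(series, subject.rr_interval)
    values = np.zeros((grid.n_frames, 3, *grid.shape))
    static = subject.edv == subject.esv
    if not static:
        for t in range(grid.n_frames):
            coeff = vdot[t] / (3.0 * series[t])  # 1/s
            values[t, 0] = coeff * X
            values[t, 1] = coeff * Y
            values[t, 2] = coeff * Z

    if subject.flow_scale != 0.0 and not static:
        # Chamber-scaled inflow ring with an absolute core floor so that the
        # phantom geometry is independent of the voxel grid (the core still
        # has to satisfy the generator's 4-voxel resolution requirement).
        ring_radius = 0.5 * b_ed
        core_radius = max(0.35 * ring_radius, 0.5)
        center = (0.0, 0.0, 0.45 * c_ed)
        u_ring = ring_unit_velocity(grid, ring_radius, core_radius, center, (0.0, 0.0, -1.0))
        inflow = np.maximum(vdot, 0.0)  # mL/s, diastole only
        for t in range(grid.n_frames):
            gamma = subject.flow_scale * inflow[t] / (np.pi * ring_radius)  # cm^2/s
            if gamma:
                values[t] += gamma * u_ring

    out = (VelocityField4D(values, grid), mask, series)
    if time_resolved_masks:
        masks = np.empty((grid.n_frames, *grid.shape), dtype=bool)
        for t in range(grid.n_frames):
            s = scale[t]
            masks[t] = (X / (b_ed * s)) ** 2 + (Y / (b_ed * s)) ** 2 + (
                Z / (c_ed * s)
            ) ** 2 <= 1.0
        out = out + (masks,)
    return out


# ---------------------------------------------------------------------------
# PC-MRI velocity noise
# ---------------------------------------------------------------------------

def add_velocity_noise(field: VelocityField4D, snr: float, seed: int) -> VelocityField4D:
    """Add zero-mean Gaussian PC-MRI velocity noise per component per voxel.

    Uses the standard phase-contrast relation sigma = VENC * sqrt(2) / (pi * SNR),
    with SNR the magnitude-image signal-to-noise ratio.  Deterministic for a
    fixed seed; ``snr = inf`` returns the field unchanged.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    if np.isinf(snr):
        return VelocityField4D(field.values.copy(), field.grid, field.venc, field.aliased)
    sigma = field.venc * np.sqrt(2.0) / (np.pi * snr)
    rng = np.random.default_rng(seed)
    noisy = field.values + rng.normal(0.0, sigma, size=field.values.shape)
    return VelocityField4D(noisy, field.grid, field.venc, field.aliased)


def wrap_aliased(field: VelocityField4D) -> VelocityField4D:
    """Opt-in VENC wrap: fold velocities into (-VENC, +VENC] like phase aliasing."""
    v = field.venc
    wrapped = np.mod(field.values + v, 2.0 * v) - v
    wrapped[wrapped == -v] = v
    return VelocityField4D(wrapped, field.grid, v, aliased=True)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupDesign:
    """Per-group sample size and target mean/SD for each generated column."""

    n: int
    targets: Dict[str, Tuple[float, float]]

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DesignError(f"need n >= 2 per group, got {self.n}")
        for name, (_, sd) in self.targets.items():
            if sd < 0:
                raise DesignError(f"negative SD for {name}")


#: Study-structured default design: group sizes and the published
#: non-dimensional vorticity and volumetric group statistics (mean, SD).
DEFAULT_DESIGN: Dict[str, GroupDesign] = {
    "sham": GroupDesign(
        4,
        {
            "rv_vorticity_star": (82, 47),
            "lv_vorticity_star": (57, 5),
            "hr_bpm": (88, 8),
            "weight_kg": (56, 7),
            "lv_edv_i": (93, 9),
            "lv_esv_i": (58, 4),
            "rv_edv_i": (83, 13),
            "rv_esv_i": (50, 13),
        },
    ),
    "PAS": GroupDesign(
        4,
        {
            "rv_vorticity_star": (120, 47),
            "lv_vorticity_star": (78, 15),
            "hr_bpm": (84, 6),
            "weight_kg": (57, 5),
            "lv_edv_i": (102, 14),
            "lv_esv_i": (62, 13),
            "rv_edv_i": (98, 20),
            "rv_esv_i": (62, 16),
        },
    ),
    "intervention": GroupDesign(
        10,
        {
            "rv_vorticity_star": (59, 12),
            "lv_vorticity_star": (41, 7),
            "hr_bpm": (94, 15),
            "weight_kg": (53, 10),
            "lv_edv_i": (75, 12),
            "lv_esv_i": (37, 10),
            "rv_edv_i": (72, 15),
            "rv_esv_i": (35, 10),
        },
    ),
}

#: Columns that must stay physiologically positive after Gaussian draws.
_POSITIVE_FLOOR = {
    "hr_bpm": 40.0,
    "weight_kg": 20.0,
    "lv_edv_i": 20.0,
    "lv_esv_i": 5.0,
    "rv_edv_i": 20.0,
    "rv_esv_i": 5.0,
    "rv_vorticity_star": 1.0,
    "lv_vorticity_star": 1.0,
}


def swine_bsa(weight_kg: float) -> float:
    """Kelley allometric body-surface-area estimate for swine (m^2)."""
    return 0.0734 * weight_kg**0.656


def gen_cohort(
    design: Optional[Dict[str, GroupDesign]] = None,
    seed: int = 0,
    mode: str = "table",
    grid: Optional[GridSpec] = None,
    chamber: str = "LV",
):
    """Draw a cohort table (and optionally per-subject phantoms).

    Table mode draws every target column from a Gaussian at the design's
    mean/SD (floored at loose physiological bounds so chamber volumes stay
    positive) and derives absolute volumes from the indexed ones via the
    Kelley BSA.  Field mode additionally emits one ventricle phantom per
    subject whose ``flow_scale`` is calibrated so the computed
    non-dimensional vorticity reproduces the drawn target exactly (the
    phantom's vorticity is linear in ``flow_scale``).

    Returns ``(table, phantoms)`` where ``phantoms`` is ``None`` in table
    mode and a dict ``subject_id -> (field, mask, volume_series)`` in field
    mode.
    """
    import pandas as pd

    design = DEFAULT_DESIGN if design is None else design
    if not design:
        raise DesignError("empty cohort design")
    for g in design.values():
        if g.n < 2:
            raise DesignError("need n >= 2 per group")
    if mode not in ("table", "fields"):
        raise ValueError(f"unknown mode {mode!r}; use 'table' or 'fields'")

    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for group, gdes in design.items():
        for _ in range(gdes.n):
            row = {"subject_id": f"{group}_{idx:02d}", "group": group}
            for name, (mean, sd) in gdes.targets.items():
                v = rng.normal(mean, sd)
                if name in _POSITIVE_FLOOR:
                    v = max(v, _POSITIVE_FLOOR[name])
                row[name] = v
            rows.append(row)
            idx += 1
    table = pd.DataFrame(rows)

    if {"weight_kg", "lv_edv_i", "lv_esv_i"}.issubset(table.columns):
        table["bsa_m2"] = table["weight_kg"].map(swine_bsa)
        for ch in ("lv", "rv"):
            if f"{ch}_edv_i" in table.columns:
                edv = table[f"{ch}_edv_i"] * table["bsa_m2"]
                esv = table[f"{ch}_esv_i"] * table["bsa_m2"]
                esv = np.minimum(esv, 0.9 * edv)  # keep EF > 0
                table[f"{ch}_edv_ml"] = edv
                table[f"{ch}_esv_ml"] = esv

    phantoms = None
    if mode == "fields":
        from . import biomarkers as bm
        from .fields import compute_flow_curves

        if grid is None:
            grid = GridSpec(shape=(56, 56, 56), spacing_mm=(2.0, 2.0, 2.0))
        phantoms = {}
        lo = chamber.lower()
        for _, row in table.iterrows():
            subj = PhantomSubject(
                group=row["group"],
                edv=row[f"{lo}_edv_ml"],
                esv=row[f"{lo}_esv_ml"],
                hr=row["hr_bpm"],
                weight=row["weight_kg"],
                flow_scale=1.0,
                chamber=chamber,
            )
            fld, msk, series = gen_ventricle_phantom(subj, grid)
            curves = compute_flow_curves(fld, msk)
            vol = bm.volumetrics_from_series(series, subj.hr, subj.weight)
            scales = bm.CharacteristicScales.from_volumetrics(vol)
            unit_star = np.mean(curves.vorticity_mean) / scales.vorticity_scale
            target = row[f"{lo}_vorticity_star"]
            flow_scale = target / unit_star if unit_star > 0 else 0.0
            subj = replace(subj, flow_scale=flow_scale)
            fld, msk, series = gen_ventricle_phantom(subj, grid)
            phantoms[row["subject_id"]] = (fld, msk, series)
            table.loc[table["subject_id"] == row["subject_id"], "flow_scale"] = flow_scale
    return table, phantoms
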