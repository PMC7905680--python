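"""One synthetic subject end to end: phantom -> curves -> biomarkers.

Generates a beating ellipsoidal ventricle (EDV 100 mL, ESV 60 mL, 80 bpm)
with a diastolic inflow vortex ring, reduces the velocity field to
per-frame curves inside the end-diastolic mask, and prints the
stroke-volume-indexed and dimensionless biomarker record.
"""

import flow4d as f4

grid = f4.GridSpec((48, 48, 48), (2.0, 2.0, 2.0), n_frames=20)
subject = f4.PhantomSubject(edv=100.0, esv=60.0, hr=80.0, weight=55.0, flow_scale=1.0)

field, mask, volume_series = f4.gen_ventricle_phantom(subject, grid)
curves = f4.compute_flow_curves(field, mask)
record = f4.compute_biomarker_record(
    curves, volume_series, hr=subject.hr, weight=subject.weight
)

d = record.to_dict()
print("volumetrics: "
      f"EDV {d['edv_ml']:.0f} mL, ESV {d['esv_ml']:.0f} mL, SV {d['sv_ml']:.0f} mL, "
      f"EF {d['ef_pct']:.0f}%, CO {d['co_l_min']:.1f} L/min")
print("stroke-volume-indexed: "
      f"KE_sys {d['ke_sys_per_sv_erg_ml']:.2f} erg/mL, "
      f"KE_dia {d['ke_dia_per_sv_erg_ml']:.2f} erg/mL, "
      f"dissipation {d['dissipation_total_per_sv_erg_ml']:.2f} erg/mL")
print(f"cycle-mean |omega|: {d['vorticity_avg_1_s']:.2f} 1/s")
print("dimensionless: "
      f"KE*_sys {d['ke_sys_star']:.3f}, KE*_dia {d['ke_dia_star']:.3f}, "
      f"omega* {d['vorticity_star']:.2f}, eps* {d['dissipation_star']:.1f}")
print(f"dissipation from vorticity: {d['pct_dissipation_from_vorticity']:.1f}% "
      "(chamber-sized region, base-flow strain dominates)")

# ancillary metrics from the same study design
lpa, left_pct = f4.lung_perfusion_split([100.0] * 20, [48.0] * 20)
print(f"lung perfusion split for MPA 100, RPA 48 mL/s: left lung {left_pct:.0f}%")
print(f"septal curvature index (r = 3 cm, LV EDV 100 mL): "
      f"{f4.septal_curvature_index(3.0, 100.0):.2f}")
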