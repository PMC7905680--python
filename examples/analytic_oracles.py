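"""Analytic velocity fields with known vorticity and strain.

Builds rigid rotation, plane shear and extensional flows on a small grid,
runs the masked finite-difference operators, and compares against the
closed forms.  The last block shows the two conventions for the
"percentage of dissipation due to vorticity": shear is pure rotation-plus-
shear (100%), extensional flow is irrotational (0%).
"""

import numpy as np

import flow4d as f4

grid = f4.GridSpec((16, 16, 16), (2.5, 2.5, 2.5), n_frames=2)

for kind, amp in (("solid_body", 1.0), ("shear", 2.0), ("extensional", 1.0)):
    field = f4.gen_analytic_field(kind, amp, grid)
    grad = f4.velocity_gradient(field, None)
    omega = f4.vorticity(grad)
    two_s2 = f4.strain_sq(grad)
    print(
        f"{kind:12s} amplitude {amp:.0f}/s:  |omega| = "
        f"{np.sqrt((omega[0] ** 2).sum(axis=0)).max():.3f} 1/s,  "
        f"2S^2 = {two_s2[0].max():.3f} 1/s^2"
    )
# rigid rotation: |omega| = 2*Omega and zero strain; shear A: |omega| = A
# and 2S^2 = A^2; extensional A: zero vorticity and 2S^2 = 4A^2.

for kind in ("shear", "extensional"):
    field = f4.gen_analytic_field(kind, 2.0, grid)
    curves = f4.compute_flow_curves(field, None)
    pct = f4.pct_dissipation_from_vorticity(curves)
    print(f"{kind:12s}: {pct:5.1f}% of dissipation attributable to vorticity")
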