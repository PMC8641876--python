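"""Phase-plane analysis: nullclines, intersections and the vector field.

Computes both nullclines of the reduced system in a bistable window.  Their
intersections are the steady states: two stable (the tissue states) and one
unstable (the basin boundary).  The L-nullcline does not depend on the
basal production rate; only the YAP/TAZ nullcline moves as kYTup0 changes.
"""
import yaptaz as yz
from yaptaz.phaseplane import compute_nullcline, compute_vector_field, intersect_nullclines

std = yz.standard_parameters()
diag = yz.sweep_bifurcation(std, sweep_range=(-0.012, 0.03), steps=300)
k = 0.5 * (diag.saddle_nodes.SN1 + diag.saddle_nodes.SN2)  # lower bistable window
p = std.replace(kYTup0=k)

cl = compute_nullcline("L_nullcline", p, resolution=300)
cy = compute_nullcline("YTup_nullcline", p, resolution=300)
inter = intersect_nullclines(cl, cy, p)
eqs = yz.find_steady_states(p)

print(f"kYTup0 = {k:.5f} (inside the degeneration switch's bistable window)")
print(f"nullcline intersections: {len(inter)}")
for s, e in zip(sorted(inter, key=lambda s: s.YT_up), eqs):
    print(f"  L={s.L:.4f} YT_up={s.YT_up:.4f}  [{e.stability}]")
vf = compute_vector_field(p, grid_n=12)
print(f"vector field: {vf.L.size} arrows, max speed {vf.magnitude.max():.4g}")
print("\nThe two stable intersections are the degenerative and homeostatic")
print("states; the middle unstable one separates their basins of attraction.")
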