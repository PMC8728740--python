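"""Per-frame membrane structure: area per lipid, thickness, enhancer depth.

The synthetic bilayer embeds a 6.60 nm lateral box and phosphate planes at
±1.95 nm, so the printed pure-POPC geometry (APL ≈ 0.68 nm², leaflet
thickness 1.95 nm) comes out by construction.
"""

import numpy as np

from memperturb import make_bilayer_trajectory, membrane_metrics_series

traj, _ = make_bilayer_trajectory(n_pe=3, n_frames=10, seed=2)
series = membrane_metrics_series(traj, n_leaflet_lipids=64)

print(f"area per lipid:    {series.apl.mean():.4f} ± {series.apl.std():.4f} nm^2")
print(f"P-P thickness:     {series.thickness_pp.mean():.3f} nm "
      f"(leaflet {series.leaflet_thickness.mean():.3f} nm)")
print(f"membrane center z: {series.z_center.mean():.3f} nm")
for pe_id, d in series.pe_depth.items():
    print(f"enhancer {pe_id}: depth d = {np.mean(d):.3f} nm from the membrane center")
# d is the |z| distance of the enhancer's heavy-atom center of mass from the
# bilayer midplane; resident enhancers sit around 0.9-1.0 nm here because the
# head anchors at 1.5 nm and the 10-carbon tail points inward.
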