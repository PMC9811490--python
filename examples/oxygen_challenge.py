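"""Dual-wavelength sO2 recovery during a hyperoxia/hypoxia challenge.

Composes 750/850 nm photoacoustic sequences from a piecewise sO2
schedule, pushes each frame through the forward model and delay-and-sum
reconstruction, and unmixes the reconstructions back into hemoglobin
concentrations.  The masked-mean sO2 trace should reproduce the
schedule's plateaus and transitions.
"""

import numpy as np

from hemipact.core import GridSpec, Volume
from hemipact.forward import impulse_response, simulate_signals
from hemipact.geometry import build_array, select_subset
from hemipact.phantom import OxygenChallengeProtocol, make_oxygen_challenge
from hemipact.reconstruction import ReconGrid, das_reconstruct
from hemipact.unmixing import default_extinction_table, functional_maps

grid_spec = GridSpec((20, 20, 20), 0.4)
labels = np.zeros(grid_spec.shape)
labels[4:16, 9:12, 9:12] = 1  # a vessel rod
label_map = Volume(labels, grid_spec.voxel_mm, grid_spec.origin_mm)

protocol = OxygenChallengeProtocol(segments=((12.0, 0.95), (12.0, 0.70), (12.0, 0.95)))
table = default_extinction_table()
challenge = make_oxygen_challenge(label_map, protocol, table, frame_rate_hz=0.25)

geom = build_array(n_elements=64, element_area_mm2=12.0 * 1024 / 64)
subset = select_subset(geom, "full")
ir = impulse_response()
recon_grid = ReconGrid((20, 20, 20), 0.4)

print(" frame   true sO2   recovered sO2")
for i in range(len(challenge.seq_750)):
    recons = [
        das_reconstruct(simulate_signals(seq[i], geom, subset, ir), geom, recon_grid)
        for seq in (challenge.seq_750, challenge.seq_850)
    ]
    maps = functional_maps(recons[0], recons[1], table, threshold_fraction=0.1)
    recovered = float(np.nanmean(maps.so2.values))
    print(f"  {i:3d}     {challenge.so2_true[i]:.2f}        {recovered:.3f}")
print("-> reconstruction is linear, so the per-voxel 750/850 ratio — and hence")
print("   sO2 — survives the acoustic round trip essentially exactly.")
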