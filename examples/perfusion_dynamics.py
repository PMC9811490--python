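"""Contrast-bolus dynamics: time-to-peak ordering and respiration rate.

Generates the default synthetic indocyanine-green perfusion sequence
(gamma-variate uptake peaking in the vessel, then kidney, then liver,
with 0.7 Hz respiratory and 5 Hz cardiac modulation), and analyzes it:
median time-to-peak per compartment and the dominant physiological
frequency of the kidney VOI trace.
"""

import numpy as np

from hemipact.core import GridSpec
from hemipact.dynamics import time_to_peak_map
from hemipact.phantom import KIDNEY, LIVER, VESSEL, default_icg_compartments, make_icg_sequence
from hemipact.workflows import kidney_perfusion_frequency

grid = GridSpec((32, 32, 32), voxel_mm=0.4)
compartments = default_icg_compartments(grid)
sequence = make_icg_sequence(compartments, duration_s=90.0, frame_rate_hz=2.0)

ttp = time_to_peak_map(sequence, baseline_frames=4)
names = {VESSEL: "vessel", KIDNEY: "kidney", LIVER: "liver"}
print("median time to peak after injection:")
for label, name in names.items():
    t = np.nanmedian(ttp.values[compartments.label_map.values == label])
    print(f"  {name:8s} {t:5.1f} s")

freq, bin_hz = kidney_perfusion_frequency(seed=0, duration_s=60.0, frame_rate_hz=5.0)
print(f"dominant kidney-VOI frequency in 0.2-1.5 Hz: {freq:.2f} Hz "
      f"(FFT bin {bin_hz:.3f} Hz)")
print("-> the bolus reaches the compartments in vessel < kidney < liver order,")
print("   and the 0.7 Hz respiratory modulation survives the analysis chain.")
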