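"""Microsphere resolution under full, cluster, and sparse apertures.

Simulates a 50 um microsphere at the array center, reconstructs it by
delay-and-sum on a 0.1 mm grid with each element subset, and measures
the full width at half maximum along each axis.  A 64^3 grid keeps the
example fast; the study is the same at 96^3 or 128^3.
"""

from hemipact.workflows import resolution_study

result = resolution_study(grid_edge=64)
print("FWHM of the reconstructed microsphere (um):")
print(f"{'aperture':10s} {'x':>7s} {'y':>7s} {'z':>7s}")
for mode, fwhm in result.fwhm_mm.items():
    x, y, z = (v * 1e3 for v in fwhm)
    print(f"{mode:10s} {x:7.0f} {y:7.0f} {z:7.0f}")
print("-> full and sparse views resolve nearly isotropically; the polar cluster")
print("   blurs laterally (limited view) while sharpening along its axis (z).")
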