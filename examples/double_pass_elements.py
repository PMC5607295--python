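"""Theoretical double-pass Mueller matrices of known optical elements.

The probe is validated against samples whose Mueller matrix is known in
closed form: a linear polariser and a quarter-wave plate, each traversed
twice with a mirror reflection in between.  Composition happens in the
full 4x4 calculus (the return pass sees the element axis at 180 - theta)
before the measurable 3x3 linear block is extracted.
"""

import numpy as np

import polarprobe as pp

np.set_printoptions(precision=3, suppress=True)

pol = pp.linear_submatrix(pp.double_pass("polariser", 45.0))
print("45-deg linear polariser double pass:")
print(pol)
print(f"-> m11 = {pol[0, 0]:.2f}: half the light survives the first pass;")
print("   the +/-0.5 corner elements encode the 45-deg projection with the")
print("   U sign flipped by the mirror's helicity reversal.\n")

qwp = pp.linear_submatrix(pp.double_pass("retarder", 45.0, 0.27 * 360.0))
print("Quarter-wave plate (0.27 wavelengths) double pass, fast axis 45 deg:")
print(qwp)
print(f"-> m22 = {qwp[1, 1]:.2f} = cos(2 x 97.2 deg): the double pass doubles")
print("   the single-pass retardance; m33 = -1 from the helicity flip.\n")

ret = pp.linear_submatrix(pp.double_pass("retarder", 90.0, 30.0))
print("30-deg retarder double pass, fast axis vertical:")
print(ret)
print("-> diag(1, 1, -0.5): the measured retardance of this matrix is")
print("   arccos(-0.5) = 120 deg although the physical round-trip retardance")
print("   is only 2 x 30 = 60 deg (see decompose_tissue_like.py).")
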