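"""Recover a release train from a cumulative secretion signal.

A cell releasing cytokine into a nanoliter well produces a cumulative
fluorescence signal: every past release keeps contributing through the
staining kinetics A(t).  Deconvolution inverts that convolution and
returns the amount released in each time bin.
"""

import numpy as np

from qlcis import builtin_calibrations, deconvolve, forward_convolve
from qlcis.deconvolve import DssTrace

model = builtin_calibrations()["human-IL-5"]

# ground truth: a burst at 5 h followed by a low sustained rate for 10 h
train = np.zeros(48)
train[5] = 20.0
train[6:16] = 1.5

dss_true = DssTrace(values=train, dt_frames=1, frame_interval=1.0, time_unit="h")
css = forward_convolve(dss_true, model)          # what the microscope sees
recovered = deconvolve(css, model, dt_frames=1)  # what the cell did

print("bin  true  recovered")
for t in range(4, 18):
    print(f"{t:3d} {train[t]:6.2f} {recovered.values[t]:10.6f}")
print(f"max abs error: {np.max(np.abs(recovered.values - train)):.2e}")
print(f"clamped mass (should be 0 on noiseless input): {recovered.clamped_mass}")

# The recovered train matches the truth to float precision: the burst at
# bin 5 and the 1.5-unit sustained rate are separated cleanly even though
# the cumulative signal itself never decreases.
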