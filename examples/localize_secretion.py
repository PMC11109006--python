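"""Localize secretion relative to the cell from spot images.

Renders secretion-spot images whose source sits 3 um right and 4 um below
the (moving) cell centroid, fits a 2D Gaussian per frame, and measures the
spot-to-cell displacement: a 3-4-5 triangle, so the median distance is 5 um.
"""

import numpy as np

from qlcis import CellTrack, displacement_series, fit_dss_gaussian
from qlcis.simulate import render_spot_stack

rng = np.random.default_rng(0)
T = 24
# cell random-walks around the well center (80 um well, 5 um binned pixels)
cell = np.cumsum(rng.normal(0, 0.8, (T, 2)), axis=0) + 40.0
amplitudes = np.full(T, 15.0)

stack = render_spot_stack(amplitudes, cell, source_offset_um=(3.0, 4.0),
                          image_size_px=16, pixel_size_um=5.0,
                          noise_sd=1.0, seed=1)

fits = {t: fit_dss_gaussian(stack[t], pixel_size_um=5.0, min_peak=3.0)
        for t in range(T)}
track = CellTrack(frames=np.arange(T), x_um=cell[:, 0], y_um=cell[:, 1])
summary = displacement_series(fits, track)

print(f"valid fits: {summary.distances_um.size}/{T}")
print(f"median displacement: {summary.median_um:.2f} um "
      f"(IQR {summary.q1_um:.2f}-{summary.q3_um:.2f})")

# With a true offset of (3, 4) um the median displacement is ~5 um; the
# spread around it reflects localization noise at this signal-to-noise,
# which shrinks as the spot brightens.
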