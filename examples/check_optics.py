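"""Validate the TIR illumination window of a dish configuration.

Total internal reflection at the well floor requires the excitation light
to arrive beyond the critical angle of every sample-side material, while
the objective can only deliver light up to its aperture limit.  A dish is
viable when the window between the largest critical angle and the aperture
limit is non-empty.
"""

from qlcis import validation_table

rows = validation_table(
    n_glass=1.52,          # coverslip
    n_sample=1.33,         # aqueous medium
    n_structure=1.40,      # PDMS well microstructure
    n_matching_layer=1.34, # amorphous fluoropolymer index-matching layer
    numerical_aperture=1.49,
)
for label, angle in rows:
    print(f"{label:35s} {angle:6.1f} deg")

# The PDMS/glass critical angle (67.1 deg) sits uncomfortably close to the
# aperture limit (78.6 deg) for a low-directivity LED source; inserting the
# n = 1.34 matching layer lowers the critical angle to 61.8 deg, widening
# the usable incidence window by ~5 deg.
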