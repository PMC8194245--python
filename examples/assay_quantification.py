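"""Closed-form bench quantifications: 2^-ddCt and caliper tumor volume."""

from cernascreen import (
    CaliperMeasurement,
    DdctInput,
    relative_expression_ddct,
    tumor_volume,
)

# knockdown qPCR: target gene vs reference gene, treated vs control
knockdown = DdctInput(
    ct_target_case=24.1, ct_reference_case=18.0,
    ct_target_control=22.6, ct_reference_control=18.1,
)
fold = relative_expression_ddct(knockdown)
print(f"2^-ddCt relative expression: {fold:.3f}")
print("  < 1 means the target is depleted in the treated sample "
      "relative to control, after reference-gene normalization")

# xenograft caliper reading
m = CaliperMeasurement(length=10.0, width=6.0)
print(f"tumor volume for length=10 mm, width=6 mm: {tumor_volume(m):.0f} mm^3")
# V = length x width^2 / 2 approximates the volume of an ellipsoidal
# subcutaneous tumor from a two-axis caliper measurement.
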