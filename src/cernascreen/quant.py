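"""Closed-form assay quantifications: 2^-ddCt fold change and caliper
tumor volume."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DdctInput:
    """qPCR cycle thresholds (cycles) for the four-well ddCt design:
    target and reference gene, in case and control conditions."""

    ct_target_case: float
    ct_reference_case: float
    ct_target_control: float
    ct_reference_control: float

    def __post_init__(self) -> None:
        for name in (
            "ct_target_case", "ct_reference_case",
            "ct_target_control", "ct_reference_control",
        ):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a finite positive cycle count")


def relative_expression_ddct(inp: DdctInput) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt_case = Ct(target, case) - Ct(reference, case); dCt_control
    analogous; the fold change is ``2 ** -(dCt_case - dCt_control)``.
    One extra cycle of the case target (ddCt = 1) means half the
    expression.
    """
    dct_case = inp.ct_target_case - inp.ct_reference_case
    dct_control = inp.ct_target_control - inp.ct_reference_control
    return float(2.0 ** -(dct_case - dct_control))


@dataclass(frozen=True)
class CaliperMeasurement:
    """A caliper reading of a subcutaneous tumor, in mm (width <= length)."""

    length: float
    width: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.length) and self.length > 0):
            raise ValueError("length must be a positive number of mm")
        if not (np.isfinite(self.width) and self.width > 0):
            raise ValueError("width must be a positive number of mm")
        if self.width > self.length:
            raise ValueError("width must not exceed length")


def tumor_volume(m: CaliperMeasurement) -> float:
    """Ellipsoid-approximation tumor volume, mm^3: length * width^2 / 2."""
    return float(m.length * m.width**2 / 2.0)
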