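"""Two-group differential expression and the threshold filter.

The contrast statistic is deliberately simple: per feature, the log2
fold change is the difference of group means of ``log2(x + pseudocount)``
(tumor minus normal) and the p-value comes from a two-sided Welch
two-sample t-test on the same log2 values.  No multiple-testing
correction is applied; the screening rule is the raw
``|log2FC| >= 1 and p < 0.05`` cut, which is liberal by design and
documented as such.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Literal

import numpy as np
from scipy import stats

from .datatypes import DifferentialExpressionRecord, ExpressionMatrix

Direction = Literal["up", "down", "both"]


def compute_differential_expression(
    matrix: ExpressionMatrix,
    pseudocount: float = 1.0,
) -> list[DifferentialExpressionRecord]:
    """Welch-t differential expression, tumor vs normal, on log2 values.

    Requires at least two samples per group.  A feature with zero
    variance in both groups gets ``p_value = 1`` with a warning.
    """
    tumor = matrix.samples_in_group("tumor")
    normal = matrix.samples_in_group("normal")
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got tumor={len(tumor)} normal={len(normal)}"
        )
    log2 = matrix.log2_values(pseudocount=pseudocount)
    xt = log2[tumor].to_numpy(dtype=float)
    xn = log2[normal].to_numpy(dtype=float)
    log2fc = xt.mean(axis=1) - xn.mean(axis=1)

    with warnings.catch_warnings():
        # constant-input features are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(xt, xn, axis=1, equal_var=False)

    records = []
    for i, feature_id in enumerate(matrix.feature_ids):
        pi = p[i]
        if not np.isfinite(pi):
            if xt[i].var() == 0 and xn[i].var() == 0:
                warnings.warn(
                    f"feature {feature_id!r} has zero variance in both groups; "
                    "p_value set to 1",
                    stacklevel=2,
                )
            pi = 1.0
        records.append(
            DifferentialExpressionRecord(
                feature_id=feature_id,
                feature_class=matrix.feature_class[feature_id],
                log2fc=float(log2fc[i]),
                p_value=float(min(max(pi, np.nextafter(0, 1)), 1.0)),
            )
        )
    return records


def apply_de_filter(
    records: Iterable[DifferentialExpressionRecord],
    min_abs_log2fc: float = 1.0,
    max_p: float = 0.05,
    direction: Direction = "both",
) -> list[DifferentialExpressionRecord]:
    """Keep records with ``|log2fc| >= min_abs_log2fc``, ``p < max_p`` and
    the requested sign (``up``: log2fc > 0, ``down``: log2fc < 0)."""
    if min_abs_log2fc < 0:
        raise ValueError("min_abs_log2fc must be >= 0")
    if not (0.0 < max_p < 1.0):
        raise ValueError("max_p must lie in (0, 1)")
    if direction not in ("up", "down", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    kept = []
    for r in records:
        if abs(r.log2fc) < min_abs_log2fc or r.p_value >= max_p:
            continue
        if direction == "up" and not r.log2fc > 0:
            continue
        if direction == "down" and not r.log2fc < 0:
            continue
        kept.append(r)
    return kept
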