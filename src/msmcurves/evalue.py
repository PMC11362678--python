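"""E-values for unmeasured confounding on the risk-ratio scale.

The E-value is the minimum strength of association (risk ratio) that an
unmeasured confounder would need to have with both exposure and outcome,
above and beyond the measured covariates, to fully explain away an observed
risk ratio: E = RR + sqrt(RR * (RR - 1)) for RR >= 1, with protective risk
ratios transformed to their reciprocal first.  The E-value for a confidence
interval is computed on the limit closer to the null and equals 1 when the
interval crosses the null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = ["EValueResult", "compute_evalue"]


@dataclass
class EValueResult:
    rr_input: float
    evalue_point: float
    evalue_ci: Optional[float]
    transformed: bool        # True when rr_input < 1 was inverted

    def __str__(self):
        note = " (computed on 1/RR)" if self.transformed else ""
        ci = "" if self.evalue_ci is None else f", CI limit: {self.evalue_ci:.2f}"
        return f"E-value point: {self.evalue_point:.2f}{ci}{note}"


def _evalue_rr(rr: float) -> float:
    if rr < 1.0:
        rr = 1.0 / rr
    return rr + math.sqrt(rr * (rr - 1.0))


def compute_evalue(rr: float, ci_lower: Optional[float] = None,
                   ci_upper: Optional[float] = None) -> EValueResult:
    """E-value for a risk ratio and (optionally) its confidence interval.

    Parameters
    ----------
    rr : float
        Observed risk ratio (> 0).
    ci_lower, ci_upper : float, optional
        Positive confidence limits with ``ci_lower <= ci_upper``.

    Returns
    -------
    EValueResult
        ``evalue_point`` >= 1 always; ``evalue_ci`` is computed on the
        limit closer to the null and is 1.0 when the CI includes 1.

    Examples
    --------
    >>> res = compute_evalue(4.00, 1.83, 7.41)
    >>> round(res.evalue_point, 2), round(res.evalue_ci, 2)
    (7.46, 3.06)
    """
    if not rr > 0:
        raise ValueError("risk ratio must be positive")
    transformed = rr < 1.0
    point = _evalue_rr(rr)

    evalue_ci = None
    if ci_lower is not None or ci_upper is not None:
        if ci_lower is None or ci_upper is None:
            raise ValueError("provide both confidence limits or neither")
        if not (ci_lower > 0 and ci_upper > 0):
            raise ValueError("confidence limits must be positive")
        if ci_lower > ci_upper:
            raise ValueError("ci_lower must not exceed ci_upper")
        if ci_lower <= 1.0 <= ci_upper:
            evalue_ci = 1.0
        elif ci_lower > 1.0:
            evalue_ci = _evalue_rr(ci_lower)
        else:
            evalue_ci = _evalue_rr(ci_upper)
    return EValueResult(rr, point, evalue_ci, transformed)
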