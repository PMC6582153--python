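"""Head-accounting statistics for the sequestered (SRX) myosin pool.

Two independent routes quantify how a mutation releases sequestered heads:

* kcat route — the 25-hep : 2-hep kcat ratio ``r`` estimates the open head
  fraction, so ``100 (1 - r)`` is the percent sequestered, and a mutant's
  conversion of the wild-type sequestered pool is
  ``100 (r_mut - r_wt) / (1 - r_wt)``.

* amplitude route — single-turnover fast fractions give SRX = 100 - fast,
  and the percent decrease of the SRX pool is
  ``100 (SRX_wt - SRX_mut) / SRX_wt``.

When fast fractions and kcat ratios derive from the same two-state
bookkeeping (ratio = fast fraction / 100) the two routes agree exactly.

Reported percentages are clamped to [0, 100]; every clamp is flagged and
the raw value retained.  Rounding to integer percent happens only in the
reporting layer (``round_half_up``).
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .datatypes import ConversionResult, KcatRatio, TestResult

__all__ = [
    "sequestered_from_ratio",
    "conversion_from_ratios",
    "srx_decrease_from_fractions",
    "compare_groups",
    "round_half_up",
]


def round_half_up(x: float, digits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed reports)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _clamp_pct(raw: float) -> tuple[float, bool]:
    clamped = min(max(raw, 0.0), 100.0)
    return clamped, clamped != raw


def sequestered_from_ratio(ratio: KcatRatio | float) -> ConversionResult:
    """Percent of heads sequestered implied by a 25-hep : 2-hep kcat ratio.

    Returns 100 (1 - ratio), clamped to [0, 100] with a flag (a ratio above
    1, e.g. R719W's 1.03, clamps to 0% sequestered).
    """
    r = ratio.ratio if isinstance(ratio, KcatRatio) else float(ratio)
    if not math.isfinite(r):
        raise ValueError("ratio must be finite")
    raw = 100.0 * (1.0 - r)
    value, capped = _clamp_pct(raw)
    return ConversionResult(
        sequestered_fraction_pct=value,
        raw_sequestered_pct=raw,
        capped_flag=capped,
        source="kcat_ratio",
    )


def conversion_from_ratios(ratio_mut: float, ratio_wt: float) -> ConversionResult:
    """Percent of the WT sequestered pool converted to open heads.

    100 (ratio_mut - ratio_wt) / (1 - ratio_wt), capped at 100 and floored
    at 0 with flags.  Requires ratio_wt < 1 (otherwise WT has no sequestered
    pool to convert).
    """
    if not (math.isfinite(ratio_mut) and math.isfinite(ratio_wt)):
        raise ValueError("ratios must be finite")
    if ratio_wt >= 1.0:
        raise ValueError("no WT sequestered pool: ratio_wt must be < 1")
    raw = 100.0 * (ratio_mut - ratio_wt) / (1.0 - ratio_wt)
    value, capped = _clamp_pct(raw)
    return ConversionResult(
        conversion_pct=value,
        raw_conversion_pct=raw,
        capped_flag=capped,
        source="kcat_ratio",
    )


def srx_decrease_from_fractions(fast_wt_pct: float, fast_mut_pct: float) -> ConversionResult:
    """Percent decrease of the SRX pool from single-turnover fast fractions.

    SRX = 100 - fast for each construct; returns
    100 (SRX_wt - SRX_mut) / SRX_wt, floored at 0 (and capped at 100) with
    flags.  Requires fast_wt_pct < 100.
    """
    for name, v in (("fast_wt_pct", fast_wt_pct), ("fast_mut_pct", fast_mut_pct)):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"{name} must lie in [0, 100], got {v!r}")
    if fast_wt_pct >= 100.0:
        raise ValueError("WT has no SRX pool: fast_wt_pct must be < 100")
    srx_wt = 100.0 - fast_wt_pct
    srx_mut = 100.0 - fast_mut_pct
    raw = 100.0 * (srx_wt - srx_mut) / srx_wt
    value, capped = _clamp_pct(raw)
    return ConversionResult(
        srx_decrease_pct=value,
        raw_srx_decrease_pct=raw,
        capped_flag=capped,
        source="turnover_amplitudes",
    )


def compare_groups(a, b, equal_var: bool = False) -> TestResult:
    """Two-sided two-sample t-test (Welch by default; set ``equal_var`` for
    the classical pooled-variance Student form).

    Two zero-variance samples with equal means return p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return TestResult(statistic=0.0, p_value=1.0, df=float(a.size + b.size - 2))
        return TestResult(statistic=float("inf"), p_value=0.0, df=float(a.size + b.size - 2))
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue), df=float(res.df))
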