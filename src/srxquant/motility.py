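"""Motility-assay velocity summaries.

Filament-tracking software emits one velocity per tracked filament; the
field's headline statistic is the mean of the fastest 5% of filaments,
which suppresses stuck or poorly tracked filaments and reflects the
unloaded gliding velocity of fully active motor fields.
"""

from __future__ import annotations

import math

import numpy as np

from .accounting import compare_groups
from .datatypes import TestResult, VelocityTable

__all__ = ["top_fraction_velocity", "compare_velocities"]


def top_fraction_velocity(
    table: VelocityTable, fraction: float = 0.05, rounding: str = "ceil"
) -> float:
    """Mean of the largest ``ceil(fraction * n)`` velocities (nm/s).

    ``rounding='floor'`` selects ``floor(fraction * n)`` instead (must keep
    at least one filament).  ``fraction = 1`` reduces to the arithmetic mean.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    n = table.velocities.size
    if rounding == "ceil":
        k = math.ceil(fraction * n)
    elif rounding == "floor":
        k = math.floor(fraction * n)
    else:
        raise ValueError("rounding must be 'ceil' or 'floor'")
    if k < 1:
        raise ValueError(f"top fraction {fraction} of {n} filaments selects no filament")
    top = np.sort(table.velocities)[-k:]
    return float(top.mean())


def compare_velocities(
    a: list[VelocityTable], b: list[VelocityTable], fraction: float = 0.05
) -> TestResult:
    """t-test on per-movie top-fraction velocities of two constructs.

    Each construct must contribute at least two movies; the unit of
    comparison is the movie-level statistic, not individual filaments.
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 movies per construct")
    stats_a = [top_fraction_velocity(t, fraction) for t in a]
    stats_b = [top_fraction_velocity(t, fraction) for t in b]
    return compare_groups(stats_a, stats_b)
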