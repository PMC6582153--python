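"""Container types shared across the pipeline.

All containers are plain dataclasses holding numpy arrays / scalars.  A
``metadata`` dict travels with every experimental record; synthetic
generators stash their ground-truth parameters there so parameter-recovery
tests can compare against it, but no fitting routine ever reads it.

Rate-sign convention: decays are written ``a * exp(-k t)`` with positive
rate constants ``k`` (units s^-1) everywhere.  A fitted exponent ``b`` of a
raw ``exp(b t)`` parameterisation therefore corresponds to ``k = -b``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TurnoverGroundTruth",
    "SamplingSchedule",
    "FluorescenceTrace",
    "ExponentialFit",
    "ModelChoice",
    "TurnoverSummary",
    "ATPaseTitration",
    "PiTimeCourse",
    "MichaelisMentenFit",
    "KcatRatio",
    "ConversionResult",
    "BindingIsotherm",
    "HillFit",
    "VelocityTable",
    "TestResult",
]


def _require_finite(name: str, value: float) -> None:
    if not np.isfinite(value):
        raise ValueError(f"parameter {name!r} must be finite, got {value!r}")


@dataclass(frozen=True)
class TurnoverGroundTruth:
    """True parameters of a two-phase single-turnover decay.

    ``slow_fraction``/``fast_fraction`` are the SRX and DRX head fractions
    (dimensionless, sum to 1); rates are positive first-order rate
    constants in s^-1 with ``fast_rate > slow_rate``.
    """

    slow_fraction: float
    fast_fraction: float
    slow_rate: float
    fast_rate: float
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("slow_fraction", "fast_fraction", "slow_rate", "fast_rate", "noise_sd"):
            _require_finite(name, getattr(self, name))
        if abs(self.slow_fraction + self.fast_fraction - 1.0) > 1e-12:
            raise ValueError(
                "slow_fraction + fast_fraction must equal 1 within 1e-12, got "
                f"{self.slow_fraction + self.fast_fraction!r}"
            )
        if not (0.0 <= self.slow_fraction <= 1.0 and 0.0 <= self.fast_fraction <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if not (self.fast_rate > self.slow_rate > 0.0):
            raise ValueError(
                f"require fast_rate > slow_rate > 0, got fast_rate={self.fast_rate}, "
                f"slow_rate={self.slow_rate}"
            )
        if self.noise_sd < 0.0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class SamplingSchedule:
    """Plate-reader sampling: one point every ``interval`` s for ``duration`` s.

    ``chase_delay`` records the dead time before the cold-ATP chase; the
    generated time axis starts at the chase (t = 0), so the delay is
    bookkeeping only.
    """

    interval: float = 2.0
    duration: float = 960.0
    chase_delay: float = 10.0

    def __post_init__(self) -> None:
        if self.interval <= 0 or self.duration <= 0:
            raise ValueError("interval and duration must be positive")
        if self.chase_delay < 0:
            raise ValueError("chase_delay must be non-negative")
        if self.duration <= self.interval or self.n_points < 10:
            raise ValueError("schedule must yield at least 10 samples")

    @property
    def n_points(self) -> int:
        return int(np.floor(self.duration / self.interval)) + 1

    def times(self) -> np.ndarray:
        return np.arange(self.n_points, dtype=float) * self.interval


@dataclass
class FluorescenceTrace:
    """One mant-ATP chase time series for one construct/replicate."""

    times: np.ndarray
    values: np.ndarray
    construct_label: str = ""
    replicate_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size < 10:
            raise ValueError("trace needs at least 10 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")


@dataclass
class ExponentialFit:
    """Least-squares multi-exponential decay fit.

    ``amplitudes``/``rates`` are canonically ordered slow phase first.
    ``offset`` is the fitted long-time plateau (0 when fixed).
    """

    n_components: int
    amplitudes: np.ndarray
    rates: np.ndarray
    offset: float
    residual_sse: float
    converged: bool
    information_criterion: float
    n_points: int = 0
    message: str = ""

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.n_components not in (1, 2):
            raise ValueError("n_components must be 1 or 2")
        if self.amplitudes.size != self.n_components or self.rates.size != self.n_components:
            raise ValueError("amplitudes/rates length must equal n_components")

    def model(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.offset)
        for a, k in zip(self.amplitudes, self.rates):
            out = out + a * np.exp(-k * t)
        return out


@dataclass(frozen=True)
class ModelChoice:
    """Outcome of single- vs double-exponential model selection."""

    n_components: int
    criterion_difference: float  # IC(2) - IC(1); negative favours 2


@dataclass
class TurnoverSummary:
    """Fast (DRX) / slow (SRX) head fractions, in percent of total amplitude."""

    fast_fraction_pct: float
    slow_fraction_pct: float
    fast_rate: float
    slow_rate: float
    sem_fast_pct: float = 0.0
    n_replicates: int = 1
    replicate_id: str = ""
    construct_label: str = ""
    ambiguous_assignment: bool = False

    def __post_init__(self) -> None:
        if abs(self.fast_fraction_pct + self.slow_fraction_pct - 100.0) > 0.01:
            raise ValueError("fast and slow percentages must sum to 100 within 0.01")


@dataclass
class ATPaseTitration:
    """Actin-activated ATPase rates (s^-1 per head) vs actin concentration (µM)."""

    actin_concs: np.ndarray
    rates: np.ndarray
    construct_label: str = ""
    replicate_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.actin_concs = np.asarray(self.actin_concs, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.actin_concs.shape != self.rates.shape:
            raise ValueError("actin_concs and rates must have equal length")
        if np.any(self.actin_concs < 0):
            raise ValueError("actin concentrations must be non-negative")
        if np.unique(self.actin_concs).size < 4:
            raise ValueError("need at least 4 distinct actin concentrations")


@dataclass
class PiTimeCourse:
    """Inorganic-phosphate production time course at one actin concentration."""

    times: np.ndarray
    phosphate: np.ndarray
    actin_conc: float
    myosin_conc: float  # µM of heads

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.phosphate = np.asarray(self.phosphate, dtype=float)
        if self.times.shape != self.phosphate.shape:
            raise ValueError("times and phosphate must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class MichaelisMentenFit:
    """kcat/KM estimate with bootstrap uncertainties."""

    kcat: float
    km: float
    basal: float
    kcat_err: float = 0.0
    km_err: float = 0.0
    n_boot: int = 0
    seed: int = 0
    converged: bool = True
    extrapolated: bool = False
    construct_label: str = ""
    replicate_id: str = ""


@dataclass(frozen=True)
class KcatRatio:
    """25-hep over 2-hep kcat ratio with first-order propagated error."""

    ratio: float
    ratio_err: float = 0.0


@dataclass
class ConversionResult:
    """Head-accounting statistics derived from kcat ratios or amplitudes.

    Raw (uncapped) values are retained; the reported value is clamped to
    [0, 100] with ``capped_flag`` set whenever clamping changed it.
    """

    sequestered_fraction_pct: float = float("nan")
    conversion_pct: float = float("nan")
    srx_decrease_pct: float = float("nan")
    source: str = "kcat_ratio"  # or "turnover_amplitudes"
    mutant_label: str = ""
    wt_label: str = ""
    capped_flag: bool = False
    raw_conversion_pct: float = float("nan")
    raw_sequestered_pct: float = float("nan")
    raw_srx_decrease_pct: float = float("nan")


@dataclass
class BindingIsotherm:
    """MST dose-response points: normalized fluorescence vs titrant (µM)."""

    titrant_concs: np.ndarray
    responses: np.ndarray
    construct_label: str = ""
    replicate_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.titrant_concs = np.asarray(self.titrant_concs, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.titrant_concs.shape != self.responses.shape:
            raise ValueError("titrant_concs and responses must have equal length")
        if np.any(self.titrant_concs <= 0):
            raise ValueError("titrant concentrations must be positive")
        if self.titrant_concs.size < 8:
            raise ValueError("need at least 8 titrant concentrations")
        span = self.titrant_concs.max() / self.titrant_concs.min()
        if span < 100.0:
            raise ValueError(f"titration must span >= 100-fold, got {span:.3g}-fold")


@dataclass
class HillFit:
    """Hill-equation fit of a binding isotherm."""

    kd: float
    hill: float
    baseline: float
    amplitude: float
    kd_err: float = 0.0
    converged: bool = True
    out_of_range: bool = False
    message: str = ""
    construct_label: str = ""
    replicate_id: str = ""


@dataclass
class VelocityTable:
    """Per-filament velocities (nm/s) from one motility movie."""

    velocities: np.ndarray
    construct_label: str = ""
    movie_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.velocities.size < 1:
            raise ValueError("velocity table is empty")
        if not np.all(np.isfinite(self.velocities)) or np.any(self.velocities <= 0):
            raise ValueError("velocities must be finite and positive")


@dataclass(frozen=True)
class TestResult:
    """Two-sample t-test outcome."""

    statistic: float
    p_value: float
    df: float


ReplicateDesign = dict  # replicate_id -> biological-group label


def hierarchical_mean_sem(
    values: Sequence[float], replicate_ids: Sequence[str], design: dict | None
) -> tuple[float, float, int]:
    """Average technical replicates within biological groups, then report the
    mean and SEM across biological-group means.

    With no ``design``, every value is its own biological replicate (pooled
    SEM).  Returns (mean, sem, n_biological).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values to aggregate")
    if design is None:
        groups = {rid if rid else str(i): [v] for i, (rid, v) in enumerate(zip(replicate_ids, values))}
    else:
        groups: dict[str, list[float]] = {}
        for rid, v in zip(replicate_ids, values):
            groups.setdefault(str(design.get(rid, rid)), []).append(v)
    bio_means = np.array([np.mean(g) for g in groups.values()])
    mean = float(np.mean(bio_means))
    n = bio_means.size
    sem = float(np.std(bio_means, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return mean, sem, n
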