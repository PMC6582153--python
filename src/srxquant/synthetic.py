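"""Synthetic data generators for every input kind the pipeline consumes.

Each generator evaluates a closed-form model (two-phase exponential decay,
Michaelis–Menten saturation, Hill binding, truncated-normal velocities),
adds i.i.d. Gaussian noise, and stores its ground-truth parameters in the
output ``metadata`` so fitting stages can be validated by parameter
recovery.  Fitters never read that record.

``CONSTRUCT_PRESETS`` encodes the study conditions for the recombinant
human β-cardiac myosin constructs: two-headed HMM molecules carrying
either 2 or 25 heptad repeats of proximal S2.  Only the 25-hep construct
can fold back into the sequestered (SRX) state, which is what the preset
fast/slow fractions and kcat values reflect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import (
    ATPaseTitration,
    BindingIsotherm,
    FluorescenceTrace,
    SamplingSchedule,
    TurnoverGroundTruth,
    VelocityTable,
)

__all__ = [
    "generate_turnover_trace",
    "generate_mm_titration",
    "generate_mst_isotherm",
    "generate_velocity_sample",
    "turnover_preset",
    "CONSTRUCT_PRESETS",
    "ConstructPreset",
    "DEFAULT_ACTIN_GRID",
    "DEFAULT_TITRANT_GRID",
    "NOMINAL_FAST_RATE",
    "NOMINAL_SLOW_RATE",
]

# Nominal single-turnover rates: open (DRX) heads release mant-nucleotide at
# the basal ~0.03 s^-1 rate, sequestered (SRX) heads at ~0.003 s^-1.
NOMINAL_FAST_RATE = 0.03
NOMINAL_SLOW_RATE = 0.003

# Actin titration grid (µM): log-ish spacing over the experimental 0-80 µM range.
DEFAULT_ACTIN_GRID = (0.0, 2.5, 5.0, 10.0, 20.0, 40.0, 80.0)

# MST titrant grid (µM): 16 capillaries, ~1.6-fold serial dilution spanning
# 1-1000 µM (1000-fold), bracketing the double-digit-µM affinities measured.
DEFAULT_TITRANT_GRID = tuple(float(10.0 ** (0.2 * i)) for i in range(16))


@dataclass(frozen=True)
class ConstructPreset:
    """Study conditions for one construct (e.g. ``WT-25hep``)."""

    fast_fraction: float  # DRX fraction of single-turnover amplitude
    kcat: float  # s^-1 per head, actin-activated
    km: float = 15.0  # µM actin
    basal: float = 0.03  # s^-1, rate at zero actin
    kd: float | None = None  # µM, proximal-S2 affinity (2-hep constructs only)
    velocity: float | None = None  # nm/s, top-5% gliding velocity


# Fast-phase fractions and kcat values per construct.  2-hep HMM cannot fold
# back, so all 2-hep constructs sit near 80% fast; 25-hep kcat equals the
# construct's kcat ratio times its 2-hep kcat.
CONSTRUCT_PRESETS: dict[str, ConstructPreset] = {
    "WT-2hep": ConstructPreset(0.81, 2.4, kd=37.0, velocity=700.0),
    "WT-25hep": ConstructPreset(0.41, 0.57 * 2.4),
    "R249Q-2hep": ConstructPreset(0.80, 2.4),
    "R249Q-25hep": ConstructPreset(0.79, 0.96 * 2.4),
    "H251N-2hep": ConstructPreset(0.80, 2.4),
    "H251N-25hep": ConstructPreset(0.65, 0.91 * 2.4),
    "D382Y-2hep": ConstructPreset(0.80, 2.4, kd=45.0),
    "D382Y-25hep": ConstructPreset(0.68, 0.84 * 2.4),
    "R719W-2hep": ConstructPreset(0.80, 2.4, kd=58.0),
    "R719W-25hep": ConstructPreset(0.81, 1.03 * 2.4),
    "I457T-2hep": ConstructPreset(0.82, 4.2, velocity=1700.0),
    "I457T-25hep": ConstructPreset(0.56, 0.56 * 4.2),
}


def turnover_preset(construct: str, noise_sd: float = 0.01, seed: int = 0) -> TurnoverGroundTruth:
    """Ground truth for a named construct's single-turnover decay."""
    try:
        preset = CONSTRUCT_PRESETS[construct]
    except KeyError:
        raise KeyError(
            f"unknown construct {construct!r}; known: {sorted(CONSTRUCT_PRESETS)}"
        ) from None
    return TurnoverGroundTruth(
        slow_fraction=1.0 - preset.fast_fraction,
        fast_fraction=preset.fast_fraction,
        slow_rate=NOMINAL_SLOW_RATE,
        fast_rate=NOMINAL_FAST_RATE,
        noise_sd=noise_sd,
        seed=seed,
    )


def generate_turnover_trace(
    truth: TurnoverGroundTruth,
    schedule: SamplingSchedule = SamplingSchedule(),
    construct_label: str = "",
    replicate_id: str = "",
) -> FluorescenceTrace:
    """Simulate a normalized mant-ATP chase decay.

    F(t) = slow_fraction * exp(-slow_rate t) + fast_fraction * exp(-fast_rate t)
    plus Gaussian(0, noise_sd), sampled on the schedule's grid with t = 0 at
    the cold-ATP chase.  Deterministic given ``truth.seed``.
    """
    t = schedule.times()
    clean = truth.slow_fraction * np.exp(-truth.slow_rate * t) + truth.fast_fraction * np.exp(
        -truth.fast_rate * t
    )
    rng = np.random.default_rng(truth.seed)
    values = clean + rng.normal(0.0, truth.noise_sd, size=t.size) if truth.noise_sd > 0 else clean
    return FluorescenceTrace(
        times=t,
        values=values,
        construct_label=construct_label,
        replicate_id=replicate_id,
        metadata={"ground_truth": truth, "schedule": schedule},
    )


def generate_mm_titration(
    kcat: float,
    km: float,
    basal: float,
    actin_concs=DEFAULT_ACTIN_GRID,
    noise_sd: float = 0.0,
    seed: int = 0,
    construct_label: str = "",
    replicate_id: str = "",
) -> ATPaseTitration:
    """Simulate an actin-activated ATPase titration.

    rate([A]) = basal + kcat [A] / (km + [A]) + Gaussian(0, noise_sd).
    """
    for name, v in (("kcat", kcat), ("km", km)):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be a positive finite number, got {v!r}")
    if basal < 0:
        raise ValueError("basal must be non-negative")
    concs = np.asarray(actin_concs, dtype=float)
    if concs.size == 0:
        raise ValueError("actin_concs must be non-empty")
    if np.any(concs < 0):
        raise ValueError("negative actin concentrations rejected")
    clean = basal + kcat * concs / (km + concs)
    rng = np.random.default_rng(seed)
    rates = clean + rng.normal(0.0, noise_sd, size=concs.size) if noise_sd > 0 else clean
    return ATPaseTitration(
        actin_concs=concs,
        rates=rates,
        construct_label=construct_label,
        replicate_id=replicate_id,
        metadata={"ground_truth": {"kcat": kcat, "km": km, "basal": basal, "noise_sd": noise_sd, "seed": seed}},
    )


def generate_mst_isotherm(
    kd: float,
    hill: float = 1.0,
    baseline: float = 0.0,
    amplitude: float = 1.0,
    titrant_concs=DEFAULT_TITRANT_GRID,
    noise_sd: float = 0.0,
    seed: int = 0,
    construct_label: str = "",
    replicate_id: str = "",
) -> BindingIsotherm:
    """Simulate an MST dose-response isotherm.

    response(x) = baseline + amplitude x^h / (kd^h + x^h) + noise.  A ``kd``
    outside the titration range is allowed but recorded as a warning in the
    output metadata.
    """
    if not np.isfinite(kd) or kd <= 0:
        raise ValueError(f"kd must be a positive finite number, got {kd!r}")
    if not np.isfinite(hill) or hill <= 0:
        raise ValueError(f"hill must be a positive finite number, got {hill!r}")
    concs = np.asarray(titrant_concs, dtype=float)
    clean = baseline + amplitude * concs ** hill / (kd ** hill + concs ** hill)
    rng = np.random.default_rng(seed)
    resp = clean + rng.normal(0.0, noise_sd, size=concs.size) if noise_sd > 0 else clean
    meta: dict = {
        "ground_truth": {
            "kd": kd, "hill": hill, "baseline": baseline, "amplitude": amplitude,
            "noise_sd": noise_sd, "seed": seed,
        }
    }
    if not (concs.min() <= kd <= concs.max()):
        meta["warning"] = f"kd {kd} µM lies outside the titration range [{concs.min()}, {concs.max()}]"
    return BindingIsotherm(
        titrant_concs=concs,
        responses=resp,
        construct_label=construct_label,
        replicate_id=replicate_id,
        metadata=meta,
    )


def velocity_normal_from_top_fraction(
    top_value: float, cv: float = 0.15, fraction: float = 0.05
) -> tuple[float, float]:
    """Normal (mean, sd) whose top-``fraction`` mean equals ``top_value``.

    Filament trackers report the mean of the fastest ``fraction`` of
    filaments, so a printed velocity is an upper-tail statistic, not the
    population mean.  For a normal with coefficient of variation ``cv`` the
    expected mean of the top fraction q is mu + sd * phi(z_q) / q with
    z_q the (1-q) quantile; inverting gives the population parameters that
    make simulated movies reproduce the printed statistic.
    """
    from scipy.stats import norm

    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    z = norm.ppf(1.0 - fraction)
    tail_factor = norm.pdf(z) / fraction  # E[(X-mu)/sd | X in top fraction]
    mean = top_value / (1.0 + cv * tail_factor)
    return mean, cv * mean


def generate_velocity_sample(
    mean: float,
    sd: float,
    n: int,
    seed: int = 0,
    construct_label: str = "",
    movie_id: str = "",
) -> VelocityTable:
    """Draw ``n`` filament velocities from a normal truncated at zero."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if not np.isfinite(mean) or mean <= 0:
        raise ValueError(f"mean must be a positive finite number, got {mean!r}")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    if sd == 0:
        v = np.full(n, mean)
    else:
        v = np.empty(n)
        filled = 0
        while filled < n:  # rejection sampling keeps the draw exact
            draw = rng.normal(mean, sd, size=n - filled)
            draw = draw[draw > 0]
            v[filled: filled + draw.size] = draw
            filled += draw.size
    return VelocityTable(
        velocities=v,
        construct_label=construct_label,
        movie_id=movie_id,
        metadata={"ground_truth": {"mean": mean, "sd": sd, "n": n, "seed": seed}},
    )
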