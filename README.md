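# srxquant

Quantification of sequestered (SRX) versus open (DRX) β-cardiac myosin
heads from the four assay types used to study the folded-back
interacting-heads state of two-headed myosin constructs:

* **mant-ATP single-turnover decays** — a fluorescent-nucleotide chase in
  which open heads release mant-nucleotide at the basal rate
  (~0.03 s⁻¹) and sequestered heads ~10× slower (~0.003 s⁻¹).  Fitting

  F(t) = a₁·exp(−k_slow·t) + a₂·exp(−k_fast·t) + c

  splits the amplitude into slow (SRX) and fast (DRX) head fractions.
* **actin-activated ATPase titrations** — Michaelis–Menten fits
  (rate = basal + k_cat·[A]/(K_M + [A])) with case-bootstrap
  uncertainties.  The k_cat ratio of a 25-heptad construct (which can
  fold back onto its S2 tail) to its 2-heptad control (which cannot)
  estimates the open-head fraction, so 1 − ratio is the fraction
  sequestered.
* **MST binding isotherms** — Hill-equation fits
  (response = baseline + amplitude·xʰ/(K_Dʰ + xʰ)) of
  myosin–proximal-S2 affinity.
* **motility velocity tables** — the top-5% filament-velocity statistic.

From these, `srxquant.accounting` derives the head-accounting
percentages that summarize how a cardiomyopathy mutation releases heads
from the sequestered state:

* percent sequestered = 100·(1 − ratio)
* percent of the wild-type SRX pool converted
  = 100·(ratio_mut − ratio_wt)/(1 − ratio_wt), capped at 100% (flagged)
* SRX-pool decrease from single-turnover fractions
  = 100·(SRX_wt − SRX_mut)/SRX_wt

A synthetic-data module generates all four input kinds with known ground
truth (two-phase exponential decays, Michaelis–Menten saturation, Hill
binding, truncated-normal velocities, additive Gaussian noise), so every
fitting stage is validated by parameter recovery without any external
data.

## Worked example

```python
import numpy as np
from srxquant import synthetic, turnover, atpase, accounting

# Single turnover: what fraction of 25-hep heads is open (fast phase)?
truth = synthetic.turnover_preset("WT-25hep", noise_sd=0.01, seed=0)
trace = synthetic.generate_turnover_trace(truth)
fit = turnover.fit_exponentials(turnover.normalize_trace(trace))
summary = turnover.classify_phases(fit)
print(f"fast (DRX) fraction: {summary.fast_fraction_pct:.1f}%  "
      f"k_fast = {summary.fast_rate:.4f} /s  k_slow = {summary.slow_rate:.4f} /s")

# ATPase: kcat ratios of 25-hep constructs to their 2-hep controls
grid = np.repeat(synthetic.DEFAULT_ACTIN_GRID, 3)   # triplicate measurements
fits = {}
for i, label in enumerate(("WT-2hep", "WT-25hep", "H251N-2hep", "H251N-25hep")):
    p = synthetic.CONSTRUCT_PRESETS[label]
    titr = synthetic.generate_mm_titration(p.kcat, p.km, p.basal,
                                           actin_concs=grid, noise_sd=0.05, seed=10 + i)
    fits[label] = atpase.bootstrap_mm(titr, n_boot=100, seed=1)
r_wt = atpase.kcat_ratio(fits["WT-25hep"], fits["WT-2hep"])
r_mut = atpase.kcat_ratio(fits["H251N-25hep"], fits["H251N-2hep"])
print(f"WT ratio    = {r_wt.ratio:.2f} +/- {r_wt.ratio_err:.2f}")
print(f"H251N ratio = {r_mut.ratio:.2f} +/- {r_mut.ratio_err:.2f}")

# Head accounting
seq = accounting.sequestered_from_ratio(r_wt)
conv = accounting.conversion_from_ratios(r_mut.ratio, r_wt.ratio)
print(f"WT heads sequestered: {seq.sequestered_fraction_pct:.0f}%")
print(f"H251N converts {accounting.round_half_up(conv.conversion_pct):.0f}% of the WT SRX pool")
```

prints

```
fast (DRX) fraction: 40.0%  k_fast = 0.0314 /s  k_slow = 0.0031 /s
WT ratio    = 0.57 +/- 0.02
H251N ratio = 0.89 +/- 0.03
WT heads sequestered: 43%
H251N converts 75% of the WT SRX pool
```

The fitted fast fraction (40%) and rates recover the generating truth
(41%, 0.03/0.003 s⁻¹) from one noisy trace; the WT ratio 0.57 means 43%
of the tailed construct's heads are sequestered, and the mutant's higher
ratio corresponds to release of about three quarters of that pool.

## Command line

```sh
srxquant simulate --out-dir data --seed 3          # synthetic CSVs, all constructs
srxquant fit-turnover data/traces.csv              # per-replicate fast/slow fractions
srxquant fit-atpase data/titrations.csv            # kcat, KM with bootstrap errors
srxquant fit-mst data/isotherms.csv                # Hill Kd per isotherm
srxquant motility data/velocities.csv              # top-5% velocity per movie
srxquant report --traces data/traces.csv --titrations data/titrations.csv \
    --isotherms data/isotherms.csv --velocities data/velocities.csv \
    --out-dir out --seed 3                         # full per-variant summary + fit log
```

Input formats are plain CSV with fixed headers (see `srxquant.io.SCHEMAS`).

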