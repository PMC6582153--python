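"""Hill-equation fitting of MST binding isotherms.

The isotherm is the reduced dose-response: normalized fluorescence vs
titrant concentration.  The fitted model is

    response(x) = baseline + amplitude * x^h / (Kd^h + x^h)

with the Hill coefficient ``h`` bounded to [0.25, 4] (free by default, or
fixable, e.g. h = 1 for a Langmuir isotherm).  Reported Kd uncertainties
come from across-replicate SEM, not per-fit covariance, matching how
replicate binding experiments are usually summarised.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit

from .datatypes import BindingIsotherm, HillFit, hierarchical_mean_sem

__all__ = ["fit_hill", "fold_change", "aggregate_kd", "HILL_BOUNDS"]

HILL_BOUNDS = (0.25, 4.0)


def _hill_model(x, kd, h, baseline, amplitude):
    xh = x ** h
    return baseline + amplitude * xh / (kd ** h + xh)


def fit_hill(isotherm: BindingIsotherm, fix_hill: float | None = None) -> HillFit:
    """Least-squares Hill fit of one isotherm.

    ``fix_hill`` pins the Hill coefficient (h = 1 gives the Langmuir
    isotherm).  An isotherm with no resolvable amplitude relative to its
    residual scatter is returned unconverged with message "no binding
    signal".  A Kd outside [min/10, 10*max] of the titration sets
    ``out_of_range``.
    """
    x = isotherm.titrant_concs
    y = isotherm.responses
    kd0 = float(np.exp(np.mean(np.log(x))))  # geometric mean of the grid
    base0 = float(y[np.argmin(x)])
    amp0 = float(y[np.argmax(x)] - base0)
    if amp0 == 0.0:
        amp0 = 1e-6

    if fix_hill is None:
        popt, _ = curve_fit(
            _hill_model, x, y,
            p0=[kd0, 1.0, base0, amp0],
            bounds=([x.min() / 1e3, HILL_BOUNDS[0], -np.inf, -np.inf],
                    [x.max() * 1e3, HILL_BOUNDS[1], np.inf, np.inf]),
            maxfev=20000,
        )
        kd, h, baseline, amplitude = map(float, popt)
    else:
        if not (HILL_BOUNDS[0] <= fix_hill <= HILL_BOUNDS[1]):
            raise ValueError(f"fixed Hill coefficient outside bounds {HILL_BOUNDS}")
        popt, _ = curve_fit(
            lambda xx, kd, baseline, amplitude: _hill_model(xx, kd, fix_hill, baseline, amplitude),
            x, y,
            p0=[kd0, base0, amp0],
            bounds=([x.min() / 1e3, -np.inf, -np.inf], [x.max() * 1e3, np.inf, np.inf]),
            maxfev=20000,
        )
        kd, baseline, amplitude = map(float, popt)
        h = float(fix_hill)

    resid = y - _hill_model(x, kd, h, baseline, amplitude)
    noise_floor = float(np.std(resid, ddof=1)) if x.size > 4 else 0.0
    no_signal = np.ptp(y) == 0 or abs(amplitude) < 3.0 * noise_floor
    out_of_range = not (x.min() / 10.0 <= kd <= x.max() * 10.0)
    return HillFit(
        kd=kd,
        hill=h,
        baseline=baseline,
        amplitude=amplitude,
        converged=not no_signal,
        out_of_range=out_of_range,
        message="no binding signal" if no_signal else "",
        construct_label=isotherm.construct_label,
        replicate_id=isotherm.replicate_id,
    )


def fold_change(kd_mut: float, kd_wt: float) -> float:
    """Kd ratio mutant / WT; values above 1 mean weaker binding."""
    if kd_mut <= 0 or kd_wt <= 0:
        raise ValueError("Kd values must be positive")
    return float(kd_mut / kd_wt)


def aggregate_kd(fits: list[HillFit], grouping: dict | None = None) -> tuple[float, float]:
    """Hierarchical (technical-within-biological) mean and SEM of replicate Kd.

    Unconverged fits are excluded; if none converged this is an error.
    """
    good = [f for f in fits if f.converged]
    if not good:
        raise ValueError("no converged Hill fits to aggregate")
    mean, sem, _ = hierarchical_mean_sem(
        [f.kd for f in good], [f.replicate_id for f in good], grouping
    )
    return mean, sem
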