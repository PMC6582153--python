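"""Tabular I/O, run configuration, and the end-to-end report.

All inputs are plain CSV (UTF-8, '.' decimal separator) with fixed headers:

======================  ==========================================
schema                  required columns
======================  ==========================================
``trace``               time_s, fluorescence, construct, replicate
``titration``           actin_uM, rate_per_s, construct, replicate
``isotherm``            titrant_uM, response, construct, replicate
``velocities``          velocity_nm_s, construct, movie
======================  ==========================================

Construct labels follow ``<variant>-<2hep|25hep>`` (e.g. ``WT-25hep``);
the report pairs each variant's 25-hep construct with its 2-hep control
and each mutant with the WT reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import accounting, atpase, binding, motility, turnover
from .datatypes import (
    ATPaseTitration,
    BindingIsotherm,
    FluorescenceTrace,
    MichaelisMentenFit,
    VelocityTable,
)

__all__ = ["RunConfig", "ReportBundle", "read_table", "write_table", "run_report", "SCHEMAS"]

SCHEMAS = {
    "trace": ["time_s", "fluorescence", "construct", "replicate"],
    "titration": ["actin_uM", "rate_per_s", "construct", "replicate"],
    "isotherm": ["titrant_uM", "response", "construct", "replicate"],
    "velocities": ["velocity_nm_s", "construct", "movie"],
}
_NUMERIC = {"time_s", "fluorescence", "actin_uM", "rate_per_s", "titrant_uM", "response", "velocity_nm_s"}

# Sentinel for report cells that are undefined for a construct (e.g. the
# conversion columns on the WT row): empty CSV cell, NaN in the DataFrame.
REPORT_NA = float("nan")


@dataclass
class RunConfig:
    """Pipeline configuration; defaults encode the standard assay constants
    (nominal DRX/SRX rates 0.03 / 0.003 s^-1, 100 bootstrap iterations)."""

    seed: int = 0
    nominal_fast_rate: float = 0.03
    nominal_slow_rate: float = 0.003
    n_boot: int = 100
    replicate_design: dict | None = None  # replicate_id -> biological group
    report_rounding: int = 2
    top_fraction: float = 0.05


@dataclass
class ReportBundle:
    """Per-construct summary table plus a structured log of every fit."""

    summary: pd.DataFrame
    log: list = field(default_factory=list)


def _validate(df: pd.DataFrame, schema: str, path) -> pd.DataFrame:
    cols = SCHEMAS[schema]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing} for schema {schema!r}")
    for c in cols:
        if c not in _NUMERIC:
            continue
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[coerced.isna() & df[c].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value {df.loc[bad[0], c]!r} in column {c!r} at row {bad[0]}"
            )
        if coerced.isna().any():
            raise ValueError(f"{path}: empty cell in column {c!r} at row {coerced.index[coerced.isna()][0]}")
        df[c] = coerced
    return df


def read_table(path, schema: str):
    """Read and validate a CSV into typed records (grouped per replicate).

    Returns a list of FluorescenceTrace / ATPaseTitration / BindingIsotherm
    / VelocityTable depending on ``schema``.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    path = Path(path)
    df = _validate(pd.read_csv(path, float_precision="round_trip"), schema, path)

    records = []
    if schema == "trace":
        for (construct, rep), g in df.groupby(["construct", "replicate"], sort=True):
            g = g.reset_index()
            if np.any(np.diff(g["time_s"].to_numpy()) <= 0):
                bad = int(g["index"][np.argmax(np.diff(g["time_s"].to_numpy()) <= 0) + 1])
                raise ValueError(f"{path}: unsorted time_s at row {bad} (construct {construct!r})")
            records.append(
                FluorescenceTrace(g["time_s"].to_numpy(), g["fluorescence"].to_numpy(),
                                  construct_label=str(construct), replicate_id=str(rep))
            )
    elif schema == "titration":
        for (construct, rep), g in df.groupby(["construct", "replicate"], sort=True):
            records.append(
                ATPaseTitration(g["actin_uM"].to_numpy(), g["rate_per_s"].to_numpy(),
                                construct_label=str(construct), replicate_id=str(rep))
            )
    elif schema == "isotherm":
        for (construct, rep), g in df.groupby(["construct", "replicate"], sort=True):
            records.append(
                BindingIsotherm(g["titrant_uM"].to_numpy(), g["response"].to_numpy(),
                                construct_label=str(construct), replicate_id=str(rep))
            )
    else:  # velocities
        for (construct, movie), g in df.groupby(["construct", "movie"], sort=True):
            records.append(
                VelocityTable(g["velocity_nm_s"].to_numpy(),
                              construct_label=str(construct), movie_id=str(movie))
            )
    return records


def write_table(records, schema: str, path) -> None:
    """Inverse of :func:`read_table`; full float precision (round-trip exact)."""
    rows = []
    for r in records:
        if schema == "trace":
            for t, v in zip(r.times, r.values):
                rows.append({"time_s": t, "fluorescence": v,
                             "construct": r.construct_label, "replicate": r.replicate_id})
        elif schema == "titration":
            for a, v in zip(r.actin_concs, r.rates):
                rows.append({"actin_uM": a, "rate_per_s": v,
                             "construct": r.construct_label, "replicate": r.replicate_id})
        elif schema == "isotherm":
            for x, v in zip(r.titrant_concs, r.responses):
                rows.append({"titrant_uM": x, "response": v,
                             "construct": r.construct_label, "replicate": r.replicate_id})
        elif schema == "velocities":
            for v in r.velocities:
                rows.append({"velocity_nm_s": v, "construct": r.construct_label, "movie": r.movie_id})
        else:
            raise ValueError(f"unknown schema {schema!r}")
    pd.DataFrame(rows, columns=SCHEMAS[schema]).to_csv(
        path, index=False, float_format=lambda v: format(v, ".17g"))


def _split_label(label: str) -> tuple[str, str]:
    variant, _, tail = label.rpartition("-")
    if tail not in ("2hep", "25hep") or not variant:
        raise ValueError(f"construct label {label!r} must look like '<variant>-<2hep|25hep>'")
    return variant, tail


def run_report(config: RunConfig, inputs: dict) -> ReportBundle:
    """Run every applicable analysis stage and assemble the per-variant report.

    ``inputs`` maps any of ``traces`` / ``titrations`` / ``isotherms`` /
    ``velocities`` to lists of typed records.  Requires a WT reference
    whenever mutants are present.  Deterministic given ``config.seed``.
    Cells that do not apply (conversion columns on the WT row, assays not
    provided for a construct) hold NaN, written as empty CSV cells.
    """
    log: list[dict] = []
    design = config.replicate_design

    # --- single turnover ---------------------------------------------------
    turnover_by_label: dict[str, turnover.TurnoverSummary] = {}
    for trace in inputs.get("traces", []):
        norm = turnover.normalize_trace(trace)
        fit = turnover.fit_exponentials(norm, n_components=2)
        summ = turnover.classify_phases(
            fit, config.nominal_fast_rate, config.nominal_slow_rate,
            construct_label=trace.construct_label, replicate_id=trace.replicate_id,
        )
        log.append({
            "id": f"turnover:{trace.construct_label}:{trace.replicate_id}",
            "stage": "turnover", "construct": trace.construct_label,
            "replicate": trace.replicate_id, "fast_pct": summ.fast_fraction_pct,
            "fast_rate": summ.fast_rate, "slow_rate": summ.slow_rate,
            "sse": fit.residual_sse, "converged": fit.converged,
        })
        turnover_by_label.setdefault(trace.construct_label, []).append(summ)
    turnover_by_label = {
        lab: turnover.aggregate_replicates(summs, design)
        for lab, summs in turnover_by_label.items()
    }

    # --- ATPase ------------------------------------------------------------
    mm_by_label: dict[str, MichaelisMentenFit] = {}
    groups: dict[str, list[ATPaseTitration]] = {}
    for titr in inputs.get("titrations", []):
        groups.setdefault(titr.construct_label, []).append(titr)
    for i, lab in enumerate(sorted(groups)):
        fits = []
        for j, titr in enumerate(sorted(groups[lab], key=lambda t: t.replicate_id)):
            fit = atpase.bootstrap_mm(titr, n_boot=config.n_boot,
                                      seed=(config.seed + 1009 * i + j) % 2**31)
            fits.append(fit)
            log.append({
                "id": f"atpase:{lab}:{titr.replicate_id}", "stage": "atpase",
                "construct": lab, "replicate": titr.replicate_id,
                "kcat": fit.kcat, "km": fit.km, "basal": fit.basal,
                "kcat_err": fit.kcat_err, "converged": fit.converged,
            })
        from .datatypes import hierarchical_mean_sem
        kcat, kcat_sem, _ = hierarchical_mean_sem(
            [f.kcat for f in fits], [f.replicate_id for f in fits], design)
        km, km_sem, _ = hierarchical_mean_sem(
            [f.km for f in fits], [f.replicate_id for f in fits], design)
        basal = float(np.mean([f.basal for f in fits]))
        mm_by_label[lab] = MichaelisMentenFit(
            kcat=kcat, km=km, basal=basal, kcat_err=kcat_sem, km_err=km_sem,
            construct_label=lab, n_boot=config.n_boot,
        )

    # --- binding -----------------------------------------------------------
    kd_by_label: dict[str, tuple[float, float]] = {}
    iso_groups: dict[str, list[BindingIsotherm]] = {}
    for iso in inputs.get("isotherms", []):
        iso_groups.setdefault(iso.construct_label, []).append(iso)
    for lab in sorted(iso_groups):
        fits = []
        for iso in sorted(iso_groups[lab], key=lambda r: r.replicate_id):
            fit = binding.fit_hill(iso)
            fits.append(fit)
            log.append({
                "id": f"binding:{lab}:{iso.replicate_id}", "stage": "binding",
                "construct": lab, "replicate": iso.replicate_id,
                "kd": fit.kd, "hill": fit.hill, "converged": fit.converged,
            })
        kd_by_label[lab] = binding.aggregate_kd(fits, design)

    # --- motility ----------------------------------------------------------
    vel_by_label: dict[str, tuple[float, float]] = {}
    vel_groups: dict[str, list[VelocityTable]] = {}
    for table in inputs.get("velocities", []):
        vel_groups.setdefault(table.construct_label, []).append(table)
    for lab in sorted(vel_groups):
        per_movie = []
        for table in sorted(vel_groups[lab], key=lambda r: r.movie_id):
            v = motility.top_fraction_velocity(table, config.top_fraction)
            per_movie.append(v)
            log.append({
                "id": f"motility:{lab}:{table.movie_id}", "stage": "motility",
                "construct": lab, "movie": table.movie_id, "top_velocity": v,
                "n_filaments": table.velocities.size,
            })
        mean = float(np.mean(per_movie))
        sem = float(np.std(per_movie, ddof=1) / np.sqrt(len(per_movie))) if len(per_movie) > 1 else 0.0
        vel_by_label[lab] = (mean, sem)

    # --- assemble per-variant rows ------------------------------------------
    all_labels = set(turnover_by_label) | set(mm_by_label) | set(kd_by_label) | set(vel_by_label)
    variants = sorted({_split_label(lab)[0] for lab in all_labels})
    if not variants:
        raise ValueError("no inputs provided")
    has_mutants = any(v != "WT" for v in variants)
    if has_mutants and "WT" not in variants:
        raise ValueError("missing WT reference construct")

    wt_ratio = None
    ratios: dict[str, atpase.KcatRatio] = {}
    for variant in variants:
        f25, f2 = mm_by_label.get(f"{variant}-25hep"), mm_by_label.get(f"{variant}-2hep")
        if f25 is not None and f2 is not None:
            ratios[variant] = atpase.kcat_ratio(f25, f2)
    wt_ratio = ratios.get("WT")
    wt_turn = turnover_by_label.get("WT-25hep")
    wt_kd = kd_by_label.get("WT-2hep")

    rnd = config.report_rounding
    rows = []
    for variant in variants:
        row: dict = {"variant": variant}
        for tail in ("2hep", "25hep"):
            lab = f"{variant}-{tail}"
            ts = turnover_by_label.get(lab)
            row[f"fast_pct_{tail}"] = round(ts.fast_fraction_pct, rnd) if ts else REPORT_NA
            row[f"fast_sem_{tail}"] = round(ts.sem_fast_pct, rnd) if ts else REPORT_NA
            mm = mm_by_label.get(lab)
            row[f"kcat_{tail}"] = round(mm.kcat, rnd) if mm else REPORT_NA
            row[f"kcat_err_{tail}"] = round(mm.kcat_err, rnd) if mm else REPORT_NA
            row[f"km_{tail}"] = round(mm.km, rnd) if mm else REPORT_NA
            row[f"km_err_{tail}"] = round(mm.km_err, rnd) if mm else REPORT_NA

        ratio = ratios.get(variant)
        row["kcat_ratio"] = round(ratio.ratio, rnd) if ratio else REPORT_NA
        row["kcat_ratio_err"] = round(ratio.ratio_err, rnd) if ratio else REPORT_NA
        if ratio is not None:
            seq = accounting.sequestered_from_ratio(ratio)
            row["sequestered_pct"] = accounting.round_half_up(seq.sequestered_fraction_pct)
        else:
            row["sequestered_pct"] = REPORT_NA

        if variant != "WT" and ratio is not None and wt_ratio is not None and wt_ratio.ratio < 1:
            conv = accounting.conversion_from_ratios(ratio.ratio, wt_ratio.ratio)
            row["conversion_pct"] = accounting.round_half_up(conv.conversion_pct)
            row["conversion_capped"] = conv.capped_flag
        else:
            row["conversion_pct"] = REPORT_NA
            row["conversion_capped"] = REPORT_NA

        ts25 = turnover_by_label.get(f"{variant}-25hep")
        if variant != "WT" and ts25 is not None and wt_turn is not None:
            dec = accounting.srx_decrease_from_fractions(
                wt_turn.fast_fraction_pct, ts25.fast_fraction_pct)
            row["srx_decrease_pct"] = accounting.round_half_up(dec.srx_decrease_pct)
        else:
            row["srx_decrease_pct"] = REPORT_NA

        kd = kd_by_label.get(f"{variant}-2hep")
        row["kd_uM"] = round(kd[0], rnd) if kd else REPORT_NA
        row["kd_sem_uM"] = round(kd[1], rnd) if kd else REPORT_NA
        if variant != "WT" and kd is not None and wt_kd is not None:
            row["kd_fold_change"] = round(binding.fold_change(kd[0], wt_kd[0]), rnd)
        else:
            row["kd_fold_change"] = REPORT_NA

        for tail in ("2hep", "25hep"):
            vel = vel_by_label.get(f"{variant}-{tail}")
            row[f"velocity_{tail}_nm_s"] = round(vel[0], rnd) if vel else REPORT_NA
            row[f"velocity_sem_{tail}_nm_s"] = round(vel[1], rnd) if vel else REPORT_NA
        rows.append(row)

    return ReportBundle(summary=pd.DataFrame(rows), log=log)
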