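"""End-to-end pipeline orchestration and report rendering.

Two entry points matter:

* :func:`run_pipeline` — simulate both study periods, classify every
  ordered medication, and compute the full set of rate comparisons and
  summaries (the simulated analogue of the published result tables).
* :func:`reference_report` — recompute every headline statistic of the
  published two-period comparison from the packaged count records alone:
  rates, rate ratios, test-based confidence intervals, rate differences,
  compliance and per-patient fractions.

Reports are plain nested dicts of JSON-serializable values, deterministic
given the seeds; timestamps never enter report bodies so outputs diff
cleanly.  Rounding for presentation follows the published conventions:
rates to one decimal of percent, rate ratios and confidence bounds to two
decimals, compliance to the nearest integer percent.
"""

from __future__ import annotations

import importlib.metadata
import json
from dataclasses import asdict
from typing import Optional

import pandas as pd

from . import reference, stats
from .classify import classify_dataset
from .simulate import (
    NOE,
    POE,
    SimulatedDataset,
    SimulationConfig,
    default_config,
    simulate_period,
)


def _version() -> str:
    try:
        return importlib.metadata.version("neodose")
    except importlib.metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def comparison_dict(cmp: stats.RateComparison) -> dict:
    """A rate comparison as plain JSON-ready values (raw, unrounded)."""
    return {
        "unit": cmp.unit,
        "poe": {"erroneous": cmp.counts_poe.erroneous, "total": cmp.counts_poe.total,
                "rate_pct": 100 * cmp.counts_poe.rate},
        "noe": {"erroneous": cmp.counts_noe.erroneous, "total": cmp.counts_noe.total,
                "rate_pct": 100 * cmp.counts_noe.rate},
        "rr": cmp.rr,
        "ci_low": cmp.ci_low,
        "ci_high": cmp.ci_high,
        "rate_difference_d": cmp.rate_difference_d,
        "chi2": cmp.chi2,
        "p": cmp.p,
    }


def _compare(quantity: str, poe: tuple[int, int], noe: tuple[int, int],
             unit: str = "ordered_medication") -> stats.RateComparison:
    return stats.compare_rates(
        unit,
        stats.UnitCounts(unit, poe[0], poe[1], POE),
        stats.UnitCounts(unit, noe[0], noe[1], NOE),
    )


def _maybe_comparison(unit: str, poe_counts: stats.UnitCounts,
                      noe_counts: stats.UnitCounts) -> dict:
    """Comparison dict, degrading to plain counts when RR/CI are undefined
    (no events in a period, or identical rates)."""
    try:
        return comparison_dict(stats.compare_rates(unit, poe_counts, noe_counts))
    except (stats.UndefinedRateRatioError, stats.DegenerateTableError):
        return {
            "unit": unit,
            "poe": {"erroneous": poe_counts.erroneous, "total": poe_counts.total,
                    "rate_pct": 100 * poe_counts.rate},
            "noe": {"erroneous": noe_counts.erroneous, "total": noe_counts.total,
                    "rate_pct": 100 * noe_counts.rate},
        }


def reference_report() -> dict:
    """Recompute the published comparison tables from the packaged counts.

    Every rate ratio, confidence bound and derived quantity is computed by
    the package's own statistics on the raw published counts; nothing is
    copied from the published tables except the counts themselves.
    """
    recs = reference.RECORDS
    report: dict = {"source": "published reference counts", "tables": {}}

    interception = {}
    for q in ("intercepted_by_warning", "intercepted_by_provider",
              "nonintercepted", "all_errors"):
        rec = recs[q]
        interception[q] = comparison_dict(_compare(q, rec.poe, rec.noe))
    report["tables"]["interception"] = interception

    units = {}
    for unit, q in (
        ("order", "errors_per_order"),
        ("ordered_medication", "errors_per_ordered_medication"),
        ("medication_day", "errors_per_medication_day"),
        ("patient_day", "errors_per_patient_day"),
    ):
        rec = recs[q]
        units[unit] = comparison_dict(_compare(q, rec.poe, rec.noe, unit=unit))
    report["tables"]["units"] = units

    stage = {}
    for q in ("prescription_errors", "transcription_errors"):
        rec = recs[q]
        stage[q] = comparison_dict(_compare(q, rec.poe, rec.noe))
    report["tables"]["stage"] = stage

    reasons = {}
    for q in ("initial_dose_incorrect", "stale_dose_after_criteria_change",
              "pborder_vs_eorder", "pbmac_vs_emac", "kardex_not_updated"):
        rec = recs[q]
        entry = {
            "poe": {"erroneous": rec.poe[0], "total": rec.poe[1],
                    "rate_pct": 100 * rec.poe[0] / rec.poe[1]},
            "noe": {"erroneous": rec.noe[0], "total": rec.noe[1],
                    "rate_pct": 100 * rec.noe[0] / rec.noe[1]},
        }
        if rec.poe[0] > 0:       # a zero reference count leaves RR undefined
            entry.update(comparison_dict(_compare(q, rec.poe, rec.noe)))
        reasons[q] = entry
    report["tables"]["reasons"] = reasons

    comp = recs["warnings_complied"]
    free = recs["error_free_patients"]
    pd_rec = recs["errors_per_patient_day"]
    report["derived"] = {
        "compliance_pct": {
            "POE": 100 * comp.poe[0] / comp.poe[1],
            "NOE": 100 * comp.noe[0] / comp.noe[1],
        },
        "error_free_patients_pct": {
            "POE": 100 * free.poe[0] / free.poe[1],
            "NOE": 100 * free.noe[0] / free.noe[1],
        },
        "errors_per_1000_patient_days": {
            "POE": 1000 * pd_rec.poe[0] / pd_rec.poe[1],
            "NOE": 1000 * pd_rec.noe[0] / pd_rec.noe[1],
        },
        "patient_day_rate_difference_pp": abs(
            100 * pd_rec.poe[0] / pd_rec.poe[1] - 100 * pd_rec.noe[0] / pd_rec.noe[1]
        ),
    }
    report["version"] = _version()
    return report


def analyze_periods(
    ds_poe: SimulatedDataset,
    cls_poe: pd.DataFrame,
    ds_noe: SimulatedDataset,
    cls_noe: pd.DataFrame,
) -> dict:
    """Full two-period analysis of classified datasets (simulated or read)."""
    report: dict = {"tables": {}}

    units = {}
    for unit in stats.UNITS:
        poe_counts = stats.count_units(cls_poe, ds_poe.lines, unit, period=POE)
        noe_counts = stats.count_units(cls_noe, ds_noe.lines, unit, period=NOE)
        units[unit] = _maybe_comparison(unit, poe_counts, noe_counts)
    report["tables"]["units"] = units

    interception = {}
    for cat in ("intercepted_by_warning", "intercepted_by_provider", "nonintercepted"):
        poe_counts = stats.count_units(
            cls_poe, ds_poe.lines, "ordered_medication", status=cat, period=POE
        )
        noe_counts = stats.count_units(
            cls_noe, ds_noe.lines, "ordered_medication", status=cat, period=NOE
        )
        interception[cat] = _maybe_comparison("ordered_medication", poe_counts, noe_counts)
    report["tables"]["interception"] = interception

    stage = {}
    for stg in ("prescription", "transcription"):
        entry = {}
        for period, ds, cls in ((POE, ds_poe, cls_poe), (NOE, ds_noe, cls_noe)):
            n = int(
                ((cls["interception"] == "nonintercepted") & (cls["stage"] == stg)).sum()
            )
            entry[period.lower()] = {
                "erroneous": n,
                "total": len(ds.lines),
                "rate_pct": 100 * n / len(ds.lines) if len(ds.lines) else 0.0,
            }
        stage[stg] = entry
    report["tables"]["stage"] = stage

    reasons = {}
    for reason in ("initial_dose_incorrect", "stale_dose_after_criteria_change",
                   "pborder_vs_eorder", "pbmac_vs_emac", "kardex_not_updated"):
        entry = {}
        for period, ds, cls in ((POE, ds_poe, cls_poe), (NOE, ds_noe, cls_noe)):
            n = int(
                ((cls["interception"] == "nonintercepted") & (cls["reason"] == reason)).sum()
            )
            entry[period.lower()] = {"erroneous": n, "total": len(ds.lines)}
        reasons[reason] = entry
    report["tables"]["reasons"] = reasons

    per_patient = {}
    compliance = {}
    for period, ds, cls in ((POE, ds_poe, cls_poe), (NOE, ds_noe, cls_noe)):
        summary = stats.per_patient_summary(cls, ds.lines, ds.patients)
        per_patient[period] = asdict(summary)
        if len(ds.warnings):
            compliance[period] = 100 * stats.compliance_rate(ds.warnings["response"])
    report["per_patient"] = per_patient
    report["compliance_pct"] = compliance

    mw_counts = {}
    for period, ds, cls in ((POE, ds_poe, cls_poe), (NOE, ds_noe, cls_noe)):
        merged = ds.lines.merge(cls, on="ordered_medication_id")
        err = (
            merged[merged["interception"] == "nonintercepted"]
            .groupby("patient_id").size()
            .reindex(ds.patients["patient_id"], fill_value=0)
        )
        mw_counts[period] = err.to_numpy()
    u, p = stats.mann_whitney(mw_counts[POE], mw_counts[NOE])
    report["per_patient_mann_whitney"] = {"U": u, "p": p}
    return report


def run_pipeline(
    config_poe: Optional[SimulationConfig] = None,
    config_noe: Optional[SimulationConfig] = None,
    seed: int = 0,
) -> dict:
    """Simulate → classify → analyze both periods; returns the full report.

    The report embeds both configurations, the seeds, and the package
    version, so a report is reproducible from its own metadata.
    """
    config_poe = config_poe or default_config(POE, seed=seed)
    config_noe = config_noe or default_config(NOE, seed=seed + 1)
    ds_poe = simulate_period(config_poe)
    ds_noe = simulate_period(config_noe)
    cls_poe = classify_dataset(ds_poe)
    cls_noe = classify_dataset(ds_noe)
    report = analyze_periods(ds_poe, cls_poe, ds_noe, cls_noe)
    report["config"] = {
        "POE": _config_dict(config_poe),
        "NOE": _config_dict(config_noe),
    }
    report["version"] = _version()
    report["cohort"] = {
        period: {
            "patients": int(len(ds.patients)),
            "orders": int(ds.lines["order_id"].nunique()),
            "ordered_medications": int(len(ds.lines)),
            "patient_days": int(
                ds.lines.groupby(["patient_id", "day"]).ngroups
            ),
            "median_gestational_age_weeks": float(
                ds.patients["gestational_age_weeks"].median()
            ),
        }
        for period, ds in ((POE, ds_poe), (NOE, ds_noe))
    }
    return report


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["magnitude_bounds"] = list(d["magnitude_bounds"])
    return d


# ---------------------------------------------------------------------------
# rendering

def round_report(value: float, kind: str) -> float | int:
    """Published rounding conventions: rates 1 dp of percent, ratios and
    confidence bounds 2 dp, compliance nearest integer percent."""
    if kind == "rate_pct":
        return round(value, 1)
    if kind in ("rr", "ci"):
        return round(value, 2)
    if kind == "pct_int":
        return int(round(value))
    raise ValueError(f"unknown rounding kind {kind!r}")


def _comparison_rows(table: dict) -> list[dict]:
    rows = []
    for name, entry in table.items():
        row = {"quantity": name}
        for period in ("poe", "noe"):
            if period in entry:
                cell = entry[period]
                row[period.upper()] = (
                    f"{cell['erroneous']}/{cell['total']}"
                    + (
                        f" ({round_report(cell['rate_pct'], 'rate_pct')})"
                        if "rate_pct" in cell
                        else ""
                    )
                )
        if "rr" in entry:
            row["RR (95% CI)"] = (
                f"{round_report(entry['rr'], 'rr'):.2f} "
                f"({round_report(entry['ci_low'], 'ci'):.2f}, "
                f"{round_report(entry['ci_high'], 'ci'):.2f})"
            )
        rows.append(row)
    return rows


def render_tables(report: dict) -> str:
    """Human-readable rendering of a report's tables.

    The text and the JSON forms of a report carry identical numbers; this
    function only formats, it never recomputes.
    """
    blocks = []
    for name, table in report.get("tables", {}).items():
        rows = _comparison_rows(table)
        frame = (
            pd.DataFrame(rows).fillna("") if rows
            else pd.DataFrame(columns=["quantity"])
        )
        blocks.append(f"== {name} ==\n{frame.to_string(index=False)}")
    if "derived" in report:
        derived = pd.DataFrame(
            [
                {"quantity": k, **{
                    kk: round(vv, 1) for kk, vv in v.items()
                }} if isinstance(v, dict) else {"quantity": k, "value": round(v, 1)}
                for k, v in report["derived"].items()
            ]
        )
        blocks.append(f"== derived ==\n{derived.to_string(index=False)}")
    if "compliance_pct" in report and report["compliance_pct"]:
        comp = ", ".join(
            f"{k}: {round_report(v, 'pct_int')}%"
            for k, v in report["compliance_pct"].items()
        )
        blocks.append(f"warning compliance: {comp}")
    return "\n\n".join(blocks) + "\n"


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
        fh.write("\n")
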