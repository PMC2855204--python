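"""Published reference counts for the two-period order-entry comparison.

The package models a before/after comparison of two computerized order-entry
strategies on a neonatal ward: strictly physician order entry (POE) versus
nurse order entry with physician countersignature (NOE).  This module
packages the published count tables of that comparison as structured
records, so every headline statistic (rates, rate ratios, test-based
confidence intervals, compliance) can be recomputed from first principles
and regression-tested.

Each record is a pair of (numerator, denominator) counts per period, tagged
with the report table it came from.  Values are verbatim from the published
tables; nothing here is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

POE = "POE"
NOE = "NOE"
PERIODS = (POE, NOE)


@dataclass(frozen=True)
class CountRecord:
    """A published count pair: events out of a denominator, per period."""

    quantity: str
    source: str                 # which published table or results passage
    poe: tuple[int, int]        # (events, denominator)
    noe: tuple[int, int]

    def counts(self, period: str) -> tuple[int, int]:
        return self.poe if period == POE else self.noe


#: cohort scale per period (denominators of the four measurement units)
COHORT = {
    "patients": (69, 89),
    "orders": (972, 978),
    "ordered_medications": (2357, 2297),
    "patient_days": (601, 648),
    "medication_days": (1466, 1492),
}

#: cohort medians per period
COHORT_MEDIANS = {
    "gestational_age_weeks": (38, 38),
    "admission_age_days": (7, 5),
    "length_of_stay_days": (9.1, 6.7),
}

_OM = COHORT["ordered_medications"]

RECORDS: dict[str, CountRecord] = {
    rec.quantity: rec
    for rec in [
        # errors by interception status, per ordered medication
        CountRecord("intercepted_by_warning", "interception_table",
                    (106, _OM[0]), (186, _OM[1])),
        CountRecord("intercepted_by_provider", "interception_table",
                    (12, _OM[0]), (11, _OM[1])),
        CountRecord("nonintercepted", "interception_table",
                    (301, _OM[0]), (175, _OM[1])),
        CountRecord("all_errors", "interception_table",
                    (419, _OM[0]), (372, _OM[1])),
        # nonintercepted errors per measurement unit
        CountRecord("errors_per_order", "units_table", (221, 972), (142, 978)),
        CountRecord("errors_per_ordered_medication", "units_table",
                    (301, 2357), (175, 2297)),
        CountRecord("errors_per_medication_day", "units_table",
                    (211, 1466), (129, 1492)),
        CountRecord("errors_per_patient_day", "units_table",
                    (147, 601), (97, 648)),
        # nonintercepted errors by stage, per ordered medication
        CountRecord("prescription_errors", "stage_table",
                    (242, _OM[0]), (106, _OM[1])),
        CountRecord("transcription_errors", "stage_table",
                    (59, _OM[0]), (69, _OM[1])),
        # nonintercepted errors by reason, per ordered medication
        CountRecord("initial_dose_incorrect", "reasons_table",
                    (163, _OM[0]), (70, _OM[1])),
        CountRecord("stale_dose_after_criteria_change", "reasons_table",
                    (79, _OM[0]), (36, _OM[1])),
        CountRecord("pborder_vs_eorder", "reasons_table",
                    (0, _OM[0]), (22, _OM[1])),
        CountRecord("pbmac_vs_emac", "reasons_table",
                    (24, _OM[0]), (13, _OM[1])),
        CountRecord("kardex_not_updated", "reasons_table",
                    (35, _OM[0]), (34, _OM[1])),
        # warning compliance and per-patient summaries (results text)
        CountRecord("warnings_complied", "results_text", (136, 312), (232, 339)),
        CountRecord("error_free_patients", "results_text", (26, 69), (47, 89)),
        CountRecord("twofold_or_greater_overdose", "results_text",
                    (16, 65), (5, 67)),
    ]
}

#: per-patient nonintercepted-error summaries (median, q25, q75) per period
PER_PATIENT_QUARTILES = {POE: (2, 0, 5), NOE: (0, 0, 2)}

#: published rate ratios and 95% confidence bounds, as printed (2 dp);
#: regression expectations for recomputation from the counts above
PUBLISHED_RATE_RATIOS: dict[str, dict] = {
    "intercepted_by_warning": {"rr": 1.80, "ci": (1.43, 2.27)},
    "intercepted_by_provider": {"rr": 0.94, "ci": (0.42, 2.13)},
    "nonintercepted": {"rr": 0.60, "ci": (0.50, 0.71)},
    "all_errors": {"rr": 0.91, "ci": (0.80, 1.03)},
    "errors_per_order": {"rr": 0.64, "ci": (0.53, 0.77)},
    "errors_per_ordered_medication": {"rr": 0.60, "ci": (0.50, 0.71)},
    "errors_per_medication_day": {"rr": 0.60, "ci": (0.49, 0.74)},
    "errors_per_patient_day": {"rr": 0.61, "ci": (0.49, 0.77)},
    "prescription_errors": {"rr": 0.45, "ci": (0.36, 0.56)},
    "transcription_errors": {"rr": 1.20, "ci": (0.85, 1.69)},
    "initial_dose_incorrect": {"rr": 0.44, "ci": (0.34, 0.58)},
    "stale_dose_after_criteria_change": {"rr": 0.47, "ci": (0.32, 0.69)},
    "pbmac_vs_emac": {"rr": 0.56, "ci": (0.28, 1.09)},
    "kardex_not_updated": {"rr": 1.00, "ci": (0.62, 1.59)},
}

#: published derived quantities (percent or per-1000 scales, as printed)
PUBLISHED_DERIVED = {
    "compliance_pct": {POE: 44, NOE: 68},
    "error_free_patients_pct": {POE: 38, NOE: 53},
    "errors_per_1000_patient_days": {POE: 245, NOE: 150},
    "patient_day_rate_difference_pp": 9.5,
    "ordered_medication_rate_difference_pp": 5.2,
}


def records_frame() -> pd.DataFrame:
    """All reference counts as a tidy frame (one row per quantity/period)."""
    rows = []
    for rec in RECORDS.values():
        for period in PERIODS:
            events, denom = rec.counts(period)
            rows.append(
                {
                    "quantity": rec.quantity,
                    "source": rec.source,
                    "period": period,
                    "events": events,
                    "denominator": denom,
                }
            )
    return pd.DataFrame(rows)
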