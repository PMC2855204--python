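"""Rule-based classification of ordered medications by chart triangulation.

Reproduces the review procedure of the surveilled wards: for every
medication line, compare the recorded dose and interval across the
documentation sources (handwritten order where one exists, electronic
order, Kardex, paper and electronic administration charts) against the
knowledge-base-derived recommended dosage, and label the line with

* its interception status — caught by a CDSS warning, caught by a care
  provider before administration, nonintercepted (reached the patient),
  or no error at all;
* the stage where the defect arose — prescription or transcription, with a
  line defective at both stages counted as a prescription error;
* a reason code (wrong initial dosage, stale dosage after a criteria
  change, paper order inconsistent with the electronic order, paper chart
  inconsistent with the electronic chart, Kardex not updated); and
* the error subtype (overdose, underdose, curtailed or prolonged interval).

Comparisons use exact equality of recorded values: the review compares
what was written down, not physical measurements.  The classifier never
sees the simulator's ground-truth labels; on simulated data its output is
checked against them line by line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

INTERCEPTION_CATEGORIES = (
    "intercepted_by_warning",
    "intercepted_by_provider",
    "nonintercepted",
    "no_error",
)

PRESCRIPTION_REASONS = ("initial_dose_incorrect", "stale_dose_after_criteria_change")
TRANSCRIPTION_REASONS = ("pborder_vs_eorder", "pbmac_vs_emac", "kardex_not_updated")


class ChainDataError(ValueError):
    """A documentation source required for the period's mode is missing."""


@dataclass(frozen=True)
class ErrorClassification:
    """Review verdict for one ordered medication."""

    ordered_medication_id: str
    interception: str
    stage: str            # prescription | transcription | not_applicable
    reason: Optional[str]
    subtype: Optional[str]


def _pair(row: pd.Series, prefix: str) -> Optional[tuple[float, float]]:
    dose, interval = row[f"{prefix}_dose"], row[f"{prefix}_interval"]
    if pd.isna(dose) or pd.isna(interval):
        return None
    return float(dose), float(interval)


def _subtype_of(value: tuple[float, float], truth: tuple[float, float]) -> str:
    if value[0] > truth[0]:
        return "overdose"
    if value[0] < truth[0]:
        return "underdose"
    if value[1] < truth[1]:
        return "curtailed"
    return "prolonged"


#: CDSS assessment statuses mapped to tabulated error subtypes
_STATUS_SUBTYPE = {
    "overdose": "overdose",
    "underdose": "underdose",
    "curtailed_interval": "curtailed",
    "prolonged_interval": "prolonged",
}


def classify_line(
    row: pd.Series,
    line_warnings: list[tuple[str, str]],
    mode: str,
) -> ErrorClassification:
    """Classify one medication line from its documentation chain.

    ``row`` holds the chain values (true/hand/eorder/kardex/pbmac/emac/admin
    dose-interval pairs); ``line_warnings`` the (response, status) pairs the
    CDSS error-registration table recorded for this line.
    Decision order: a complied warning with a fully correct
    downstream chain is a warning interception; an erroneous electronic
    order with a correct administration chart is a provider interception;
    an erroneous electronic order reaching the chart is a nonintercepted
    prescription error (dominating any additional transcription defect); a
    correct electronic order with a corrupted chain is a nonintercepted
    transcription error attributed to the earliest corrupted hop.
    """
    line_id = str(row["ordered_medication_id"])
    truth = _pair(row, "true")
    eorder = _pair(row, "eorder")
    pbmac = _pair(row, "pbmac")
    kardex = _pair(row, "kardex")
    hand = _pair(row, "hand")
    if truth is None or eorder is None:
        raise ChainDataError(f"{line_id}: electronic order or reference dosage missing")
    if pbmac is None or kardex is None:
        raise ChainDataError(f"{line_id}: paper administration chain missing")
    if mode == "NOE" and hand is None:
        raise ChainDataError(f"{line_id}: handwritten order missing in NOE mode")

    complied = any(resp == "complied" for resp, _ in line_warnings)
    any_warning = bool(line_warnings)

    if eorder == truth and pbmac == truth:
        if complied:
            # the CDSS corrected the prescription and nothing downstream
            # re-corrupted it; the registered warning status carries the
            # subtype of the original erroneous entry
            status = next(s for resp, s in line_warnings if resp == "complied")
            return ErrorClassification(
                line_id, "intercepted_by_warning", "prescription",
                "initial_dose_incorrect", _STATUS_SUBTYPE.get(status),
            )
        return ErrorClassification(line_id, "no_error", "not_applicable", None, None)

    if eorder != truth:
        # prescription-stage defect in the system of record; a warning on
        # file means the initial entry was wrong, no warning means a
        # standing order went stale after a criteria change
        reason = (
            "initial_dose_incorrect" if any_warning
            else "stale_dose_after_criteria_change"
        )
        subtype = _subtype_of(eorder, truth)
        if pbmac == truth:
            return ErrorClassification(
                line_id, "intercepted_by_provider", "prescription", reason, subtype
            )
        return ErrorClassification(
            line_id, "nonintercepted", "prescription", reason, subtype
        )

    # electronic order correct, administered value wrong: transcription
    if hand is not None and hand != eorder:
        reason = "pborder_vs_eorder"
    elif kardex != eorder:
        reason = "kardex_not_updated"
    else:
        reason = "pbmac_vs_emac"
    return ErrorClassification(
        line_id, "nonintercepted", "transcription", reason, _subtype_of(pbmac, truth)
    )


def classify_dataset(dataset) -> pd.DataFrame:
    """Classify every ordered medication of a simulated or recorded period.

    Returns one row per line with columns ordered_medication_id,
    interception, stage, reason, subtype.  Line-level data errors propagate
    with the offending line id in the message.
    """
    mode = dataset.config.period_mode
    responses: dict[str, list[tuple[str, str]]] = {}
    if len(dataset.warnings):
        for line_id, group in dataset.warnings.groupby("ordered_medication_id"):
            responses[str(line_id)] = list(
                zip(group["response"], group["status"])
            )
    rows = []
    for _, row in dataset.lines.iterrows():
        cls = classify_line(row, responses.get(str(row["ordered_medication_id"]), []), mode)
        rows.append(
            {
                "ordered_medication_id": cls.ordered_medication_id,
                "interception": cls.interception,
                "stage": cls.stage,
                "reason": cls.reason if cls.reason is not None else "none",
                "subtype": cls.subtype if cls.subtype is not None else "none",
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["ordered_medication_id", "interception", "stage", "reason", "subtype"],
    )
    return frame
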