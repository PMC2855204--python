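"""Rule-based neonatal dose and frequency checking.

The engine mirrors a ward CDSS: a knowledge base of weight-based dosing
rules, banded by gestational age, postnatal age, weight and renal function,
is checked against every prescription line.  A line whose dose falls outside
a tolerance band around the recommended dose, or whose dosing interval
differs from the recommended one, yields a warning carrying the recommended
dosage and an explanation.

The knowledge base shipped with the package is illustrative and exists for
testing the machinery only.  It must never be used for clinical dosing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import yaml

logger = logging.getLogger(__name__)

#: statuses a checked prescription line can carry
STATUS_CORRECT = "correct"
STATUS_OVERDOSE = "overdose"
STATUS_UNDERDOSE = "underdose"
STATUS_CURTAILED = "curtailed_interval"
STATUS_PROLONGED = "prolonged_interval"

#: dosing intervals (hours) the order-entry system offers
ALLOWED_INTERVALS = (4, 6, 8, 12, 24, 48)

#: wildcard indication matching every diagnosis
ANY_INDICATION = "any"


class KnowledgeBaseError(ValueError):
    """Raised when the rule collection violates its integrity constraints."""


@dataclass(frozen=True)
class PatientState:
    """A neonate's dosing criteria on one day.

    Weight is in grams, gestational age in completed weeks, postnatal age in
    days, estimated GFR in mL/min/1.73 m².
    """

    patient_id: str
    postnatal_age: float
    gestational_age: float
    weight: float
    estimated_gfr: float
    serum_creatinine: Optional[float] = None
    diagnosis: str = "sepsis"

    def __post_init__(self) -> None:
        if not 22 <= self.gestational_age <= 44:
            raise ValueError(
                f"gestational age {self.gestational_age} wk outside [22, 44]"
            )
        if self.postnatal_age < 0:
            raise ValueError("postnatal age must be >= 0 days")
        if self.weight <= 0:
            raise ValueError("weight must be positive (grams)")
        if self.estimated_gfr < 0:
            raise ValueError("estimated GFR must be >= 0")


@dataclass(frozen=True)
class DoseRule:
    """One knowledge-base entry: recommended dosage for a patient band."""

    drug: str
    pharmaceutical_form: str
    indication: str
    ga_band: tuple[float, float]          # weeks, closed
    pna_band: tuple[float, float]         # days, closed
    recommended_dose_per_kg: float        # mg/kg/dose
    recommended_interval: int             # hours
    tolerance: float = 0.10               # fraction of recommended dose
    weight_band: Optional[tuple[float, float]] = None   # grams
    gfr_threshold: Optional[float] = None  # rule applies strictly below
    gfr_floor: Optional[float] = None      # rule applies at or above

    def __post_init__(self) -> None:
        for lo, hi in (self.ga_band, self.pna_band):
            if lo > hi:
                raise KnowledgeBaseError(f"empty band [{lo}, {hi}] in rule for {self.drug}")
        if self.weight_band and self.weight_band[0] > self.weight_band[1]:
            raise KnowledgeBaseError(f"empty weight band in rule for {self.drug}")
        if self.recommended_dose_per_kg <= 0:
            raise KnowledgeBaseError("recommended dose must be positive")
        if self.recommended_interval not in ALLOWED_INTERVALS:
            raise KnowledgeBaseError(
                f"interval {self.recommended_interval} h not in {ALLOWED_INTERVALS}"
            )
        if not 0 <= self.tolerance < 1:
            raise KnowledgeBaseError("tolerance must be a fraction in [0, 1)")

    def applies_to(self, state: PatientState) -> bool:
        """True when every band of the rule contains the patient state."""
        if self.indication != ANY_INDICATION and self.indication != state.diagnosis:
            return False
        if not self.ga_band[0] <= state.gestational_age <= self.ga_band[1]:
            return False
        if not self.pna_band[0] <= state.postnatal_age <= self.pna_band[1]:
            return False
        if self.weight_band is not None:
            if not self.weight_band[0] <= state.weight <= self.weight_band[1]:
                return False
        if self.gfr_threshold is not None and state.estimated_gfr >= self.gfr_threshold:
            return False
        if self.gfr_floor is not None and state.estimated_gfr < self.gfr_floor:
            return False
        return True

    def recommended_dose_mg(self, state: PatientState) -> float:
        return self.recommended_dose_per_kg * state.weight / 1000.0


@dataclass(frozen=True)
class DoseAssessment:
    """Verdict of checking one prescription line against its matched rule.

    ``status`` is the single label used for tabulation: a dose defect wins
    over an interval defect on the same line; ``interval_flag`` preserves a
    concurrent interval defect without creating a second countable error.
    """

    status: str
    severity_pct: float
    recommended_dose: float
    recommended_interval: int
    explanation: str
    matched_rule: DoseRule
    interval_flag: Optional[str] = None

    @property
    def is_error(self) -> bool:
        return self.status != STATUS_CORRECT


@dataclass
class WarningMessage:
    """A CDSS warning shown to the prescriber, with their recorded response."""

    ordered_medication_id: str
    assessment: DoseAssessment
    displayed_at: str                     # "order-entry" (POE) or "countersignature" (NOE)
    response: str = "pending"             # complied | ignored | pending


def estimate_gfr(
    length_cm: float,
    serum_creatinine: float,
    maturity: str = "term",
    k_term: float = 0.45,
    k_preterm: float = 0.33,
) -> float:
    """Estimate GFR (mL/min/1.73 m²) with the pediatric Schwartz formula.

    GFR = k × length / Scr, with the proportionality constant k chosen per
    maturity class (term vs preterm).  The constants are configuration, not
    doctrine; local practice may substitute others.
    """
    if serum_creatinine <= 0:
        raise ValueError("serum creatinine must be positive (mg/dL)")
    if length_cm <= 0:
        raise ValueError("length must be positive (cm)")
    k = {"term": k_term, "preterm": k_preterm}.get(maturity)
    if k is None:
        raise ValueError(f"maturity must be 'term' or 'preterm', got {maturity!r}")
    return k * length_cm / serum_creatinine


class KnowledgeBase:
    """Validated collection of :class:`DoseRule` entries.

    Load-time validation rejects any pair of rules for the same drug and
    indication whose applicability bands overlap, so that at most one rule
    can ever match a patient state.  A wildcard-indication rule is shadowed
    by an indication-specific rule at match time.
    """

    def __init__(self, rules: Sequence[DoseRule]):
        self.rules = list(rules)
        self._validate()

    def _validate(self) -> None:
        by_group: dict[tuple[str, str], list[DoseRule]] = {}
        for rule in self.rules:
            by_group.setdefault((rule.drug, rule.indication), []).append(rule)
        for (drug, indication), group in by_group.items():
            for i, a in enumerate(group):
                for b in group[i + 1:]:
                    if _bands_overlap(a, b):
                        raise KnowledgeBaseError(
                            f"overlapping rules for {drug}/{indication}: "
                            f"GA {a.ga_band} PNA {a.pna_band} vs "
                            f"GA {b.ga_band} PNA {b.pna_band}"
                        )

    @property
    def drugs(self) -> list[str]:
        return sorted({r.drug for r in self.rules})

    def match(self, state: PatientState, drug: str) -> Optional[DoseRule]:
        """Return the unique applicable rule, or None for an unlisted drug.

        None mirrors the real system's silence on drugs outside the knowledge
        base (anything other than the covered antibiotics/anticonvulsants).
        """
        applicable = [r for r in self.rules if r.drug == drug and r.applies_to(state)]
        specific = [r for r in applicable if r.indication != ANY_INDICATION]
        pool = specific or applicable
        if not pool:
            return None
        if len(pool) > 1:
            raise KnowledgeBaseError(
                f"{len(pool)} overlapping rules match {drug} for patient "
                f"{state.patient_id}"
            )
        return pool[0]


def _intervals_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _bands_overlap(a: DoseRule, b: DoseRule) -> bool:
    if not _intervals_overlap(a.ga_band, b.ga_band):
        return False
    if not _intervals_overlap(a.pna_band, b.pna_band):
        return False
    if a.weight_band is not None and b.weight_band is not None:
        if not _intervals_overlap(a.weight_band, b.weight_band):
            return False
    # GFR applicability is the half-open interval [floor, threshold)
    a_lo, a_hi = a.gfr_floor or 0.0, a.gfr_threshold or float("inf")
    b_lo, b_hi = b.gfr_floor or 0.0, b.gfr_threshold or float("inf")
    return a_lo < b_hi and b_lo < a_hi


def load_kb(path=None) -> KnowledgeBase:
    """Load a knowledge base from YAML (the packaged illustrative KB by default)."""
    if path is None:
        source = resources.files("neodose").joinpath("data/knowledge_base.yaml")
        raw = yaml.safe_load(source.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    rules: list[DoseRule] = []
    for entry in raw["drugs"]:
        for raw in entry["rules"]:
            try:
                rules.append(
                    DoseRule(
                        drug=entry["drug"],
                        pharmaceutical_form=entry.get("form", "vial"),
                        indication=raw.get("indication", ANY_INDICATION),
                        ga_band=tuple(raw["ga_weeks"]),
                        pna_band=tuple(raw["pna_days"]),
                        recommended_dose_per_kg=raw["dose_mg_per_kg"],
                        recommended_interval=raw["interval_hours"],
                        tolerance=raw.get("tolerance", 0.10),
                        weight_band=tuple(raw["weight_g"]) if "weight_g" in raw else None,
                        gfr_threshold=raw.get("gfr_below"),
                        gfr_floor=raw.get("gfr_at_least"),
                    )
                )
            except KnowledgeBaseError as exc:
                logger.warning("rejected rule for %s: %s", entry.get("drug"), exc)
    return KnowledgeBase(rules)


def assess(
    prescribed_dose: float,
    prescribed_interval: int,
    state: PatientState,
    rule: DoseRule,
) -> DoseAssessment:
    """Check a prescribed dose (mg) and interval (h) against the matched rule.

    severity_pct is the prescribed dose as a percentage of the recommended
    dose for the patient's current weight.  A dose outside the rule's
    tolerance band is an overdose/underdose; an interval differing from the
    recommended one is curtailed (shorter) or prolonged (longer).  A line
    with both defects is labelled by its dose status and carries the
    interval defect as a flag, so it is counted once.
    """
    if prescribed_dose <= 0:
        raise ValueError("prescribed dose must be positive (mg)")
    if not rule.applies_to(state):
        raise ValueError(
            f"rule for {rule.drug} ({rule.ga_band} wk, {rule.pna_band} d) "
            f"does not apply to patient {state.patient_id}"
        )
    recommended = rule.recommended_dose_mg(state)
    severity = 100.0 * prescribed_dose / recommended

    if severity > 100.0 * (1 + rule.tolerance):
        dose_status = STATUS_OVERDOSE
        detail = f"dose {severity:.0f}% of recommended {recommended:.1f} mg"
    elif severity < 100.0 * (1 - rule.tolerance):
        dose_status = STATUS_UNDERDOSE
        detail = f"dose {severity:.0f}% of recommended {recommended:.1f} mg"
    else:
        dose_status = STATUS_CORRECT
        detail = ""

    if prescribed_interval < rule.recommended_interval:
        interval_status = STATUS_CURTAILED
        idetail = (
            f"interval {prescribed_interval} h shorter than recommended "
            f"{rule.recommended_interval} h"
        )
    elif prescribed_interval > rule.recommended_interval:
        interval_status = STATUS_PROLONGED
        idetail = (
            f"interval {prescribed_interval} h longer than recommended "
            f"{rule.recommended_interval} h"
        )
    else:
        interval_status = STATUS_CORRECT
        idetail = ""

    if dose_status != STATUS_CORRECT:
        status = dose_status
        interval_flag = interval_status if interval_status != STATUS_CORRECT else None
        explanation = "; ".join(x for x in (detail, idetail) if x)
    elif interval_status != STATUS_CORRECT:
        status, interval_flag, explanation = interval_status, None, idetail
    else:
        status, interval_flag, explanation = STATUS_CORRECT, None, "dose and interval within range"

    return DoseAssessment(
        status=status,
        severity_pct=severity,
        recommended_dose=recommended,
        recommended_interval=rule.recommended_interval,
        explanation=explanation,
        matched_rule=rule,
        interval_flag=interval_flag,
    )


def generate_warning(
    assessment: DoseAssessment, step: str, ordered_medication_id: str = ""
) -> WarningMessage:
    """Emit the warning a non-correct assessment triggers at a workflow step.

    A renewed order with the same erroneous dosage is re-assessed and emits a
    fresh warning; warnings never exist for correct assessments.
    """
    if not assessment.is_error:
        raise ValueError("warnings are only generated for erroneous assessments")
    if step not in ("order-entry", "countersignature"):
        raise ValueError(f"unknown workflow step {step!r}")
    return WarningMessage(
        ordered_medication_id=ordered_medication_id,
        assessment=assessment,
        displayed_at=step,
    )


def severity_category(severity_pct: float, bins: Sequence[float] = (150.0, 200.0)) -> int:
    """Ordinal severity category of an overdose (1 = mildest).

    With the default cuts the bins are (100, 150], (150, 200) and [200, ∞):
    the top bin is closed on the left so that a two-fold dose falls in the
    most severe category.  ``bins`` is the ordered sequence of interior cuts.
    """
    if severity_pct <= 100:
        raise ValueError("severity categories are defined for overdoses only (>100%)")
    cuts = sorted(bins)
    if not cuts:
        return 1
    cat = 1 + sum(severity_pct > c for c in cuts[:-1]) + (severity_pct >= cuts[-1])
    return cat
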