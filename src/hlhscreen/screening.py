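"""Screening-rule evaluation: simple conjunctive predicates over a patient
record (ferritin cutoff, fever, thrombocytopaenia) scored against a
reference standard as a 2x2 confusion matrix.

The motivating use is hyperferritinaemia triage: e.g. "fever AND ferritin
> 5,000 ug/L" as a bedside screen for secondary HLH, judged against HLH-04
or HScore positivity. Censored ferritins compare as the assay ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Callable, Iterable, Literal, Sequence

import pandas as pd

from .cohort import Cohort, PatientRecord
from .hlh04 import HLH04Policy, hlh04
from .hscore import HScorePolicy, hscore

__all__ = [
    "ScreeningRule",
    "ConfusionMatrix",
    "apply_rule",
    "evaluate_rule",
    "rule_grid",
    "percent_display",
]

ReferenceStandard = Literal["hlh04", "hscore", "clinician"]


def percent_display(fraction: float) -> str:
    """A proportion as a percent string, one decimal, half-up: 0.683 ->
    '68.3'."""
    return str(Decimal(fraction * 100).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ScreeningRule:
    """Conjunction of up to three predicates; all active parts must hold.

    ``ferritin_cutoff_ugL``: ferritin strictly greater than this;
    ``require_fever``: documented fever present;
    ``platelet_cutoff_1e9L``: platelets strictly below this.
    """

    ferritin_cutoff_ugL: float | None = None
    require_fever: bool = False
    platelet_cutoff_1e9L: float | None = None

    def __post_init__(self) -> None:
        if self.ferritin_cutoff_ugL is None and not self.require_fever and self.platelet_cutoff_1e9L is None:
            raise ValueError("screening rule must have at least one active predicate")
        if self.ferritin_cutoff_ugL is not None and self.ferritin_cutoff_ugL <= 0:
            raise ValueError("ferritin cutoff must be positive")

    def describe(self) -> str:
        parts = []
        if self.ferritin_cutoff_ugL is not None:
            parts.append(f"ferritin > {self.ferritin_cutoff_ugL:g} ug/L")
        if self.require_fever:
            parts.append("fever")
        if self.platelet_cutoff_1e9L is not None:
            parts.append(f"platelets < {self.platelet_cutoff_1e9L:g} x10^9/L")
        return " AND ".join(parts)


#: Sentinel for a patient who cannot be evaluated under the current policy.
UNEVALUABLE = None

MissingPolicy = Literal["fail", "exclude"]


def apply_rule(
    rule: ScreeningRule, p: PatientRecord, missing_policy: MissingPolicy = "fail"
) -> bool | None:
    """Does the patient satisfy the rule?

    Missing required inputs either fail the rule (``"fail"``, default —
    conservative screening: an unknown fever cannot trigger a screen) or
    mark the patient :data:`UNEVALUABLE` (``"exclude"``).
    """
    missing = False
    if rule.ferritin_cutoff_ugL is not None:
        # censored value carries the ceiling; strict inequality
        if not p.ferritin_ugL.value > rule.ferritin_cutoff_ugL:
            return False
    if rule.require_fever:
        fever = p.has_fever()
        if fever is None:
            missing = True
        elif not fever:
            return False
    if rule.platelet_cutoff_1e9L is not None:
        if p.platelets_1e9L is None:
            missing = True
        elif not p.platelets_1e9L < rule.platelet_cutoff_1e9L:
            return False
    if missing:
        return UNEVALUABLE if missing_policy == "exclude" else False
    return True


@dataclass
class ConfusionMatrix:
    """2x2 rule outcome vs reference standard; rates as proportions."""

    tp: int
    fp: int
    tn: int
    fn: int
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float | None:
        """tp/(tp+fn); None when the reference has no positives."""
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def specificity(self) -> float | None:
        denom = self.tn + self.fp
        return self.tn / denom if denom else None

    @property
    def youden(self) -> float | None:
        if self.sensitivity is None or self.specificity is None:
            return None
        return self.sensitivity + self.specificity - 1

    def summary(self) -> str:
        sens = percent_display(self.sensitivity) + "%" if self.sensitivity is not None else "undefined"
        spec = percent_display(self.specificity) + "%" if self.specificity is not None else "undefined"
        return (
            f"tp={self.tp} fp={self.fp} tn={self.tn} fn={self.fn} "
            f"sensitivity={sens} specificity={spec}"
        )


def _reference_labels(
    cohort: Cohort,
    reference: ReferenceStandard | Sequence[bool] | Callable[[PatientRecord], bool],
    hscore_policy: HScorePolicy | None,
    hlh04_policy: HLH04Policy | None,
) -> list[bool]:
    if isinstance(reference, str):
        if reference == "hlh04":
            return [hlh04(p, hlh04_policy).positive for p in cohort]
        if reference == "hscore":
            return [hscore(p, hscore_policy).positive for p in cohort]
        if reference == "clinician":
            return [p.clinician_hlh_diagnosis for p in cohort]
        raise ValueError(f"unknown reference standard {reference!r}")
    if callable(reference):
        return [bool(reference(p)) for p in cohort]
    labels = [bool(v) for v in reference]
    if len(labels) != len(cohort):
        raise ValueError("reference label vector length does not match cohort size")
    return labels


def evaluate_rule(
    rule: ScreeningRule,
    cohort: Cohort,
    reference: ReferenceStandard | Sequence[bool] | Callable[[PatientRecord], bool] = "hlh04",
    missing_policy: MissingPolicy = "fail",
    hscore_policy: HScorePolicy | None = None,
    hlh04_policy: HLH04Policy | None = None,
) -> ConfusionMatrix:
    """Cross the rule's per-patient outcome with a reference standard.

    ``reference`` may be a named standard (``"hlh04"`` — the default,
    ``"hscore"``, ``"clinician"``), an explicit label vector, or a
    predicate over records (e.g. generator truth on synthetic cohorts).
    """
    labels = _reference_labels(cohort, reference, hscore_policy, hlh04_policy)
    tp = fp = tn = fn = excluded = 0
    for p, truth in zip(cohort, labels):
        outcome = apply_rule(rule, p, missing_policy)
        if outcome is UNEVALUABLE:
            excluded += 1
            continue
        if outcome and truth:
            tp += 1
        elif outcome:
            fp += 1
        elif truth:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp, fp, tn, fn, n_excluded=excluded)


def rule_grid(
    cohort: Cohort,
    ferritin_cutoffs: Iterable[float],
    with_fever: Iterable[bool] = (True, False),
    platelet_cutoffs: Iterable[float | None] = (None,),
    reference: ReferenceStandard | Sequence[bool] = "hlh04",
    missing_policy: MissingPolicy = "fail",
    hscore_policy: HScorePolicy | None = None,
    hlh04_policy: HLH04Policy | None = None,
) -> pd.DataFrame:
    """Evaluate every rule combination; one row each, sorted by Youden
    index descending (ties: lower ferritin cutoff first)."""
    if len(cohort) == 0:
        raise ValueError("rule_grid: empty cohort")
    ferritin_cutoffs = list(ferritin_cutoffs)
    with_fever = list(with_fever)
    platelet_cutoffs = list(platelet_cutoffs)
    if not ferritin_cutoffs or not with_fever or not platelet_cutoffs:
        raise ValueError("rule_grid: all grids must be non-empty")
    rows = []
    for fc in ferritin_cutoffs:
        for fever in with_fever:
            for pc in platelet_cutoffs:
                rule = ScreeningRule(fc, fever, pc)
                cm = evaluate_rule(
                    rule, cohort, reference, missing_policy, hscore_policy, hlh04_policy
                )
                rows.append(
                    {
                        "rule": rule.describe(),
                        "ferritin_cutoff_ugL": fc,
                        "require_fever": fever,
                        "platelet_cutoff_1e9L": pc,
                        "tp": cm.tp,
                        "fp": cm.fp,
                        "tn": cm.tn,
                        "fn": cm.fn,
                        "sensitivity": cm.sensitivity,
                        "specificity": cm.specificity,
                        "youden": cm.youden,
                    }
                )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["youden", "ferritin_cutoff_ugL"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df
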