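"""Revised HLH-04 criteria: an eight-item checklist, positive at >=5/8.

Criteria: fever; splenomegaly; ferritin >=500 ug/L; cytopaenia in >=2
lineages (haemoglobin <=90 g/L, platelets <=100e9/L, neutrophils <=1e9/L);
hypertriglyceridaemia (>=3 mmol/L) OR hypofibrinogenaemia (<=1.5 g/L) —
one point maximum for the pair; haemophagocytosis in marrow, spleen or
nodes; low/absent NK-cell activity; soluble CD25 >=2,400 U/mL.

Under the default missing-data policy an unmeasured input leaves its
criterion unmet, so in cohorts where NK activity and sCD25 were never
assayed the effective ceiling is 6/8 — the 5/8 rule still applies to that
reduced set, which matches retrospective practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .cohort import Cohort, PatientRecord

__all__ = ["HLH04Policy", "HLH04Result", "ScoringCrossTab", "hlh04", "compare_scoring_systems"]


@dataclass(frozen=True)
class HLH04Policy:
    """``on_missing="unmet"`` (default) treats unmeasured inputs as
    not fulfilling their criterion; ``"error"`` raises instead."""

    on_missing: Literal["unmet", "error"] = "unmet"
    positivity_threshold: int = 5


@dataclass
class HLH04Result:
    met_fever: bool
    met_splenomegaly: bool
    met_ferritin: bool
    met_cytopaenia: bool
    met_tg_or_fibrinogen: bool
    met_haemophagocytosis: bool
    met_nk_low: bool
    met_scd25: bool
    count: int
    positive: bool

    @property
    def criteria(self) -> dict[str, bool]:
        return {
            "fever": self.met_fever,
            "splenomegaly": self.met_splenomegaly,
            "ferritin": self.met_ferritin,
            "cytopaenia": self.met_cytopaenia,
            "tg_or_fibrinogen": self.met_tg_or_fibrinogen,
            "haemophagocytosis": self.met_haemophagocytosis,
            "nk_low": self.met_nk_low,
            "scd25": self.met_scd25,
        }


def _flag(value, policy: HLH04Policy, name: str) -> bool:
    if value is None:
        if policy.on_missing == "error":
            raise ValueError(f"HLH-04 input missing: {name}")
        return False
    return bool(value)


def hlh04(p: PatientRecord, policy: HLH04Policy | None = None) -> HLH04Result:
    """Evaluate the revised HLH-04 criteria for one patient.

    Boundary values meet their criteria as printed: ferritin exactly 500,
    triglycerides exactly 3, fibrinogen exactly 1.5 and sCD25 exactly
    2,400 all qualify. Hepatomegaly plays no role here.
    """
    policy = policy or HLH04Policy()

    fever = _flag(p.has_fever(), policy, "fever")
    spleno = _flag(p.splenomegaly, policy, "splenomegaly")
    ferritin = p.ferritin_ugL.value >= 500

    lineages = 0
    if p.haemoglobin_gL is not None and p.haemoglobin_gL <= 90:
        lineages += 1
    if p.platelets_1e9L is not None and p.platelets_1e9L <= 100:
        lineages += 1
    if p.neutrophils_1e9L is not None and p.neutrophils_1e9L <= 1:
        lineages += 1
    if policy.on_missing == "error" and all(
        v is None for v in (p.haemoglobin_gL, p.platelets_1e9L, p.neutrophils_1e9L)
    ):
        raise ValueError("HLH-04 input missing: cytopaenia labs")
    cytopaenia = lineages >= 2

    tg_met = p.triglycerides_mmolL is not None and p.triglycerides_mmolL >= 3
    fib_met = p.fibrinogen_gL is not None and p.fibrinogen_gL <= 1.5
    if policy.on_missing == "error" and p.triglycerides_mmolL is None and p.fibrinogen_gL is None:
        raise ValueError("HLH-04 input missing: triglycerides and fibrinogen")
    tg_or_fib = tg_met or fib_met  # the pair awards one point maximum

    haemophag = _flag(p.haemophagocytosis, policy, "haemophagocytosis")
    nk_low = _flag(p.nk_activity_low, policy, "nk_activity_low")
    if p.scd25_UmL is None:
        if policy.on_missing == "error":
            raise ValueError("HLH-04 input missing: scd25")
        scd25 = False
    else:
        scd25 = p.scd25_UmL >= 2400

    flags = [fever, spleno, ferritin, cytopaenia, tg_or_fib, haemophag, nk_low, scd25]
    count = sum(flags)
    return HLH04Result(
        met_fever=fever,
        met_splenomegaly=spleno,
        met_ferritin=ferritin,
        met_cytopaenia=cytopaenia,
        met_tg_or_fibrinogen=tg_or_fib,
        met_haemophagocytosis=haemophag,
        met_nk_low=nk_low,
        met_scd25=scd25,
        count=count,
        positive=count >= policy.positivity_threshold,
    )


@dataclass
class ScoringCrossTab:
    """2x2 cross-tabulation of HScore vs HLH-04 positivity with the
    discordant patient ids."""

    both_positive: int
    hscore_only: int
    hlh04_only: int
    both_negative: int
    hscore_only_ids: list[str]
    hlh04_only_ids: list[str]

    @property
    def table(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (
            (self.both_positive, self.hscore_only),
            (self.hlh04_only, self.both_negative),
        )


def compare_scoring_systems(
    cohort: Cohort | Iterable[PatientRecord],
    hscore_policy=None,
    hlh04_policy: HLH04Policy | None = None,
) -> ScoringCrossTab:
    """Cross-tabulate HScore positivity against HLH-04 positivity over a
    cohort, listing the discordant patients."""
    from .hscore import hscore

    both_pos = h_only = l_only = both_neg = 0
    h_ids: list[str] = []
    l_ids: list[str] = []
    for p in cohort:
        h = hscore(p, hscore_policy).positive
        l = hlh04(p, hlh04_policy).positive
        if h and l:
            both_pos += 1
        elif h:
            h_only += 1
            h_ids.append(p.patient_id)
        elif l:
            l_only += 1
            l_ids.append(p.patient_id)
        else:
            both_neg += 1
    return ScoringCrossTab(both_pos, h_only, l_only, both_neg, h_ids, l_ids)
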