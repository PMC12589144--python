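"""The HScore: a weighted points-based diagnostic score for reactive HLH.

Nine components contribute fixed point values; the total (0-337) maps to a
probability of secondary HLH, and totals at or above a cutoff (169) are
treated as positive (93% sensitive, 86% specific in the derivation study).

Component bands and points:

===================  =======================================  ============
component            bands                                    points
===================  =======================================  ============
temperature (C)      <38.4 / 38.4-39.4 / >=39.4               0 / 33 / 49
organomegaly         neither / either / both                  0 / 23 / 38
immunosuppression    no / yes (HIV+ or long-term therapy)     0 / 18
ferritin (ug/L)      <2,000 / 2,000-6,000 / >6,000            0 / 35 / 50
cytopaenia lineages  0-1 / 2 / 3                              0 / 24 / 34
triglycerides        <1.5 / 1.5-4 / >4  (mmol/L)              0 / 44 / 64
fibrinogen (g/L)     >=2.5 / <2.5                             0 / 30
transaminases        AST <30 / AST >=30 (ALT >=100 fallback)  0 / 19
haemophagocytosis    no / yes                                 0 / 35
===================  =======================================  ============

Two retrospective-audit policies are built in and on by default: patients
with a documented fever but no charted temperature score the middle fever
band (33 points), and ALT >= 100 substitutes for the transaminase criterion
when AST was never measured. Missing inputs score 0 under the default
policy — an unrequested test cannot contribute points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Literal

import yaml

from .cohort import PatientRecord

__all__ = [
    "HScorePolicy",
    "HScoreResult",
    "BandTable",
    "hscore",
    "hscore_positive",
    "probability_band",
    "default_band_table",
    "HSCORE_MAX_TOTAL",
    "HSCORE_DEFAULT_CUTOFF",
]

HSCORE_MAX_TOTAL = 337  # 49+38+18+50+34+64+30+19+35
HSCORE_DEFAULT_CUTOFF = 169

# Allowed point sets per component, in worsening order.
COMPONENT_POINTS: dict[str, tuple[int, ...]] = {
    "fever": (0, 33, 49),
    "organomegaly": (0, 23, 38),
    "immunosuppression": (0, 18),
    "ferritin": (0, 35, 50),
    "cytopaenia": (0, 24, 34),
    "triglycerides": (0, 44, 64),
    "fibrinogen": (0, 30),
    "transaminase": (0, 19),
    "haemophagocytosis": (0, 35),
}


@dataclass(frozen=True)
class HScorePolicy:
    """Tunable scoring conventions.

    ``cutoff``/``strict_cutoff``: positivity is ``total >= cutoff`` by
    default (the study counted patients "scoring >=169"); set
    ``strict_cutoff`` for the alternative ``total > cutoff`` reading.
    ``documented_fever_points``: points awarded when only a documented-
    fever flag (no exact temperature) is available; the study awarded the
    middle band, 33.
    ``on_missing``: ``"zero"`` scores missing inputs 0; ``"error"`` raises
    when any scoring input is missing.
    Cytopaenia lineage thresholds follow the shared criteria table:
    haemoglobin <=90 g/L, platelets <=100e9/L, neutrophils <=1e9/L.
    """

    cutoff: int = HSCORE_DEFAULT_CUTOFF
    strict_cutoff: bool = False
    documented_fever_points: int = 33
    on_missing: Literal["zero", "error"] = "zero"
    ast_precedence: bool = True  # ALT used only when AST missing
    haemoglobin_threshold_gL: float = 90.0
    platelet_threshold_1e9L: float = 100.0
    neutrophil_threshold_1e9L: float = 1.0


@dataclass
class HScoreResult:
    points_fever: int
    points_organomegaly: int
    points_immunosuppression: int
    points_ferritin: int
    points_cytopaenia: int
    points_triglycerides: int
    points_fibrinogen: int
    points_transaminase: int
    points_haemophagocytosis: int
    total: int
    positive: bool
    probability_band: str
    component_basis: dict[str, str] = field(default_factory=dict)

    @property
    def components(self) -> dict[str, int]:
        return {
            "fever": self.points_fever,
            "organomegaly": self.points_organomegaly,
            "immunosuppression": self.points_immunosuppression,
            "ferritin": self.points_ferritin,
            "cytopaenia": self.points_cytopaenia,
            "triglycerides": self.points_triglycerides,
            "fibrinogen": self.points_fibrinogen,
            "transaminase": self.points_transaminase,
            "haemophagocytosis": self.points_haemophagocytosis,
        }


class MissingInputError(ValueError):
    """Raised under ``on_missing="error"`` when a scoring input is absent."""


def _missing(name: str, policy: HScorePolicy, basis: dict[str, str]) -> int:
    if policy.on_missing == "error":
        raise MissingInputError(f"HScore input missing: {name}")
    basis[name] = "missing -> 0"
    return 0


def _fever_points(p: PatientRecord, policy: HScorePolicy, basis: dict[str, str]) -> int:
    if p.temperature_celsius is not None:
        t = p.temperature_celsius
        basis["fever"] = f"temperature {t:g} C"
        if t >= 39.4:
            return 49
        if t >= 38.4:
            return 33
        return 0
    if p.fever_documented is not None:
        basis["fever"] = "documented-fever flag"
        return policy.documented_fever_points if p.fever_documented else 0
    return _missing("fever", policy, basis)


def _organomegaly_points(p: PatientRecord, policy: HScorePolicy, basis: dict[str, str]) -> int:
    if p.hepatomegaly is None and p.splenomegaly is None:
        return _missing("organomegaly", policy, basis)
    n = int(bool(p.hepatomegaly)) + int(bool(p.splenomegaly))
    basis["organomegaly"] = f"{n} organ(s) enlarged"
    return (0, 23, 38)[n]


def _ferritin_points(p: PatientRecord, basis: dict[str, str]) -> int:
    f = p.ferritin_ugL.value  # censored carries the ceiling, still > 6,000
    basis["ferritin"] = str(p.ferritin_ugL)
    if f > 6000:
        return 50
    if f >= 2000:
        return 35
    return 0


def _cytopaenia_points(p: PatientRecord, policy: HScorePolicy, basis: dict[str, str]) -> int:
    labs = (p.haemoglobin_gL, p.platelets_1e9L, p.neutrophils_1e9L)
    if all(v is None for v in labs):
        return _missing("cytopaenia", policy, basis)
    lineages = 0
    if p.haemoglobin_gL is not None and p.haemoglobin_gL <= policy.haemoglobin_threshold_gL:
        lineages += 1
    if p.platelets_1e9L is not None and p.platelets_1e9L <= policy.platelet_threshold_1e9L:
        lineages += 1
    if (
        p.neutrophils_1e9L is not None
        and p.neutrophils_1e9L <= policy.neutrophil_threshold_1e9L
    ):
        lineages += 1
    basis["cytopaenia"] = f"{lineages} lineage(s)"
    return (0, 0, 24, 34)[lineages]


def _triglyceride_points(p: PatientRecord, policy: HScorePolicy, basis: dict[str, str]) -> int:
    if p.triglycerides_mmolL is None:
        return _missing("triglycerides", policy, basis)
    tg = p.triglycerides_mmolL
    basis["triglycerides"] = f"{tg:g} mmol/L"
    if tg > 4:
        return 64
    if tg >= 1.5:
        return 44
    return 0


def _fibrinogen_points(p: PatientRecord, policy: HScorePolicy, basis: dict[str, str]) -> int:
    if p.fibrinogen_gL is None:
        return _missing("fibrinogen", policy, basis)
    basis["fibrinogen"] = f"{p.fibrinogen_gL:g} g/L"
    return 30 if p.fibrinogen_gL < 2.5 else 0


def _transaminase_points(p: PatientRecord, policy: HScorePolicy, basis: dict[str, str]) -> int:
    if policy.ast_precedence and p.ast_UL is not None:
        basis["transaminase"] = f"AST {p.ast_UL:g} U/L"
        return 19 if p.ast_UL >= 30 else 0
    if p.alt_UL is not None:
        basis["transaminase"] = f"ALT {p.alt_UL:g} U/L (AST unavailable)"
        return 19 if p.alt_UL >= 100 else 0
    if p.ast_UL is not None:  # ast_precedence off but only AST present
        basis["transaminase"] = f"AST {p.ast_UL:g} U/L"
        return 19 if p.ast_UL >= 30 else 0
    return _missing("transaminase", policy, basis)


def _haemophagocytosis_points(p: PatientRecord, policy: HScorePolicy, basis: dict[str, str]) -> int:
    if p.haemophagocytosis is None:
        return _missing("haemophagocytosis", policy, basis)
    basis["haemophagocytosis"] = "present" if p.haemophagocytosis else "absent"
    return 35 if p.haemophagocytosis else 0


def _immunosuppression_points(p: PatientRecord, policy: HScorePolicy, basis: dict[str, str]) -> int:
    if p.immunosuppressed is None:
        return _missing("immunosuppression", policy, basis)
    basis["immunosuppression"] = "yes" if p.immunosuppressed else "no"
    return 18 if p.immunosuppressed else 0


def hscore_positive(total: int, cutoff: int = HSCORE_DEFAULT_CUTOFF, strict: bool = False) -> bool:
    """Positivity at the cutoff: ``total >= cutoff`` (or strictly greater
    when ``strict``)."""
    return total > cutoff if strict else total >= cutoff


def hscore(
    p: PatientRecord,
    policy: HScorePolicy | None = None,
    band_table: "BandTable | None" = None,
) -> HScoreResult:
    """Compute the HScore for one patient."""
    policy = policy or HScorePolicy()
    basis: dict[str, str] = {}
    pts = {
        "fever": _fever_points(p, policy, basis),
        "organomegaly": _organomegaly_points(p, policy, basis),
        "immunosuppression": _immunosuppression_points(p, policy, basis),
        "ferritin": _ferritin_points(p, basis),
        "cytopaenia": _cytopaenia_points(p, policy, basis),
        "triglycerides": _triglyceride_points(p, policy, basis),
        "fibrinogen": _fibrinogen_points(p, policy, basis),
        "transaminase": _transaminase_points(p, policy, basis),
        "haemophagocytosis": _haemophagocytosis_points(p, policy, basis),
    }
    total = sum(pts.values())
    return HScoreResult(
        points_fever=pts["fever"],
        points_organomegaly=pts["organomegaly"],
        points_immunosuppression=pts["immunosuppression"],
        points_ferritin=pts["ferritin"],
        points_cytopaenia=pts["cytopaenia"],
        points_triglycerides=pts["triglycerides"],
        points_fibrinogen=pts["fibrinogen"],
        points_transaminase=pts["transaminase"],
        points_haemophagocytosis=pts["haemophagocytosis"],
        total=total,
        positive=hscore_positive(total, policy.cutoff, policy.strict_cutoff),
        probability_band=probability_band(total, band_table),
        component_basis=basis,
    )


# ---------------------------------------------------------------------------
# Probability bands


@dataclass(frozen=True)
class Band:
    lo: int | None  # inclusive; None = open below
    hi: int | None  # inclusive; None = open above
    label: str
    interpolated: bool = False

    def contains(self, total: int) -> bool:
        return (self.lo is None or total >= self.lo) and (self.hi is None or total <= self.hi)


class BandTable:
    """Ordered, non-overlapping score intervals -> probability-band labels."""

    def __init__(self, bands: list[Band]):
        if not bands:
            raise ValueError("band table must be non-empty")
        for prev, cur in zip(bands, bands[1:]):
            if prev.hi is None or cur.lo is None or cur.lo != prev.hi + 1:
                raise ValueError(
                    f"bands must be contiguous and ordered: {prev} then {cur}"
                )
        self.bands = bands

    def lookup(self, total: int) -> Band:
        for band in self.bands:
            if band.contains(total):
                return band
        # out of range: clamp to sentinel end bands
        return self.bands[0] if (self.bands[0].lo is None or total < self.bands[0].lo) else self.bands[-1]

    @classmethod
    def from_yaml(cls, path) -> "BandTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls([Band(b.get("lo"), b.get("hi"), str(b["label"]), bool(b.get("interpolated"))) for b in raw["bands"]])


_DEFAULT_BAND_TABLE: BandTable | None = None


def default_band_table() -> BandTable:
    """The packaged calibration, anchored to the published (score, band)
    pairs; interval boundaries between anchors are interpolated."""
    global _DEFAULT_BAND_TABLE
    if _DEFAULT_BAND_TABLE is None:
        ref = resources.files("hlhscreen.data").joinpath("hscore_probability_bands.yaml")
        with resources.as_file(ref) as path:
            _DEFAULT_BAND_TABLE = BandTable.from_yaml(path)
    return _DEFAULT_BAND_TABLE


def probability_band(total: int, calibration: BandTable | None = None) -> str:
    """Probability-of-sHLH band label (percent, e.g. ``"54"``, ``">99"``)
    for a total score."""
    table = calibration or default_band_table()
    return table.lookup(total).label
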