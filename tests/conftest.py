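"""Shared fixtures and oracle helpers.

The record builders here realise each scoring band with concrete lab
values, so brute-force enumeration oracles (every HScore band combination;
every HLH-04 criterion pattern) can be written independently of the
engines they check.
"""

from __future__ import annotations

import itertools

import pytest

from hlhscreen import CensoredValue, PatientRecord

# ---------------------------------------------------------------------------
# HScore band realisations: (points, field overrides) per component, in
# worsening order. Point values restate the published scoring table.

HSCORE_BANDS: dict[str, list[tuple[int, dict]]] = {
    "fever": [
        (0, {"temperature_celsius": 37.0}),
        (33, {"temperature_celsius": 38.8}),
        (49, {"temperature_celsius": 39.6}),
    ],
    "organomegaly": [
        (0, {"hepatomegaly": False, "splenomegaly": False}),
        (23, {"hepatomegaly": True, "splenomegaly": False}),
        (38, {"hepatomegaly": True, "splenomegaly": True}),
    ],
    "immunosuppression": [
        (0, {"immunosuppressed": False}),
        (18, {"immunosuppressed": True}),
    ],
    "ferritin": [
        (0, {"ferritin_ugL": CensoredValue(1500)}),
        (35, {"ferritin_ugL": CensoredValue(3000)}),
        (50, {"ferritin_ugL": CensoredValue(9000)}),
    ],
    "cytopaenia": [
        (0, {"haemoglobin_gL": 120.0, "platelets_1e9L": 250.0, "neutrophils_1e9L": 3.0}),
        (24, {"haemoglobin_gL": 80.0, "platelets_1e9L": 60.0, "neutrophils_1e9L": 3.0}),
        (34, {"haemoglobin_gL": 80.0, "platelets_1e9L": 60.0, "neutrophils_1e9L": 0.5}),
    ],
    "triglycerides": [
        (0, {"triglycerides_mmolL": 1.0}),
        (44, {"triglycerides_mmolL": 2.5}),
        (64, {"triglycerides_mmolL": 5.0}),
    ],
    "fibrinogen": [
        (0, {"fibrinogen_gL": 3.0}),
        (30, {"fibrinogen_gL": 1.2}),
    ],
    "transaminase": [
        (0, {"ast_UL": 20.0}),
        (19, {"ast_UL": 60.0}),
    ],
    "haemophagocytosis": [
        (0, {"haemophagocytosis": False}),
        (35, {"haemophagocytosis": True}),
    ],
}


def make_record(**overrides) -> PatientRecord:
    """A patient with every scoring input at its benign band, overridable."""
    base = dict(
        patient_id="P",
        ferritin_ugL=CensoredValue(1500),
        temperature_celsius=37.0,
        hepatomegaly=False,
        splenomegaly=False,
        immunosuppressed=False,
        haemoglobin_gL=120.0,
        platelets_1e9L=250.0,
        neutrophils_1e9L=3.0,
        triglycerides_mmolL=1.0,
        fibrinogen_gL=3.0,
        ast_UL=20.0,
        alt_UL=30.0,
        haemophagocytosis=False,
    )
    base.update(overrides)
    return PatientRecord(**base)


def enumerate_hscore_combinations():
    """Yield (expected_total, record) over the full cartesian product of
    component bands: 3*3*2*3*3*3*2*2*2 = 2916 combinations."""
    names = list(HSCORE_BANDS)
    for choice in itertools.product(*(HSCORE_BANDS[n] for n in names)):
        expected = sum(points for points, _ in choice)
        overrides: dict = {}
        for _, fields in choice:
            overrides.update(fields)
        yield expected, make_record(**overrides)


# ---------------------------------------------------------------------------
# HLH-04 criterion-pattern realisations (the TG/fibrinogen pair is one bit).

HLH04_BITS = [
    ("fever", {True: {"fever_documented": True}, False: {"fever_documented": False}}),
    ("splenomegaly", {True: {"splenomegaly": True}, False: {"splenomegaly": False}}),
    ("ferritin", {True: {"ferritin_ugL": CensoredValue(600)}, False: {"ferritin_ugL": CensoredValue(400)}}),
    (
        "cytopaenia",
        {
            True: {"haemoglobin_gL": 80.0, "platelets_1e9L": 60.0, "neutrophils_1e9L": 3.0},
            False: {"haemoglobin_gL": 120.0, "platelets_1e9L": 250.0, "neutrophils_1e9L": 3.0},
        },
    ),
    ("tg_or_fibrinogen", {True: {"triglycerides_mmolL": 3.5}, False: {"triglycerides_mmolL": 1.0}}),
    ("haemophagocytosis", {True: {"haemophagocytosis": True}, False: {"haemophagocytosis": False}}),
    ("nk_low", {True: {"nk_activity_low": True}, False: {"nk_activity_low": False}}),
    ("scd25", {True: {"scd25_UmL": 3000.0}, False: {"scd25_UmL": 1000.0}}),
]


def enumerate_hlh04_patterns():
    """Yield (pattern_bools, record) over all 2**8 criterion patterns."""
    for bits in itertools.product([False, True], repeat=8):
        overrides: dict = {"fibrinogen_gL": 2.0}  # never meets <=1.5
        for (name, realisations), bit in zip(HLH04_BITS, bits):
            overrides.update(realisations[bit])
        yield bits, make_record(**overrides)


@pytest.fixture(scope="session")
def table2():
    from hlhscreen import table2_fixture

    return table2_fixture()
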