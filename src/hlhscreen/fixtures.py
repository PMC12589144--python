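"""Packaged in-study fixtures: the printed HScore-positive patients and the
group-comparison count table.

These are the rows the source study printed, shipped as small CSVs so the
replication statistics can be exercised without any external data. The full
120-patient cohort was never published; only the 14 HScore-positive rows
(conditions, peak ferritin, score, probability band) and the per-group
feature counts are available.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cohort import Cohort, PatientRecord, parse_ferritin

__all__ = ["table2_fixture", "table3_counts"]


def _data_path(name: str):
    return resources.files("hlhscreen.data").joinpath(name)


def table2_fixture() -> Cohort:
    """The 14 HScore-positive patients as a :class:`Cohort`.

    Each record carries the documented conditions, the peak ferritin (ten
    rows censored at the 16,500 ug/L assay ceiling) and the clinician HLH
    diagnosis flag. The published HScore totals and probability bands are
    attached under ``cohort.metadata["published_scores"]`` — they cannot be
    recomputed from these rows because the component inputs (temperature,
    counts, triglycerides, ...) were not printed.
    """
    with _data_path("table2_hscore_positive.csv").open() as fh:
        df = pd.read_csv(fh, dtype=str, keep_default_na=False)
    patients = [
        PatientRecord(
            patient_id=row.patient_id,
            ferritin_ugL=parse_ferritin(row.ferritin_ugL),
            conditions=[c.strip() for c in row.conditions.split(";")],
            clinician_hlh_diagnosis=row.clinician_hlh_diagnosis == "true",
        )
        for row in df.itertuples()
    ]
    published = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "hscore": df["published_hscore"].astype(int),
            "probability_band": df["published_probability_band"],
        }
    )
    return Cohort(
        patients,
        provenance="packaged fixture: published HScore-positive patients",
        metadata={"published_scores": published},
    )


def table3_counts() -> pd.DataFrame:
    """Published per-group feature counts (HScore < 169: n=106 vs >= 169:
    n=14) with the published test statistics and p-values."""
    with _data_path("table3_group_counts.csv").open() as fh:
        df = pd.read_csv(fh)
    return df
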