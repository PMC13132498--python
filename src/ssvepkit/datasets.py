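"""Bundled reference tables.

`load_crb1_demographics` returns the published demographics of an 18-patient
CRB1-retinopathy cohort (age, per-eye visual acuity including the
categorical entries HM and PL, phenotype, disease duration).  It is the
input for the cohort-descriptive computations and a convenient real-world
example of the HM/PL logMAR convention.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_crb1_demographics", "crb1_eye_table"]

#: Phenotype -> analysis group: macular dystrophy stays its own group;
#: LCA/EOSRD and advanced CRD pool into generalized retinal degeneration.
PHENOTYPE_GROUP = {"MD": "MD", "LCA/EOSRD": "GRD", "CRD": "GRD"}


def load_crb1_demographics() -> pd.DataFrame:
    """Patient-level table: one row per patient, acuity per eye (OS/OD)."""
    with resources.files("ssvepkit.data").joinpath("crb1_demographics.csv").open() as fh:
        return pd.read_csv(fh, dtype={"participant_id": str})


def crb1_eye_table() -> pd.DataFrame:
    """Eye-level long table with the MD/GRD grouping attached.

    Columns: participant_id, eye, acuity_raw, age, disease_duration,
    phenotype, group — the layout the descriptive and validity analyses
    expect (36 rows: 18 patients x 2 eyes).
    """
    wide = load_crb1_demographics()
    rows = []
    for r in wide.itertuples():
        for eye, acuity in (("OS", r.va_os), ("OD", r.va_od)):
            rows.append(
                {
                    "participant_id": r.participant_id,
                    "eye": eye,
                    "acuity_raw": acuity,
                    "age": r.age,
                    "disease_duration": r.disease_duration,
                    "phenotype": r.phenotype,
                    "group": PHENOTYPE_GROUP[r.phenotype],
                }
            )
    return pd.DataFrame(rows)
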