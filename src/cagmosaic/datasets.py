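"""Small bundled reference values from a published postmortem SCA cohort.

These are per-individual expansion indices read off the descriptive table of
a four-disease postmortem brain cohort (SCA1/SCA2/SCA3/SCA7), kept here so
worked examples and regression checks can run without access to clinical
data.  Values are EI units; keys are tissue names.
"""

from __future__ import annotations

import pandas as pd

#: Per-individual cerebellar EIs by disease group.
CEREBELLUM_EI = {
    "SCA1": [1.26, 0.31, 0.36],
    "SCA2": [0.37],
    "SCA3": [0.76, 0.77, 0.59, 0.42],
    "SCA7": [0.52, 0.56],
}

#: Per-individual cortical EIs (the region with the highest mosaicism per
#: group: frontal cortex for SCA1-3, primary visual cortex for SCA7).
CORTEX_EI = {
    "SCA1": [3.52],
    "SCA2": [2.18],
    "SCA3": [2.01, 1.74, 1.60, 1.81],
    "SCA7": [1.72, 2.71],
}

#: Longitudinal blood draws of one SCA2 individual who died at 35: visit age
#: (years) -> EI.  The four visits took place 18, 17, 2 and 1 years before
#: death.
SCA2_BLOOD_VISITS = pd.DataFrame(
    {
        "individual_id": ["SCA2_pm4"] * 4,
        "age": [17.0, 18.0, 33.0, 34.0],
        "ei": [0.94, 0.79, 1.20, 1.20],
    }
)

#: Fetal/early-gestation EIs: four CNS regions of an SCA1 fetus (GW18), one
#: SCA3 fetal cortex (GW13) and one SCA7 fetal cortex (GW14).
FETAL_EI = {
    "SCA1": [0.053, 0.057, 0.058, 0.090],
    "SCA3": [0.066],
    "SCA7": [0.037],
}


def cerebellum_ei_frame() -> pd.DataFrame:
    """Long-format frame of the cerebellar EIs (columns group, ei)."""
    rows = [
        {"group": g, "ei": v} for g, vals in CEREBELLUM_EI.items() for v in vals
    ]
    return pd.DataFrame(rows)


def cortex_ei_frame() -> pd.DataFrame:
    """Long-format frame of the cortical EIs (columns group, ei)."""
    rows = [{"group": g, "ei": v} for g, vals in CORTEX_EI.items() for v in vals]
    return pd.DataFrame(rows)
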