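"""Fixed-effects design matrix shared by the generator and the model.

Treatment coding with the baselines of the study tables: rural residence,
no education, poorest wealth tier, male sex, age under 12 months, survey
year 2008.  Mother's age enters linearly in years, centred so intercepts
refer to a mother of average age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# full column set, in reporting order
FULL_DESIGN_COLUMNS = (
    "urban",
    "edu_primary",
    "edu_secondary_plus",
    "wealth_poorer_middle",
    "wealth_richer_richest",
    "female",
    "age_12_23",
    "age_24_59",
    "mother_age_c",
    "year_2013",
    "year_2018",
)


@dataclass(frozen=True)
class DesignInfo:
    columns: tuple[str, ...]
    age_center: float


def build_design(
    df: pd.DataFrame,
    age_center: float | None = None,
    year_dummies: str = "auto",
) -> tuple[np.ndarray, DesignInfo]:
    """Build the fixed-effects design matrix (no intercept column).

    Parameters
    ----------
    df
        Record table (see :mod:`comorbmap.records`).
    age_center
        Value subtracted from mother's age; defaults to the sample mean.
    year_dummies
        "auto" includes a dummy for each non-2008 year present in the data;
        "full" always includes 2013 and 2018 dummies (the generator's
        convention); "none" drops year terms (per-survey fits).
    """
    n = len(df)
    if age_center is None:
        age_center = float(df["mother_age"].mean()) if n else 0.0
    cols: dict[str, np.ndarray] = {
        "urban": (df["residence"] == "urban").to_numpy(float),
        "edu_primary": (df["education"] == "primary").to_numpy(float),
        "edu_secondary_plus": (df["education"] == "secondary_plus").to_numpy(float),
        "wealth_poorer_middle": (df["wealth"] == "poorer_middle").to_numpy(float),
        "wealth_richer_richest": (df["wealth"] == "richer_richest").to_numpy(float),
        "female": (df["sex"] == "female").to_numpy(float),
        "age_12_23": (df["age_band"] == "m12_23").to_numpy(float),
        "age_24_59": (df["age_band"] == "m24_59").to_numpy(float),
        "mother_age_c": df["mother_age"].to_numpy(float) - age_center,
    }
    if year_dummies == "full":
        year_cols = [2013, 2018]
    elif year_dummies == "auto":
        present = sorted(set(df["year"])) if n else []
        year_cols = [y for y in present if y != 2008]
    elif year_dummies == "none":
        year_cols = []
    else:
        raise ValueError(f"unknown year_dummies mode {year_dummies!r}")
    for y in year_cols:
        cols[f"year_{y}"] = (df["year"] == y).to_numpy(float)
    names = tuple(cols)
    x = np.column_stack([cols[c] for c in names]) if n else np.empty((0, len(names)))
    return x, DesignInfo(columns=names, age_center=age_center)
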