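"""Published aggregate counts of the pooled 2008/2013/2018 Nigeria DHS
child-morbidity sample.

The child-level NDHS micro-data are request-only, but the per-year
frequency table of the pooled analysis sample is public.  These counts
drive the worked examples: summing the year columns reproduces the pooled
study totals (61,579 children; 2,923 with ARI; 6,675 with diarrhoea;
8,940 stunted; 1,013 with both ARI and diarrhoea; 173 with all three),
and the ARI x diarrhoea 2x2 table assembled from the pooled margins feeds
the tetrachoric worked example.
"""

from __future__ import annotations

import pandas as pd

from .descriptives import TwoByTwoTable, pair_table_from_margins, pooled_summary

_PER_YEAR = {
    "2008": {
        "total_children": 23851,
        "ari": 1134,
        "diarrhoea": 2495,
        "stunting": 4055,
        "ari_and_diarrhoea": 371,
        "ari_and_stunting": 459,
        "diarrhoea_and_stunting": 205,
        "all_illnesses": 80,
        "residence_rural": 17298,
        "residence_urban": 6553,
        "education_none": 11714,
        "education_primary": 5471,
        "education_secondary_plus": 6666,
        "wealth_poorest": 6193,
        "wealth_poorer_middle": 10252,
        "wealth_richer_richest": 7406,
        "sex_male": 12040,
        "sex_female": 11811,
        "age_band_lt12": 6357,
        "age_band_m12_23": 4629,
        "age_band_m24_59": 12865,
    },
    "2013": {
        "total_children": 27524,
        "ari": 1114,
        "diarrhoea": 2868,
        "stunting": 3453,
        "ari_and_diarrhoea": 448,
        "ari_and_stunting": 393,
        "diarrhoea_and_stunting": 166,
        "all_illnesses": 64,
        "residence_rural": 18206,
        "residence_urban": 9318,
        "education_none": 12661,
        "education_primary": 5594,
        "education_secondary_plus": 9269,
        "wealth_poorest": 6020,
        "wealth_poorer_middle": 11813,
        "wealth_richer_richest": 9691,
        "sex_male": 13854,
        "sex_female": 13670,
        "age_band_lt12": 8762,
        "age_band_m12_23": 6916,
        "age_band_m24_59": 15085,
    },
    "2018": {
        "total_children": 10204,
        "ari": 675,
        "diarrhoea": 1312,
        "stunting": 1432,
        "ari_and_diarrhoea": 194,
        "ari_and_stunting": 202,
        "diarrhoea_and_stunting": 97,
        "all_illnesses": 29,
        "residence_rural": 6633,
        "residence_urban": 3571,
        "education_none": 4234,
        "education_primary": 1771,
        "education_secondary_plus": 4199,
        "wealth_poorest": 2283,
        "wealth_poorer_middle": 4570,
        "wealth_richer_richest": 3351,
        "sex_male": 5123,
        "sex_female": 5081,
        "age_band_lt12": 2533,
        "age_band_m12_23": 2054,
        "age_band_m24_59": 5617,
    },
}


def ndhs_reference_counts() -> pd.DataFrame:
    """Per-year reference counts (columns 2008/2013/2018, no pooled column)."""
    return pd.DataFrame(_PER_YEAR)


def ndhs_pooled_counts() -> pd.DataFrame:
    """Reference counts with the pooled column appended."""
    return pooled_summary(ndhs_reference_counts())


def ndhs_ari_diarrhoea_table() -> TwoByTwoTable:
    """Pooled ARI x diarrhoea 2x2 table assembled from the study margins."""
    pooled = ndhs_pooled_counts()["pooled"]
    return pair_table_from_margins(
        total=int(pooled["total_children"]),
        first=int(pooled["ari"]),
        second=int(pooled["diarrhoea"]),
        both=int(pooled["ari_and_diarrhoea"]),
    )
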