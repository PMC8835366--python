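"""Descriptive layer: prevalence summaries, 2x2 tables, tetrachoric
correlation, and per-area proportion correlations.

The tetrachoric correlation of two binary indicators is the correlation of
a latent standard bivariate normal assumed to underlie their 2x2 table.
Estimation is the classical two-step maximum-likelihood: thresholds are
fixed at the marginal normal quantiles h = Phi^-1(1 - p_row),
k = Phi^-1(1 - p_col), and the multinomial likelihood of the table is
maximized over the correlation alone.  The standard error comes from the
inverse observed information of the profile log-likelihood at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import multivariate_normal, norm

from .records import CATEGORIES, DISEASES, YEARS

__all__ = [
    "TwoByTwoTable",
    "TetrachoricResult",
    "summarize_counts",
    "pooled_summary",
    "pair_table",
    "pair_table_from_margins",
    "tetrachoric",
    "state_proportions",
    "pairwise_state_correlation",
]

_RHO_BOUND = 0.9999


@dataclass(frozen=True)
class TwoByTwoTable:
    """Joint counts of two binary indicators.

    ``n11`` both present, ``n10`` first only, ``n01`` second only,
    ``n00`` neither.
    """

    n11: float
    n10: float
    n01: float
    n00: float

    def __post_init__(self) -> None:
        for c in (self.n11, self.n10, self.n01, self.n00):
            if c < 0:
                raise ValueError("cell counts must be non-negative")
        if self.total <= 0:
            raise ValueError("table total must be positive for estimation")

    @property
    def total(self) -> float:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (self.n11, self.n10, self.n01, self.n00)


@dataclass(frozen=True)
class TetrachoricResult:
    rho: float
    se: float
    boundary: bool = False
    corrected: bool = False

    def __post_init__(self) -> None:
        if abs(self.rho) > 1:
            raise ValueError("|rho| cannot exceed 1")


# ---------------------------------------------------------------- summaries

_SUMMARY_ROWS = (
    "total_children",
    "ari",
    "diarrhoea",
    "stunting",
    "ari_and_diarrhoea",
    "ari_and_stunting",
    "diarrhoea_and_stunting",
    "all_illnesses",
    "residence_rural",
    "residence_urban",
    "education_none",
    "education_primary",
    "education_secondary_plus",
    "wealth_poorest",
    "wealth_poorer_middle",
    "wealth_richer_richest",
    "sex_male",
    "sex_female",
    "age_band_lt12",
    "age_band_m12_23",
    "age_band_m24_59",
)


def summarize_counts(records: pd.DataFrame) -> pd.DataFrame:
    """Per-year and pooled counts of each disease, pair, triple, and
    covariate category (one row per quantity, one column per year plus
    ``pooled``).  The pooled column is exactly the sum of year columns."""
    if len(records) == 0:
        raise ValueError("records must be non-empty")
    out = {}
    for year in YEARS:
        sub = records[records["year"] == year]
        a, d, s = (sub[c].to_numpy(bool) for c in DISEASES)
        col = {
            "total_children": len(sub),
            "ari": a.sum(),
            "diarrhoea": d.sum(),
            "stunting": s.sum(),
            "ari_and_diarrhoea": (a & d).sum(),
            "ari_and_stunting": (a & s).sum(),
            "diarrhoea_and_stunting": (d & s).sum(),
            "all_illnesses": (a & d & s).sum(),
        }
        for covar, levels in CATEGORIES.items():
            if covar not in ("residence", "education", "wealth", "sex", "age_band"):
                continue
            for lev in levels:
                col[f"{covar}_{lev}"] = int((sub[covar] == lev).sum())
        out[str(year)] = col
    table = pd.DataFrame(out, index=list(_SUMMARY_ROWS)).astype(np.int64)
    return pooled_summary(table)


def pooled_summary(per_year: pd.DataFrame) -> pd.DataFrame:
    """Append (or recompute) the pooled column as the sum of year columns.

    Accepts any integer table whose columns are survey years — e.g. the
    published per-year frequency table — so pooled study totals can be
    reproduced from printed per-year counts alone.
    """
    year_cols = [c for c in per_year.columns if str(c) != "pooled"]
    table = per_year[year_cols].copy()
    table["pooled"] = table[year_cols].sum(axis=1)
    return table


def percentage(table: pd.DataFrame, row: str, column: str = "pooled") -> float:
    """Percentage of children in ``row`` relative to the total, as printed
    in study tables (0-100 scale)."""
    return 100.0 * float(table.loc[row, column]) / float(table.loc["total_children", column])


# ---------------------------------------------------------------- 2x2 tables


def pair_table(records: pd.DataFrame, disease_a: str, disease_b: str) -> TwoByTwoTable:
    """Cross-tabulate two diseases over all records."""
    for d in (disease_a, disease_b):
        if d not in DISEASES:
            raise ValueError(f"unknown disease {d!r}")
    a = records[disease_a].to_numpy(bool)
    b = records[disease_b].to_numpy(bool)
    return TwoByTwoTable(
        n11=int((a & b).sum()),
        n10=int((a & ~b).sum()),
        n01=int((~a & b).sum()),
        n00=int((~a & ~b).sum()),
    )


def pair_table_from_margins(
    total: int, first: int, second: int, both: int
) -> TwoByTwoTable:
    """Assemble a 2x2 table from marginal totals and the joint count —
    the arithmetic used to rebuild tables from printed study totals."""
    return TwoByTwoTable(
        n11=both, n10=first - both, n01=second - both, n00=total - first - second + both
    )


# ---------------------------------------------------------------- tetrachoric


def _quadrant_prob(h: float, k: float, rho: float) -> float:
    """P(X > h, Y > k) under a standard bivariate normal (scipy CDF)."""
    phi2 = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf(
        np.array([h, k])
    )
    return float(phi2 - norm.cdf(h) - norm.cdf(k) + 1.0)


def tetrachoric_loglik(table: TwoByTwoTable, rho: float) -> float:
    """Profile multinomial log-likelihood of the table at correlation rho,
    thresholds fixed at the empirical marginal quantiles."""
    n11, n10, n01, n00 = table.cells
    n = table.total
    p1 = (n11 + n10) / n
    p2 = (n11 + n01) / n
    h = norm.ppf(1 - p1)
    k = norm.ppf(1 - p2)
    q11 = _quadrant_prob(h, k, rho)
    probs = np.array([q11, p1 - q11, p2 - q11, 1 - p1 - p2 + q11])
    if np.any(probs <= 0):
        return -np.inf
    return float(np.dot(table.cells, np.log(probs)))


def tetrachoric(
    table: TwoByTwoTable, continuity_correction: bool = True
) -> TetrachoricResult:
    """Two-step ML tetrachoric correlation with profile-likelihood SE.

    A zero margin returns the +/-1 boundary convention with a warning.  A
    zero cell with nonzero margins is (optionally) repaired by adding 0.5
    to every cell before estimation, flagged via ``corrected``.
    """
    n11, n10, n01, n00 = table.cells
    # zero margin: correlation is at the boundary by convention
    row1, row0 = n11 + n10, n01 + n00
    col1, col0 = n11 + n01, n10 + n00
    if min(row1, row0, col1, col0) == 0:
        warnings.warn("zero margin: tetrachoric at boundary", stacklevel=2)
        sign = 1.0 if (n11 + n00) >= (n10 + n01) else -1.0
        return TetrachoricResult(rho=sign, se=np.nan, boundary=True)
    corrected = False
    if min(table.cells) == 0:
        if not continuity_correction:
            warnings.warn("zero cell: tetrachoric at boundary", stacklevel=2)
            sign = 1.0 if (n11 * n00) > (n10 * n01) else -1.0
            return TetrachoricResult(rho=sign, se=np.nan, boundary=True)
        table = TwoByTwoTable(n11 + 0.5, n10 + 0.5, n01 + 0.5, n00 + 0.5)
        corrected = True

    res = minimize_scalar(
        lambda r: -tetrachoric_loglik(table, r),
        bounds=(-_RHO_BOUND, _RHO_BOUND),
        method="bounded",
        options={"xatol": 1e-9},
    )
    rho = float(res.x)
    # observed information of the profile log-likelihood
    eps = 1e-4
    ll = tetrachoric_loglik
    d2 = (ll(table, rho + eps) - 2 * ll(table, rho) + ll(table, rho - eps)) / eps**2
    se = float(1.0 / np.sqrt(-d2)) if d2 < 0 else np.nan
    return TetrachoricResult(rho=rho, se=se, corrected=corrected)


def tetrachoric_z_test(result: TetrachoricResult) -> float:
    """Two-sided Wald z-test p-value for rho = 0 (offered for convenience;
    the study's p-value method is not reproduced)."""
    z = result.rho / result.se
    return float(2 * norm.sf(abs(z)))


# ------------------------------------------------------- state proportions


def state_proportions(records: pd.DataFrame, n_areas: int | None = None) -> pd.DataFrame:
    """Per-area proportion of children with each disease.

    Every area present must have at least one record; rows are indexed by
    area id.
    """
    if n_areas is not None:
        present = set(records["area"])
        missing = sorted(set(range(n_areas)) - present)
        if missing:
            raise ValueError(f"areas with no records: {missing}")
    props = records.groupby("area")[list(DISEASES)].mean()
    return props.sort_index()


def pairwise_state_correlation(props: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between per-area disease proportions.

    Returns one row per disease pair; a zero-variance proportion vector
    yields NaN with a ``degenerate`` flag rather than an arbitrary number.
    """
    if len(props) < 2:
        raise ValueError("need at least two areas for a correlation")
    rows = []
    pairs = [("ari", "diarrhoea"), ("ari", "stunting"), ("diarrhoea", "stunting")]
    for a, b in pairs:
        xa, xb = props[a].to_numpy(), props[b].to_numpy()
        degenerate = np.std(xa) == 0 or np.std(xb) == 0
        r = np.nan if degenerate else float(np.corrcoef(xa, xb)[0, 1])
        rows.append({"pair": f"{a}/{b}", "correlation": r, "degenerate": degenerate})
    return pd.DataFrame(rows)
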