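"""Synthetic DHS-like child morbidity data with shared-component structure.

The generator runs the shared-component logistic model forward: it samples
the seven ICAR latent fields (three pairwise-shared, one all-disease
shared, three disease-specific), draws each child's covariates, assembles
the three linear predictors exactly as the model specifies —

    logit pi_1 = a1 + x'b1 + w_ad*u12 + w_as*u13 + d1*u + s1       (ARI)
    logit pi_2 = a2 + x'b2 + (1/w_ad)*u12 + w_ds*u23 + d2*u + s2   (diarrhoea)
    logit pi_3 = a3 + x'b3 + (1/w_as)*u13 + (1/w_ds)*u23 + d3*u + s3  (stunting)

— and draws Bernoulli outcomes.  The pairwise gradient weights enter one
disease as w and the other as 1/w; the three all-disease weights are
constrained to multiply to one.  Defaults emulate the pooled 2008/2013/
2018 Nigeria DHS child sample: 37 areas, covariate margins matching the
published frequency table, and marginal prevalences near 4.7% (ARI),
10.8% (diarrhoea) and 14.5% (stunting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .areal import StateGraph, icar_precision, lattice_graph, sample_icar
from .design import FULL_DESIGN_COLUMNS, build_design
from .records import CATEGORIES, RECORD_COLUMNS, YEARS, validate_records
from .records import read_records, write_records  # re-export  # noqa: F401

FIELD_NAMES = ("u12", "u13", "u23", "u", "s1", "s2", "s3")


@dataclass(frozen=True)
class CovariateDistribution:
    """Marginal covariate distribution (independent of area by default).

    Category probabilities follow the pooled NDHS frequency margins;
    mother's age is normal, truncated to the DHS-eligible 15–49 range.
    """

    residence: tuple[float, ...] = (0.684, 0.316)  # rural, urban
    education: tuple[float, ...] = (0.465, 0.208, 0.327)
    wealth: tuple[float, ...] = (0.235, 0.433, 0.332)
    sex: tuple[float, ...] = (0.504, 0.496)  # male, female
    age_band: tuple[float, ...] = (0.287, 0.221, 0.492)
    year: tuple[float, ...] = (0.387, 0.447, 0.166)
    mother_age_mean: float = 29.0
    mother_age_sd: float = 7.0

    def __post_init__(self) -> None:
        for name in ("residence", "education", "wealth", "sex", "age_band", "year"):
            p = np.asarray(getattr(self, name), float)
            if len(p) != len(CATEGORIES.get(name, YEARS)):
                raise ValueError(f"{name} needs {len(CATEGORIES.get(name, YEARS))} probabilities")
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
                raise ValueError(f"{name} probabilities must be >=0 and sum to 1")


# Fixed-effect log-odds defaults, one vector per disease over
# FULL_DESIGN_COLUMNS, in the neighbourhood of the pooled-survey odds
# ratios (urban, education, wealth, sex, age band, mother's age, year).
DEFAULT_BETA = np.array(
    [
        [0.04, -0.11, -0.35, -0.32, -0.55, -0.23, -0.04, -0.64, -0.080, -0.20, -0.10],
        [0.10, -0.19, -0.42, -0.27, -0.45, -0.21, 0.25, -0.62, -0.054, -0.15, -0.20],
        [-0.06, -0.12, -0.44, -0.12, -0.40, -0.08, -0.08, -0.18, -0.042, -0.10, 0.00],
    ]
)

# Intercepts calibrated once (see calibrate_intercepts) so that the default
# configuration yields marginal prevalences near 4.7%, 10.8% and 14.5%.
DEFAULT_ALPHA = np.array([-2.648, -1.478, -1.541])

DEFAULT_PRECISIONS = {
    # shared fields carry most spatial variation (tau 4 -> sd ~ 0.5);
    # disease-specific residual fields are tighter (tau 10)
    "u12": 4.0,
    "u13": 4.0,
    "u23": 4.0,
    "u": 4.0,
    "s1": 10.0,
    "s2": 10.0,
    "s3": 10.0,
}


@dataclass
class SimulationConfig:
    """All knobs of the forward model.

    ``w_ad``, ``w_as``, ``w_ds`` are the pairwise gradient weights
    (ARI–diarrhoea, ARI–stunting, diarrhoea–stunting); ``w_all`` the three
    all-disease weights, renormalized (with a warning) to product one.
    ``precisions`` maps each latent field to its ICAR precision tau.
    """

    graph: StateGraph = field(default_factory=lambda: lattice_graph(6, 6, 1))
    children_per_area: int | np.ndarray = 1600
    alpha: np.ndarray = field(default_factory=lambda: DEFAULT_ALPHA.copy())
    beta: np.ndarray = field(default_factory=lambda: DEFAULT_BETA.copy())
    w_ad: float = 2.0
    w_as: float = 1.0
    w_ds: float = 0.5
    w_all: tuple[float, float, float] = (1.0, 1.0, 1.0)
    precisions: dict = field(default_factory=lambda: dict(DEFAULT_PRECISIONS))
    covariates: CovariateDistribution = field(default_factory=CovariateDistribution)
    seed: int = 0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, float)
        self.beta = np.asarray(self.beta, float)
        if self.alpha.shape != (3,):
            raise ValueError("alpha must have length 3")
        if self.beta.shape != (3, len(FULL_DESIGN_COLUMNS)):
            raise ValueError(
                f"beta must be 3 x {len(FULL_DESIGN_COLUMNS)} over {FULL_DESIGN_COLUMNS}"
            )
        for w in (self.w_ad, self.w_as, self.w_ds):
            if not w > 0:
                raise ValueError("pairwise gradient weights must be positive")
        w_all = np.asarray(self.w_all, float)
        if w_all.shape != (3,) or np.any(w_all <= 0):
            raise ValueError("w_all must be three positive weights")
        prod = float(np.prod(w_all))
        if abs(prod - 1.0) > 1e-12:
            warnings.warn(
                "all-disease weights renormalized to product one", stacklevel=2
            )
            w_all = w_all / prod ** (1.0 / 3.0)
        self.w_all = tuple(float(v) for v in w_all)
        missing = set(FIELD_NAMES) - set(self.precisions)
        if missing:
            raise ValueError(f"missing precisions for fields: {sorted(missing)}")
        for name in FIELD_NAMES:
            if not self.precisions[name] > 0:
                raise ValueError(f"precision for {name} must be positive")

    @property
    def n_children(self) -> np.ndarray:
        if np.isscalar(self.children_per_area):
            return np.full(self.graph.n_areas, int(self.children_per_area))
        arr = np.asarray(self.children_per_area, int)
        if arr.shape != (self.graph.n_areas,):
            raise ValueError("children_per_area vector must have one entry per area")
        return arr


@dataclass
class TruthRecord:
    """Latent fields and parameters that generated a dataset."""

    fields: dict[str, np.ndarray]
    alpha: np.ndarray
    beta: np.ndarray
    w_ad: float
    w_as: float
    w_ds: float
    w_all: tuple[float, float, float]
    precisions: dict
    seed: int

    def area_effects(self) -> np.ndarray:
        """True composite spatial effect per disease, shape (3, n_areas)."""
        f = self.fields
        d1, d2, d3 = self.w_all
        return np.stack(
            [
                self.w_ad * f["u12"] + self.w_as * f["u13"] + d1 * f["u"] + f["s1"],
                f["u12"] / self.w_ad + self.w_ds * f["u23"] + d2 * f["u"] + f["s2"],
                f["u13"] / self.w_as + f["u23"] / self.w_ds + d3 * f["u"] + f["s3"],
            ]
        )

    def to_yaml(self, path) -> None:
        payload = {
            "fields": {k: [float(v) for v in vec] for k, vec in self.fields.items()},
            "alpha": [float(v) for v in self.alpha],
            "beta": [[float(v) for v in row] for row in self.beta],
            "w_ad": float(self.w_ad),
            "w_as": float(self.w_as),
            "w_ds": float(self.w_ds),
            "w_all": [float(v) for v in self.w_all],
            "precisions": {k: float(v) for k, v in self.precisions.items()},
            "seed": int(self.seed),
        }
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "TruthRecord":
        with open(path, "rt", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        return cls(
            fields={k: np.asarray(v, float) for k, v in payload["fields"].items()},
            alpha=np.asarray(payload["alpha"], float),
            beta=np.asarray(payload["beta"], float),
            w_ad=payload["w_ad"],
            w_as=payload["w_as"],
            w_ds=payload["w_ds"],
            w_all=tuple(payload["w_all"]),
            precisions=payload["precisions"],
            seed=payload["seed"],
        )


def _draw_covariates(
    cov: CovariateDistribution, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    def cat(levels, probs):
        return rng.choice(levels, size=n, p=probs)

    age = rng.normal(cov.mother_age_mean, cov.mother_age_sd, size=n)
    age = np.clip(age, 15.0, 49.0)
    return pd.DataFrame(
        {
            "residence": cat(CATEGORIES["residence"], cov.residence),
            "education": cat(CATEGORIES["education"], cov.education),
            "wealth": cat(CATEGORIES["wealth"], cov.wealth),
            "sex": cat(CATEGORIES["sex"], cov.sex),
            "age_band": cat(CATEGORIES["age_band"], cov.age_band),
            "mother_age": np.round(age, 1),
            "year": rng.choice(YEARS, size=n, p=cov.year),
        }
    )


def sample_truth(config: SimulationConfig, rng: np.random.Generator) -> TruthRecord:
    """Draw the latent ICAR fields of one simulated world."""
    structure = icar_precision(config.graph)
    fields = {
        name: sample_icar(structure, config.precisions[name], rng)
        for name in FIELD_NAMES
    }
    return TruthRecord(
        fields=fields,
        alpha=config.alpha.copy(),
        beta=config.beta.copy(),
        w_ad=config.w_ad,
        w_as=config.w_as,
        w_ds=config.w_ds,
        w_all=config.w_all,
        precisions=dict(config.precisions),
        seed=config.seed,
    )


def simulate_dataset(
    config: SimulationConfig, truth: TruthRecord | None = None
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate one child-level dataset; returns (records, truth).

    Covariates are drawn independently of area from
    ``config.covariates``; mother's age is centred at its configured mean
    inside the linear predictor, matching the model's centring convention.
    """
    rng = np.random.default_rng(config.seed)
    if truth is None:
        truth = sample_truth(config, rng)
    counts = config.n_children
    n_total = int(counts.sum())
    area = np.repeat(np.arange(config.graph.n_areas), counts)
    df = _draw_covariates(config.covariates, n_total, rng)
    df.insert(0, "area", area)

    x, _ = build_design(
        df, age_center=config.covariates.mother_age_mean, year_dummies="full"
    )
    area_eff = truth.area_effects()  # (3, n_areas)
    for d, disease in enumerate(("ari", "diarrhoea", "stunting")):
        eta = config.alpha[d] + x @ config.beta[d] + area_eff[d, area]
        p = 1.0 / (1.0 + np.exp(-eta))
        df.insert(1 + d, disease, (rng.random(n_total) < p).astype(np.int64))
    df = df[list(RECORD_COLUMNS)]
    return validate_records(df, n_areas=config.graph.n_areas), truth


def calibrate_intercepts(
    config: SimulationConfig,
    target_prevalence=(0.047, 0.108, 0.145),
    n_mc: int = 200_000,
    n_worlds: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Solve for intercepts giving target marginal prevalences.

    Monte-Carlo averages the inverse-logit over covariates and over
    ``n_worlds`` independent draws of the latent fields (a single field
    realization on a few dozen areas shifts the marginal by percentage
    points), then root-finds each intercept — the mean response is
    monotone in the intercept.  Used once to fix the package defaults.
    """
    from scipy.optimize import brentq

    rng = np.random.default_rng(seed)
    df = _draw_covariates(config.covariates, n_mc, rng)
    x, _ = build_design(
        df, age_center=config.covariates.mother_age_mean, year_dummies="full"
    )
    area = rng.integers(0, config.graph.n_areas, size=n_mc)
    world = rng.integers(0, n_worlds, size=n_mc)
    effects = np.stack(
        [sample_truth(config, rng).area_effects() for _ in range(n_worlds)]
    )  # (n_worlds, 3, n_areas)
    out = np.empty(3)
    for d in range(3):
        base = x @ config.beta[d] + effects[world, d, area]

        def mean_prev(a, base=base, d=d):
            return float(np.mean(1.0 / (1.0 + np.exp(-(a + base))))) - target_prevalence[d]

        out[d] = brentq(mean_prev, -10, 5, xtol=1e-6)
    return out
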