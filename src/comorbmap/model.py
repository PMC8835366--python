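"""Three-disease shared-component logistic model with ICAR priors.

Each child's disease status is Bernoulli with logit-linear predictor

    logit pi_ij1 = a1 + x'b1 + w_ad*u12_i + w_as*u13_i + d1*u_i + s1_i
    logit pi_ij2 = a2 + x'b2 + (1/w_ad)*u12_i + w_ds*u23_i + d2*u_i + s2_i
    logit pi_ij3 = a3 + x'b3 + (1/w_as)*u13_i + (1/w_ds)*u23_i + d3*u_i + s3_i

for diseases 1=ARI, 2=diarrhoea, 3=stunting in area i.  The seven latent
area fields (three pairwise-shared u12/u13/u23, one all-disease shared u,
three disease-specific s_d) carry ICAR priors with field-specific
precisions; the positive gradient weights let each disease load
differently on the components it shares.  Identifiability: every field is
sum-to-zero within each connected component, pairwise weights enter as
(w, 1/w), and the three all-disease weights multiply to one (two free
log-weights).

Posterior sampling is Metropolis-within-Gibbs: conjugate Gamma updates
for the ICAR precisions, adaptive random-walk Metropolis for everything
else (single-site for latent fields, per-coordinate for intercepts and
fixed effects, scalar for log-weights), with per-component re-centering
of every field each sweep, the subtracted mean absorbed into the
intercepts through the disease-specific weight combination.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import gamma as gamma_dist

from .areal import IcarStructure, StateGraph, icar_precision
from .design import DesignInfo, build_design
from .records import DISEASES, ChildRecord, records_to_frame, validate_records

FIELD_NAMES = ("u12", "u13", "u23", "u", "s1", "s2", "s3")
WEIGHT_NAMES = ("log_w_ad", "log_w_as", "log_w_ds", "log_d1", "log_d2")

_SOFTPLUS = lambda x: np.logaddexp(0.0, x)  # noqa: E731


@dataclass(frozen=True)
class ModelSpec:
    """Which latent components the model includes.

    ``pairwise=False, overall=False`` gives the no-sharing benchmark
    (independent ICAR field per disease); all False is a plain logistic
    regression.
    """

    pairwise: bool = True
    overall: bool = True
    specific: bool = True
    # disease-specific fields are ICAR by default; "exchangeable" swaps in
    # iid normal priors for s_1..s_3 (same precision parameterization)
    specific_prior: str = "icar"

    def active_fields(self) -> tuple[str, ...]:
        out = []
        if self.pairwise:
            out += ["u12", "u13", "u23"]
        if self.overall:
            out += ["u"]
        if self.specific:
            out += ["s1", "s2", "s3"]
        return tuple(out)

    def active_weights(self) -> tuple[str, ...]:
        out = []
        if self.pairwise:
            out += ["log_w_ad", "log_w_as", "log_w_ds"]
        if self.overall:
            out += ["log_d1", "log_d2"]
        return tuple(out)


@dataclass(frozen=True)
class PriorSpec:
    """Hyperpriors: Gamma(shape, rate) on each ICAR precision, normal
    priors on log gradient weights, intercepts and fixed effects.

    The precision hyperprior Gamma(1, 0.1) (mean 10, sd 10) spreads its
    mass over the precisions implied by plausible logit-scale field
    standard deviations (~0.05-1.5).  Extremely diffuse precision priors
    (e.g. mean-1000 variants) concentrate on degenerate zero-variance
    fields, which in an over-parameterized shared-component decomposition
    collapses weakly-identified components and traps the sampler in
    metastable allocations; avoid them unless the fields are strongly
    identified.
    """

    tau_shape: float = 1.0
    tau_rate: float = 0.1
    log_weight_sd: float = 0.5
    alpha_sd: float = 10.0
    beta_sd: float = 10.0

    def __post_init__(self) -> None:
        for v in (self.tau_shape, self.tau_rate, self.log_weight_sd,
                  self.alpha_sd, self.beta_sd):
            if not v > 0:
                raise ValueError("prior hyperparameters must be positive")

    @property
    def tau_prior_mean(self) -> float:
        return self.tau_shape / self.tau_rate


@dataclass
class SharedComponentParams:
    """One point in parameter space (one MCMC state/draw)."""

    alpha: np.ndarray                 # (3,)
    beta: np.ndarray                  # (3, p)
    fields: dict[str, np.ndarray]     # name -> (n_areas,)
    log_w_ad: float = 0.0
    log_w_as: float = 0.0
    log_w_ds: float = 0.0
    log_d1: float = 0.0
    log_d2: float = 0.0
    tau: dict[str, float] = dc_field(default_factory=dict)

    @property
    def log_d3(self) -> float:
        return -(self.log_d1 + self.log_d2)

    @property
    def w_ad(self) -> float:
        return float(np.exp(self.log_w_ad))

    @property
    def w_as(self) -> float:
        return float(np.exp(self.log_w_as))

    @property
    def w_ds(self) -> float:
        return float(np.exp(self.log_w_ds))

    @property
    def w_all(self) -> tuple[float, float, float]:
        return (
            float(np.exp(self.log_d1)),
            float(np.exp(self.log_d2)),
            float(np.exp(self.log_d3)),
        )

    def loadings(self) -> dict[str, list[tuple[int, float]]]:
        """Per-field (disease index, weight) pairs of the linear predictor."""
        d1, d2, d3 = self.w_all
        return {
            "u12": [(0, self.w_ad), (1, 1.0 / self.w_ad)],
            "u13": [(0, self.w_as), (2, 1.0 / self.w_as)],
            "u23": [(1, self.w_ds), (2, 1.0 / self.w_ds)],
            "u": [(0, d1), (1, d2), (2, d3)],
            "s1": [(0, 1.0)],
            "s2": [(1, 1.0)],
            "s3": [(2, 1.0)],
        }

    def area_effects(self, model: ModelSpec | None = None) -> np.ndarray:
        """Composite spatial effect per disease, shape (3, n_areas)."""
        model = model or ModelSpec()
        n_areas = len(next(iter(self.fields.values())))
        eff = np.zeros((3, n_areas))
        loads = self.loadings()
        for name in model.active_fields():
            for d, w in loads[name]:
                eff[d] += w * self.fields[name]
        return eff

    @classmethod
    def zeros(cls, n_areas: int, n_covariates: int) -> "SharedComponentParams":
        return cls(
            alpha=np.zeros(3),
            beta=np.zeros((3, n_covariates)),
            fields={f: np.zeros(n_areas) for f in FIELD_NAMES},
            tau={f: 1.0 for f in FIELD_NAMES},
        )


@dataclass(frozen=True)
class McmcSettings:
    n_iter: int = 3000
    burn_in: int = 1000
    thin: int = 2
    seed: int = 0
    target_accept_site: float = 0.44
    target_accept_block: float = 0.23

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


# --------------------------------------------------------------- predictors


def _design_row(record, info: DesignInfo) -> np.ndarray:
    if isinstance(record, ChildRecord):
        rec = record
    else:  # pandas Series / mapping
        rec = ChildRecord(**{k: record[k] for k in (
            "area", "ari", "diarrhoea", "stunting", "residence", "education",
            "wealth", "sex", "age_band", "mother_age", "year")})
    values = {
        "urban": float(rec.residence == "urban"),
        "edu_primary": float(rec.education == "primary"),
        "edu_secondary_plus": float(rec.education == "secondary_plus"),
        "wealth_poorer_middle": float(rec.wealth == "poorer_middle"),
        "wealth_richer_richest": float(rec.wealth == "richer_richest"),
        "female": float(rec.sex == "female"),
        "age_12_23": float(rec.age_band == "m12_23"),
        "age_24_59": float(rec.age_band == "m24_59"),
        "mother_age_c": rec.mother_age - info.age_center,
        "year_2013": float(rec.year == 2013),
        "year_2018": float(rec.year == 2018),
    }
    return np.array([values[c] for c in info.columns])


def linear_predictor(
    params: SharedComponentParams,
    record,
    disease: int | str,
    info: DesignInfo,
    model: ModelSpec | None = None,
) -> float:
    """Logit-scale predictor for one child and one disease (0=ARI,
    1=diarrhoea, 2=stunting)."""
    d = DISEASES.index(disease) if isinstance(disease, str) else int(disease)
    x = _design_row(record, info)
    area = int(record.area if isinstance(record, ChildRecord) else record["area"])
    eff = params.area_effects(model)
    return float(params.alpha[d] + x @ params.beta[d] + eff[d, area])


def linear_predictors(
    params: SharedComponentParams,
    x: np.ndarray,
    area: np.ndarray,
    model: ModelSpec | None = None,
) -> np.ndarray:
    """Vectorized predictors for all records, shape (n, 3)."""
    eff = params.area_effects(model)
    return params.alpha[None, :] + x @ params.beta.T + eff[:, area].T


def bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    """Sum of Bernoulli log-likelihoods at logits eta."""
    return float(np.sum(y * eta) - np.sum(_SOFTPLUS(eta)))


def log_posterior(
    params: SharedComponentParams,
    records: pd.DataFrame,
    prior: PriorSpec,
    structure: IcarStructure,
    model: ModelSpec | None = None,
    age_center: float | None = None,
    year_dummies: str = "auto",
) -> float:
    """Unnormalized log posterior density (up to an additive constant).

    Sum of the Bernoulli log-likelihood, the improper ICAR log-densities
    (tau/2 quadratic form with (n-k)/2 log tau), the Gamma hyperpriors on
    the precisions, and the normal priors on log-weights, intercepts and
    fixed effects.
    """
    model = model or ModelSpec()
    df = records_to_frame(records)
    x, info = build_design(df, age_center=age_center, year_dummies=year_dummies)
    if x.shape[1] != params.beta.shape[1]:
        raise ValueError(
            f"design has {x.shape[1]} columns but beta has {params.beta.shape[1]}"
        )
    y = df[list(DISEASES)].to_numpy(float) if len(df) else np.empty((0, 3))
    area = df["area"].to_numpy(int) if len(df) else np.empty(0, int)
    eta = linear_predictors(params, x, area, model)
    lp = bernoulli_loglik(eta, y)

    q = structure.precision_pattern
    rank = structure.n_areas - structure.rank_deficiency
    for name in model.active_fields():
        vec = params.fields[name]
        tau = params.tau[name]
        if name.startswith("s") and model.specific_prior == "exchangeable":
            lp += 0.5 * len(vec) * np.log(tau) - 0.5 * tau * float(vec @ vec)
        else:
            lp += 0.5 * rank * np.log(tau) - 0.5 * tau * float(vec @ (q @ vec))
        lp += gamma_dist.logpdf(tau, prior.tau_shape, scale=1.0 / prior.tau_rate)
    for name in model.active_weights():
        lw = getattr(params, name)
        lp += -0.5 * (lw / prior.log_weight_sd) ** 2
    lp += float(np.sum(-0.5 * (params.alpha / prior.alpha_sd) ** 2))
    lp += float(np.sum(-0.5 * (params.beta / prior.beta_sd) ** 2))
    return float(lp)


def conjugate_tau_update(
    field_values: np.ndarray,
    structure: IcarStructure,
    prior: PriorSpec,
    rng: np.random.Generator,
) -> float:
    """Gibbs draw of an ICAR precision: Gamma(shape + (n-k)/2,
    rate + x'Qx/2).  The field must already be centred per component."""
    q = structure.precision_pattern
    rank = structure.n_areas - structure.rank_deficiency
    quad = float(field_values @ (q @ field_values))
    return float(
        rng.gamma(prior.tau_shape + 0.5 * rank, 1.0 / (prior.tau_rate + 0.5 * quad))
    )


def recenter(
    params: SharedComponentParams,
    structure: IcarStructure,
    model: ModelSpec | None = None,
) -> SharedComponentParams:
    """Return a copy with every active field centred per component and the
    subtracted means absorbed into the intercepts.

    For a connected graph the returned parameters give identical linear
    predictors.  For a disconnected graph the distinct per-component
    shifts cannot all be absorbed into a single intercept; the unique
    non-singleton component's mean is absorbed and singleton (island)
    components are pinned at zero.
    """
    model = model or ModelSpec()
    out = copy.deepcopy(params)
    labels = np.asarray(structure.component_labels)
    loads = out.loadings()
    for name in model.active_fields():
        vec = out.fields[name]
        absorbable = []
        for cid in range(labels.max() + 1):
            mask = labels == cid
            m = float(vec[mask].mean())
            vec[mask] -= m
            if mask.sum() > 1:
                absorbable.append(m)
        if len(absorbable) == 1:
            for d, w in loads[name]:
                out.alpha[d] += w * absorbable[0]
    return out


# ------------------------------------------------------------------ chains


@dataclass
class PosteriorChain:
    """Stored MCMC draws plus everything needed to reproduce summaries."""

    alpha: np.ndarray        # (m, 3)
    beta: np.ndarray         # (m, 3, p)
    fields: np.ndarray       # (m, F, n_areas)
    log_weights: np.ndarray  # (m, 5) in WEIGHT_NAMES order
    tau: np.ndarray          # (m, F)
    deviance: np.ndarray     # (m,)
    field_names: tuple[str, ...]
    design_info: DesignInfo
    model: ModelSpec
    settings: McmcSettings
    acceptance_rates: dict
    component_labels: tuple[int, ...]

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_areas(self) -> int:
        return self.fields.shape[2]

    def params_at(self, idx: int) -> SharedComponentParams:
        fields = {f: self.fields[idx, k] for k, f in enumerate(self.field_names)}
        for f in FIELD_NAMES:
            fields.setdefault(f, np.zeros(self.n_areas))
        lw = dict(zip(WEIGHT_NAMES, self.log_weights[idx]))
        return SharedComponentParams(
            alpha=self.alpha[idx].copy(),
            beta=self.beta[idx].copy(),
            fields=fields,
            tau={f: self.tau[idx, k] for k, f in enumerate(self.field_names)},
            **lw,
        )

    def posterior_mean_params(self) -> SharedComponentParams:
        """Posterior means of intercepts, fixed effects, fields, and
        log-weights (means taken on the log scale)."""
        fields = {
            f: self.fields[:, k].mean(axis=0) for k, f in enumerate(self.field_names)
        }
        for f in FIELD_NAMES:
            fields.setdefault(f, np.zeros(self.n_areas))
        lw = dict(zip(WEIGHT_NAMES, self.log_weights.mean(axis=0)))
        return SharedComponentParams(
            alpha=self.alpha.mean(axis=0),
            beta=self.beta.mean(axis=0),
            fields=fields,
            tau={f: float(self.tau[:, k].mean()) for k, f in enumerate(self.field_names)},
            **lw,
        )

    def scalar_draws(self) -> pd.DataFrame:
        """All stored draws flattened to one column per scalar."""
        cols: dict[str, np.ndarray] = {}
        for d in range(3):
            cols[f"alpha_{DISEASES[d]}"] = self.alpha[:, d]
            for c, name in enumerate(self.design_info.columns):
                cols[f"beta_{DISEASES[d]}_{name}"] = self.beta[:, d, c]
        for k, f in enumerate(self.field_names):
            for i in range(self.n_areas):
                cols[f"{f}_{i}"] = self.fields[:, k, i]
            cols[f"tau_{f}"] = self.tau[:, k]
        for k, name in enumerate(WEIGHT_NAMES):
            cols[name] = self.log_weights[:, k]
        cols["deviance"] = self.deviance
        return pd.DataFrame(cols)

    # -- persistence: columnar text + YAML manifest

    def save(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.scalar_draws().to_csv(directory / "draws.csv", index=False)
        manifest = {
            "field_names": list(self.field_names),
            "design_columns": list(self.design_info.columns),
            "age_center": float(self.design_info.age_center),
            "model": {
                "pairwise": self.model.pairwise,
                "overall": self.model.overall,
                "specific": self.model.specific,
                "specific_prior": self.model.specific_prior,
            },
            "settings": {
                "n_iter": self.settings.n_iter,
                "burn_in": self.settings.burn_in,
                "thin": self.settings.thin,
                "seed": self.settings.seed,
            },
            "acceptance_rates": {
                k: float(v) for k, v in self.acceptance_rates.items()
            },
            "component_labels": list(self.component_labels),
            "n_areas": self.n_areas,
        }
        with open(directory / "manifest.yaml", "wt", encoding="utf-8") as fh:
            yaml.safe_dump(manifest, fh)

    @classmethod
    def load(cls, directory) -> "PosteriorChain":
        from pathlib import Path

        directory = Path(directory)
        with open(directory / "manifest.yaml", "rt", encoding="utf-8") as fh:
            manifest = yaml.safe_load(fh)
        df = pd.read_csv(directory / "draws.csv")
        field_names = tuple(manifest["field_names"])
        n_areas = int(manifest["n_areas"])
        design = DesignInfo(
            columns=tuple(manifest["design_columns"]),
            age_center=manifest["age_center"],
        )
        m = len(df)
        p = len(design.columns)
        alpha = np.column_stack([df[f"alpha_{d}"] for d in DISEASES])
        beta = np.zeros((m, 3, p))
        for d in range(3):
            for c, name in enumerate(design.columns):
                beta[:, d, c] = df[f"beta_{DISEASES[d]}_{name}"]
        fields = np.zeros((m, len(field_names), n_areas))
        tau = np.zeros((m, len(field_names)))
        for k, f in enumerate(field_names):
            for i in range(n_areas):
                fields[:, k, i] = df[f"{f}_{i}"]
            tau[:, k] = df[f"tau_{f}"]
        log_weights = np.column_stack([df[n] for n in WEIGHT_NAMES])
        return cls(
            alpha=alpha,
            beta=beta,
            fields=fields,
            log_weights=log_weights,
            tau=tau,
            deviance=df["deviance"].to_numpy(),
            field_names=field_names,
            design_info=design,
            model=ModelSpec(**manifest["model"]),
            settings=McmcSettings(**manifest["settings"]),
            acceptance_rates=manifest["acceptance_rates"],
            component_labels=tuple(manifest["component_labels"]),
        )


# ----------------------------------------------------------------- sampler


class _Sampler:
    """Metropolis-within-Gibbs engine over collapsed per-area row blocks."""

    def __init__(self, x, y, area, graph, structure, prior, model, settings, info):
        self.x = x
        self.y = y
        self.area = area
        self.n, self.p = x.shape
        self.graph = graph
        self.structure = structure
        self.prior = prior
        self.model = model
        self.settings = settings
        self.info = info
        self.rng = np.random.default_rng(settings.seed)

        na = graph.n_areas
        self.n_areas = na
        self.deg = graph.degrees.astype(float)
        self.nbr = [np.array(nb, dtype=int) for nb in graph.neighbors]
        counts = np.bincount(area, minlength=na) if self.n else np.zeros(na, int)
        self.starts = np.concatenate([[0], np.cumsum(counts)])
        self.sites = [i for i in range(na) if self.deg[i] > 0]
        self.labels = np.asarray(structure.component_labels)
        nonsingleton = [
            c for c in range(self.labels.max() + 1) if (self.labels == c).sum() > 1
        ]
        self.absorb_component = nonsingleton[0] if len(nonsingleton) == 1 else None
        self.rank = na - structure.rank_deficiency

        self.sum_y = np.stack(
            [np.bincount(area, weights=y[:, d], minlength=na) for d in range(3)]
        ) if self.n else np.zeros((3, na))
        self.y_tot = y.sum(axis=0) if self.n else np.zeros(3)
        self.yx = x.T @ y if self.n else np.zeros((self.p, 3))

        # eigen-structure of Q, reused by the redistribution Gibbs step
        eigval, eigvec = np.linalg.eigh(structure.precision_pattern)
        tol = max(eigval.max(), 1.0) * na * np.finfo(float).eps
        pos = eigval > tol
        self.lam_pos = eigval[pos]
        self.v_pos = eigvec[:, pos]

        # initialization: intercepts at marginal logits; latent fields at
        # the minimum-norm allocation of the shrunk empirical area
        # residuals across all active components, precisions at the
        # conjugate mean of that allocation (a zero-field start is an
        # absorbing trap: the first precision update jumps to the
        # hyperprior ceiling and the field can never re-enter)
        prev = np.clip(self.y_tot / max(self.n, 1), 1e-4, 1 - 1e-4) \
            if self.n else np.full(3, 0.5)
        self.params = SharedComponentParams.zeros(na, self.p)
        self.params.alpha = np.log(prev / (1 - prev))
        act = model.active_fields()
        if self.n and act:
            n_per_area = np.maximum(self.starts[1:] - self.starts[:-1], 0)
            resid = np.zeros((3, na))
            for d in range(3):
                p_hat = (self.sum_y[d] + 0.5) / (n_per_area + 1.0)
                r = np.log(p_hat / (1 - p_hat)) - self.params.alpha[d]
                r[n_per_area == 0] = 0.0
                resid[d] = r - r.mean()
            load = self._loading_matrix_for(self.params, act)
            alloc = load.T @ np.linalg.solve(load @ load.T, resid)  # (F, na)
            q_mat = structure.precision_pattern
            for k, f in enumerate(act):
                self.params.fields[f] = alloc[k] - alloc[k].mean()
                quad = float(alloc[k] @ (q_mat @ alloc[k]))
                self.params.tau[f] = float(np.clip(self.rank / max(quad, 1e-8),
                                                   0.5, 50.0))
        for d in range(3):
            if self.n and self.y_tot[d] == 0:
                warnings.warn(
                    f"disease {DISEASES[d]!r} has zero cases; intercept will drift low",
                    stacklevel=3,
                )

        # adaptive step sizes (log scale), Robbins–Monro during burn-in
        info_proxy = 0.05 * (x**2).sum(axis=0) + 1.0
        self.step_beta = 2.4 / np.sqrt(info_proxy)[None, :].repeat(3, axis=0)
        self.step_alpha = np.full(3, 2.4 / np.sqrt(0.05 * self.n + 1.0))
        self.step_field = {f: 0.3 for f in FIELD_NAMES}
        self.step_weight = {w: 0.1 for w in WEIGHT_NAMES}

        self.acc = {
            "fields": [0, 0],
            "alpha": [0, 0],
            "beta": [0, 0],
            "weights": [0, 0],
        }
        self.refresh()
        if not np.isfinite(self._loglik()):
            raise RuntimeError("non-finite posterior at initialization")

    # -- caches

    def rows(self, i):
        return slice(self.starts[i], self.starts[i + 1])

    def refresh(self):
        self.xbeta = self.x @ self.params.beta.T if self.n else np.zeros((0, 3))
        eff = self.params.area_effects(self.model)
        self.eta = self.params.alpha[None, :] + self.xbeta + eff[:, self.area].T
        sp = _SOFTPLUS(self.eta)
        self.sp_area = np.stack(
            [np.bincount(self.area, weights=sp[:, d], minlength=self.n_areas)
             for d in range(3)]
        ) if self.n else np.zeros((3, self.n_areas))

    def _loglik(self):
        return float(np.sum(self.y * self.eta) - self.sp_area.sum())

    # -- update blocks

    def update_fields(self, adapt):
        loads = self.params.loadings()
        for name in self.model.active_fields():
            vec = self.params.fields[name]
            tau = self.params.tau[name]
            load = loads[name]
            step = self.step_field[name]
            exchangeable = (
                name.startswith("s") and self.model.specific_prior == "exchangeable"
            )
            n_acc = 0
            site_list = self.sites if not exchangeable else range(self.n_areas)
            for i in site_list:
                z = step * self.rng.standard_normal()
                xi = vec[i]
                xp = xi + z
                if exchangeable:
                    dlp = -0.5 * tau * (xp * xp - xi * xi)
                else:
                    s_nbr = vec[self.nbr[i]].sum()
                    dquad = self.deg[i] * (xp * xp - xi * xi) - 2.0 * z * s_nbr
                    dlp = -0.5 * tau * dquad
                sl = self.rows(i)
                news = []
                for d, w in load:
                    de = w * z
                    new_eta = self.eta[sl, d] + de
                    new_sp = float(_SOFTPLUS(new_eta).sum())
                    dlp += de * self.sum_y[d, i] - (new_sp - self.sp_area[d, i])
                    news.append((d, new_eta, new_sp))
                if np.log(self.rng.random()) < dlp:
                    vec[i] = xp
                    for d, new_eta, new_sp in news:
                        self.eta[sl, d] = new_eta
                        self.sp_area[d, i] = new_sp
                    n_acc += 1
            n_sites = len(self.sites) if not exchangeable else self.n_areas
            self.acc["fields"][0] += n_acc
            self.acc["fields"][1] += n_sites
            if adapt and n_sites:
                rate = n_acc / n_sites
                self.step_field[name] = float(np.clip(
                    step * np.exp(adapt * (rate - self.settings.target_accept_site)),
                    1e-4, 10.0,
                ))

    def update_alpha(self, adapt):
        for d in range(3):
            z = self.step_alpha[d] * self.rng.standard_normal()
            a = self.params.alpha[d]
            dprior = -0.5 * ((a + z) ** 2 - a**2) / self.prior.alpha_sd**2
            dll = dprior + z * self.y_tot[d]
            new_eta = self.eta[:, d] + z
            new_sp = _SOFTPLUS(new_eta)
            dll -= float(new_sp.sum()) - float(self.sp_area[d].sum())
            accepted = np.log(self.rng.random()) < dll
            if accepted:
                self.params.alpha[d] = a + z
                self.eta[:, d] = new_eta
                self.sp_area[d] = np.bincount(
                    self.area, weights=new_sp, minlength=self.n_areas
                ) if self.n else self.sp_area[d]
            self.acc["alpha"][0] += accepted
            self.acc["alpha"][1] += 1
            if adapt:
                self.step_alpha[d] = float(np.clip(
                    self.step_alpha[d]
                    * np.exp(adapt * (accepted - self.settings.target_accept_site)),
                    1e-5, 10.0,
                ))

    def update_beta(self, adapt):
        for d in range(3):
            for c in range(self.p):
                z = self.step_beta[d, c] * self.rng.standard_normal()
                b = self.params.beta[d, c]
                dprior = -0.5 * ((b + z) ** 2 - b**2) / self.prior.beta_sd**2
                delta_vec = z * self.x[:, c]
                # y-term uses the precomputed cross-product for speed
                new_eta = self.eta[:, d] + delta_vec
                new_sp = _SOFTPLUS(new_eta)
                dll = dprior + z * self.yx[c, d] - (
                    float(new_sp.sum()) - float(self.sp_area[d].sum())
                )
                accepted = np.log(self.rng.random()) < dll
                if accepted:
                    self.params.beta[d, c] = b + z
                    self.eta[:, d] = new_eta
                    self.xbeta[:, d] += delta_vec
                    self.sp_area[d] = np.bincount(
                        self.area, weights=new_sp, minlength=self.n_areas
                    )
                self.acc["beta"][0] += accepted
                self.acc["beta"][1] += 1
                if adapt:
                    self.step_beta[d, c] = float(np.clip(
                        self.step_beta[d, c]
                        * np.exp(adapt * (accepted - self.settings.target_accept_site)),
                        1e-6, 10.0,
                    ))

    @staticmethod
    def _loading_matrix_for(params, active) -> np.ndarray:
        loads = params.loadings()
        mat = np.zeros((3, len(active)))
        for k, f in enumerate(active):
            for d, w in loads[f]:
                mat[d, k] = w
        return mat

    def _loading_matrix(self) -> np.ndarray:
        return self._loading_matrix_for(self.params, self.model.active_fields())

    def update_redistribute(self):
        """Exact Gibbs resampling of the field decomposition given totals.

        The composite per-disease area effects A = L F (L the 3 x F loading
        matrix) identify the fields only up to the null space of L; the
        likelihood is constant along those directions and mixing there by
        random walk is hopeless.  Conditional on A, the weights and the
        precisions, the null-space coordinates are exactly Gaussian with
        Kronecker precision (N'TN) x Q (N a null-space basis, T =
        diag(tau)), so they are redrawn in closed form per eigen-direction
        of Q.  Leaves every linear predictor unchanged.
        """
        from scipy.linalg import null_space

        if self.model.specific and self.model.specific_prior == "exchangeable":
            return  # mixed quadratic forms break the Kronecker structure
        act = self.model.active_fields()
        basis = null_space(self._loading_matrix())
        r = basis.shape[1]
        if r == 0 or self.lam_pos.size == 0:
            return
        tau_vec = np.array([self.params.tau[f] for f in act])
        m_mat = basis.T @ (tau_vec[:, None] * basis)
        k_mat = np.linalg.inv(m_mat)
        f_stack = np.stack([self.params.fields[f] for f in act])   # (F, n)
        coefs = f_stack @ self.v_pos                               # (F, J)
        mu = -k_mat @ (basis.T @ (tau_vec[:, None] * coefs))       # (r, J)
        chol = np.linalg.cholesky(k_mat)
        eps = self.rng.standard_normal(mu.shape)
        z = mu + (chol @ eps) / np.sqrt(self.lam_pos)[None, :]
        f_new = (coefs + basis @ z) @ self.v_pos.T
        for k, f in enumerate(act):
            self.params.fields[f] = f_new[k]

    _WEIGHT_EFFECTS = {
        # weight name -> list of (disease, field, sign of exponent)
        "log_w_ad": [(0, "u12", +1), (1, "u12", -1)],
        "log_w_as": [(0, "u13", +1), (2, "u13", -1)],
        "log_w_ds": [(1, "u23", +1), (2, "u23", -1)],
    }

    def update_weights(self, adapt):
        for name in self.model.active_weights():
            z = self.step_weight[name] * self.rng.standard_normal()
            lw = getattr(self.params, name)
            dprior = -0.5 * ((lw + z) ** 2 - lw**2) / self.prior.log_weight_sd**2
            # per-disease eta shifts induced by the weight change
            shifts: list[tuple[int, np.ndarray]] = []
            if name in self._WEIGHT_EFFECTS:
                for d, fname, sgn in self._WEIGHT_EFFECTS[name]:
                    dw = np.exp(sgn * (lw + z)) - np.exp(sgn * lw)
                    shifts.append((d, dw * self.params.fields[fname]))
            else:
                g1, g2 = self.params.log_d1, self.params.log_d2
                if name == "log_d1":
                    new_g1, new_g2 = g1 + z, g2
                else:
                    new_g1, new_g2 = g1, g2 + z
                u = self.params.fields["u"]
                for d, old_e, new_e in (
                    (0, g1, new_g1),
                    (1, g2, new_g2),
                    (2, -(g1 + g2), -(new_g1 + new_g2)),
                ):
                    if old_e != new_e:
                        shifts.append((d, (np.exp(new_e) - np.exp(old_e)) * u))
            dll = dprior
            proposals = []
            for d, per_area in shifts:
                delta_vec = per_area[self.area]
                new_eta = self.eta[:, d] + delta_vec
                new_sp = _SOFTPLUS(new_eta)
                dll += float(per_area @ self.sum_y[d]) - (
                    float(new_sp.sum()) - float(self.sp_area[d].sum())
                )
                proposals.append((d, new_eta, new_sp))
            accepted = np.log(self.rng.random()) < dll
            if accepted:
                setattr(self.params, name, lw + z)
                for d, new_eta, new_sp in proposals:
                    self.eta[:, d] = new_eta
                    self.sp_area[d] = np.bincount(
                        self.area, weights=new_sp, minlength=self.n_areas
                    ) if self.n else self.sp_area[d]
            self.acc["weights"][0] += accepted
            self.acc["weights"][1] += 1
            if adapt:
                self.step_weight[name] = float(np.clip(
                    self.step_weight[name]
                    * np.exp(adapt * (accepted - self.settings.target_accept_site)),
                    1e-4, 5.0,
                ))

    def update_tau(self):
        for name in self.model.active_fields():
            vec = self.params.fields[name]
            if name.startswith("s") and self.model.specific_prior == "exchangeable":
                quad = float(vec @ vec)
                shape = self.prior.tau_shape + 0.5 * self.n_areas
            else:
                quad = float(vec @ (self.structure.precision_pattern @ vec))
                shape = self.prior.tau_shape + 0.5 * self.rank
            self.params.tau[name] = float(
                self.rng.gamma(shape, 1.0 / (self.prior.tau_rate + 0.5 * quad))
            )

    def recenter_and_refresh(self):
        loads = self.params.loadings()
        for name in self.model.active_fields():
            if name.startswith("s") and self.model.specific_prior == "exchangeable":
                continue  # proper prior, no constraint needed
            vec = self.params.fields[name]
            for cid in range(self.labels.max() + 1):
                mask = self.labels == cid
                m = float(vec[mask].mean())
                vec[mask] -= m
                if cid == self.absorb_component:
                    for d, w in loads[name]:
                        self.params.alpha[d] += w * m
        self.refresh()

    def sweep(self, adapt):
        self.update_fields(adapt)
        self.update_redistribute()
        self.update_weights(adapt)
        self.update_alpha(adapt)
        self.update_beta(adapt)
        self.update_tau()
        self.recenter_and_refresh()


def fit(
    records,
    graph: StateGraph,
    prior: PriorSpec | None = None,
    settings: McmcSettings | None = None,
    model: ModelSpec | None = None,
    year_dummies: str = "auto",
    age_center: float | None = None,
) -> PosteriorChain:
    """Posterior sampling for the shared-component model.

    Records may be a DataFrame or a list of ChildRecord; every area index
    must exist in ``graph``.  Reproducible given ``settings.seed``.
    """
    prior = prior or PriorSpec()
    settings = settings or McmcSettings()
    model = model or ModelSpec()
    df = records_to_frame(records)
    if len(df):
        validate_records(df, n_areas=graph.n_areas)
        df = df.sort_values("area", kind="stable").reset_index(drop=True)
    x, info = build_design(df, age_center=age_center, year_dummies=year_dummies)
    y = df[list(DISEASES)].to_numpy(float) if len(df) else np.empty((0, 3))
    area = df["area"].to_numpy(int) if len(df) else np.empty(0, int)
    structure = icar_precision(graph)

    sampler = _Sampler(x, y, area, graph, structure, prior, model, settings, info)

    n_store = (settings.n_iter - settings.burn_in) // settings.thin
    f_names = model.active_fields()
    store = {
        "alpha": np.zeros((n_store, 3)),
        "beta": np.zeros((n_store, 3, x.shape[1])),
        "fields": np.zeros((n_store, len(f_names), graph.n_areas)),
        "log_weights": np.zeros((n_store, len(WEIGHT_NAMES))),
        "tau": np.zeros((n_store, len(f_names))),
        "deviance": np.zeros(n_store),
    }
    kept = 0
    for it in range(settings.n_iter):
        in_burn = it < settings.burn_in
        adapt = min(0.25, 5.0 / np.sqrt(it + 1.0)) if in_burn else 0.0
        sampler.sweep(adapt)
        if not in_burn and (it - settings.burn_in) % settings.thin == 0 \
                and kept < n_store:
            p = sampler.params
            store["alpha"][kept] = p.alpha
            store["beta"][kept] = p.beta
            for k, f in enumerate(f_names):
                store["fields"][kept, k] = p.fields[f]
                store["tau"][kept, k] = p.tau[f]
            store["log_weights"][kept] = [getattr(p, w) for w in WEIGHT_NAMES]
            store["deviance"][kept] = -2.0 * sampler._loglik()
            kept += 1

    acc_rates = {
        k: (v[0] / v[1] if v[1] else np.nan) for k, v in sampler.acc.items()
    }
    return PosteriorChain(
        alpha=store["alpha"][:kept],
        beta=store["beta"][:kept],
        fields=store["fields"][:kept],
        log_weights=store["log_weights"][:kept],
        tau=store["tau"][:kept],
        deviance=store["deviance"][:kept],
        field_names=f_names,
        design_info=info,
        model=model,
        settings=settings,
        acceptance_rates=acc_rates,
        component_labels=graph.component_labels,
    )


# ---------------------------------------------------------------- summaries


def odds_ratios(chain: PosteriorChain) -> pd.DataFrame:
    """Posterior-mean odds ratios exp(beta) with 95% credible intervals."""
    if chain.n_draws == 0:
        raise ValueError("chain has no stored draws")
    rows = []
    for d, disease in enumerate(DISEASES):
        for c, name in enumerate(chain.design_info.columns):
            draws = np.exp(chain.beta[:, d, c])
            lo, hi = np.percentile(draws, [2.5, 97.5])
            rows.append(
                {
                    "disease": disease,
                    "variable": name,
                    "odds_ratio": float(draws.mean()),
                    "cri_low": float(lo),
                    "cri_high": float(hi),
                }
            )
    return pd.DataFrame(rows)


def spatial_effect_summaries(
    chain: PosteriorChain, exp_scale: bool = False
) -> pd.DataFrame:
    """Per-area posterior mean and 95% CrI of each disease's total spatial
    effect and of each shared component (reported on the raw field scale,
    the geometric mean of the two weighted loadings)."""
    if chain.n_draws == 0:
        raise ValueError("chain has no stored draws")
    m, _, na = chain.fields.shape
    comps: dict[str, np.ndarray] = {}
    totals = np.zeros((m, 3, na))
    for idx in range(m):
        totals[idx] = chain.params_at(idx).area_effects(chain.model)
    for d, disease in enumerate(DISEASES):
        comps[f"{disease}_total"] = totals[:, d, :]
    label = {
        "u12": "shared_ari_diarrhoea",
        "u13": "shared_ari_stunting",
        "u23": "shared_diarrhoea_stunting",
        "u": "shared_all",
    }
    for k, f in enumerate(chain.field_names):
        if f in label:
            comps[label[f]] = chain.fields[:, k, :]
    rows = []
    for name, draws in comps.items():
        vals = np.exp(draws) if exp_scale else draws
        mean = vals.mean(axis=0)
        lo, hi = np.percentile(vals, [2.5, 97.5], axis=0)
        for i in range(na):
            rows.append(
                {
                    "component": name,
                    "area": i,
                    "mean": float(mean[i]),
                    "cri_low": float(lo[i]),
                    "cri_high": float(hi[i]),
                }
            )
    return pd.DataFrame(rows)
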