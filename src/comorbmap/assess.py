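"""Model assessment: DIC, convergence diagnostics, parameter recovery.

DIC follows the classical conditional-deviance form: with deviance
D = -2 log L (likelihood part only, latent fields treated as parameters),

    pD  = Dbar - D(theta_bar),      DIC = Dbar + pD = 2 Dbar - D(theta_bar)

where theta_bar takes posterior means of the intercepts, fixed effects,
latent fields and log-weights (means on the log scale — pD is
parameterization-dependent, so the convention is fixed and documented).
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from .model import (
    McmcSettings,
    ModelSpec,
    PosteriorChain,
    PriorSpec,
    WEIGHT_NAMES,
    bernoulli_loglik,
    fit,
    linear_predictors,
)
from .design import build_design
from .records import DISEASES, records_to_frame
from .simulate import SimulationConfig, simulate_dataset

__all__ = [
    "DicResult",
    "compute_dic",
    "convergence_report",
    "recovery_experiment",
    "RecoveryReport",
]


@dataclass(frozen=True)
class DicResult:
    dbar: float
    d_at_mean: float

    @property
    def pd(self) -> float:
        return self.dbar - self.d_at_mean

    @property
    def dic(self) -> float:
        # computed in the 2*Dbar - D(theta_bar) form so the identity holds
        # exactly in floating point (Dbar + pD can differ in the last ulp)
        return 2.0 * self.dbar - self.d_at_mean


def compute_dic(chain: PosteriorChain, records) -> DicResult:
    """Deviance information criterion from a posterior chain.

    ``Dbar`` averages the per-draw deviances stored with the chain;
    ``D(theta_bar)`` re-evaluates the likelihood at the posterior-mean
    parameters on the supplied records.
    """
    if chain.n_draws == 0:
        raise ValueError("chain has no stored draws")
    df = records_to_frame(records).sort_values("area", kind="stable")
    # rebuild the design with the chain's exact column set
    xfull, info_full = build_design(
        df, age_center=chain.design_info.age_center, year_dummies="full"
    )
    cols = [xfull[:, info_full.columns.index(c)] for c in chain.design_info.columns]
    x = np.column_stack(cols) if cols else np.empty((len(df), 0))
    y = df[list(DISEASES)].to_numpy(float)
    area = df["area"].to_numpy(int)
    mean_params = chain.posterior_mean_params()
    eta = linear_predictors(mean_params, x, area, chain.model)
    d_at_mean = -2.0 * bernoulli_loglik(eta, y)
    return DicResult(dbar=float(chain.deviance.mean()), d_at_mean=float(d_at_mean))


def convergence_report(
    chain: PosteriorChain,
    rhat_threshold: float = 1.05,
    ess_threshold: float = 200.0,
    include_fields: bool = False,
) -> pd.DataFrame:
    """Split-chain R-hat and bulk ESS per reported scalar.

    A single chain is split into two halves (the standard split-R-hat
    construction).  Scalars failing either threshold — or constant, where
    R-hat is undefined — are flagged.
    """
    draws = chain.scalar_draws().drop(columns=["deviance"])
    if not include_fields:
        keep = [
            c
            for c in draws.columns
            if c.startswith(("alpha_", "beta_", "tau_")) or c in WEIGHT_NAMES
        ]
        draws = draws[keep]
    m = len(draws)
    if m < 4:
        raise ValueError("chain too short for split diagnostics")
    half = m // 2
    rows = []
    for name in draws.columns:
        arr = draws[name].to_numpy()[: 2 * half].reshape(2, half)
        if np.allclose(arr.std(), 0):
            rows.append(
                {"parameter": name, "rhat": np.nan, "ess": 0.0,
                 "mean": float(arr.mean()), "sd": 0.0, "flagged": True}
            )
            continue
        data = az.convert_to_dataset(arr[:, :, None], dims={"x": ["v"]})
        rhat = float(az.rhat(data)["x"].values[0])
        ess = float(az.ess(data)["x"].values[0])
        rows.append(
            {
                "parameter": name,
                "rhat": rhat,
                "ess": ess,
                "mean": float(arr.mean()),
                "sd": float(arr.std()),
                "flagged": bool(np.isnan(rhat) or rhat > rhat_threshold
                                or ess < ess_threshold),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RecoveryReport:
    """Outcome of a simulate-fit-compare experiment."""

    per_parameter: pd.DataFrame   # parameter, truth, bias, rmse, coverage
    per_replicate: pd.DataFrame   # replicate, parameter-level detail
    field_rank_correlations: pd.DataFrame
    n_replicates: int
    failures: list

    def summary(self) -> pd.DataFrame:
        return self.per_parameter


def _chain_weight_draws(chain: PosteriorChain, name: str) -> np.ndarray:
    return chain.log_weights[:, WEIGHT_NAMES.index(name)]


def recovery_experiment(
    sim_config: SimulationConfig,
    prior: PriorSpec | None = None,
    settings: McmcSettings | None = None,
    n_replicates: int = 5,
    seed: int = 0,
    model: ModelSpec | None = None,
) -> RecoveryReport:
    """Repeatedly simulate from known parameters, refit, and score recovery.

    For each replicate the generator and sampler seeds are derived from
    ``seed``; per-parameter bias, RMSE and 95% CrI coverage are aggregated
    over replicates for the log gradient weights and fixed effects, and
    Spearman rank correlations between posterior-mean latent fields and
    the generating truth are reported per shared component.  Replicates
    whose fit raises are recorded as failures, not fatal.
    """
    from scipy.stats import spearmanr

    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    prior = prior or PriorSpec()
    settings = settings or McmcSettings()
    model = model or ModelSpec()
    rng = np.random.default_rng(seed)

    truth_logw = {
        "log_w_ad": np.log(sim_config.w_ad),
        "log_w_as": np.log(sim_config.w_as),
        "log_w_ds": np.log(sim_config.w_ds),
        "log_d1": np.log(sim_config.w_all[0]),
        "log_d2": np.log(sim_config.w_all[1]),
    }
    rep_rows, rank_rows, failures = [], [], []
    for rep in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        cfg = replace_seed(sim_config, rep_seed)
        records, truth = simulate_dataset(cfg)
        try:
            chain = fit(
                records,
                cfg.graph,
                prior=prior,
                settings=McmcSettings(
                    n_iter=settings.n_iter,
                    burn_in=settings.burn_in,
                    thin=settings.thin,
                    seed=rep_seed + 1,
                ),
                model=model,
                year_dummies="full",
                age_center=cfg.covariates.mother_age_mean,
            )
        except Exception as exc:  # recorded, not fatal
            failures.append({"replicate": rep, "error": repr(exc)})
            continue
        if chain.n_draws == 0:
            failures.append({"replicate": rep, "error": "no stored draws"})
            continue
        converged = chain.n_draws >= 4
        for name in model.active_weights():
            draws = _chain_weight_draws(chain, name)
            lo, hi = np.percentile(draws, [2.5, 97.5])
            t = truth_logw[name]
            rep_rows.append(
                {"replicate": rep, "parameter": name, "truth": t,
                 "estimate": float(draws.mean()),
                 "cri_low": float(lo), "cri_high": float(hi),
                 "covered": bool(lo <= t <= hi), "converged": converged}
            )
        for d, disease in enumerate(DISEASES):
            for c, col in enumerate(chain.design_info.columns):
                draws = chain.beta[:, d, c]
                lo, hi = np.percentile(draws, [2.5, 97.5])
                t = float(sim_config.beta[d, c])
                rep_rows.append(
                    {"replicate": rep, "parameter": f"beta_{disease}_{col}",
                     "truth": t, "estimate": float(draws.mean()),
                     "cri_low": float(lo), "cri_high": float(hi),
                     "covered": bool(lo <= t <= hi), "converged": converged}
                )
        for k, fname in enumerate(chain.field_names):
            post_mean = chain.fields[:, k, :].mean(axis=0)
            rho = spearmanr(post_mean, truth.fields[fname]).statistic
            rank_rows.append(
                {"replicate": rep, "field": fname, "rank_correlation": float(rho)}
            )

    per_rep = pd.DataFrame(rep_rows)
    if len(per_rep):
        grouped = per_rep.groupby("parameter", sort=False)
        per_param = grouped.apply(
            lambda g: pd.Series(
                {
                    "truth": g["truth"].iloc[0],
                    "bias": float((g["estimate"] - g["truth"]).mean()),
                    "rmse": float(np.sqrt(((g["estimate"] - g["truth"]) ** 2).mean())),
                    "coverage": float(g["covered"].mean()),
                    "n": len(g),
                }
            ),
            include_groups=False,
        ).reset_index()
    else:
        per_param = pd.DataFrame(
            columns=["parameter", "truth", "bias", "rmse", "coverage", "n"]
        )
    return RecoveryReport(
        per_parameter=per_param,
        per_replicate=per_rep,
        field_rank_correlations=pd.DataFrame(rank_rows),
        n_replicates=n_replicates,
        failures=failures,
    )


def replace_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of a simulation config with a different seed."""
    return SimulationConfig(
        graph=config.graph,
        children_per_area=config.children_per_area,
        alpha=config.alpha.copy(),
        beta=config.beta.copy(),
        w_ad=config.w_ad,
        w_as=config.w_as,
        w_ds=config.w_ds,
        w_all=config.w_all,
        precisions=dict(config.precisions),
        covariates=config.covariates,
        seed=seed,
    )
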