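import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gamma as gamma_dist, kstest, norm

import comorbmap as cm
from comorbmap.areal import StateGraph, icar_precision, lattice_graph
from comorbmap.design import build_design
from comorbmap.model import (
    FIELD_NAMES,
    McmcSettings,
    ModelSpec,
    PosteriorChain,
    PriorSpec,
    SharedComponentParams,
    WEIGHT_NAMES,
    conjugate_tau_update,
    fit,
    linear_predictor,
    linear_predictors,
    log_posterior,
    odds_ratios,
    recenter,
    spatial_effect_summaries,
)
from comorbmap.records import DISEASES
from comorbmap.simulate import SimulationConfig, simulate_dataset


def random_params(n_areas, n_cov, rng, centered=True):
    fields = {}
    for f in FIELD_NAMES:
        v = rng.normal(0, 0.5, n_areas)
        if centered:
            v -= v.mean()
        fields[f] = v
    return SharedComponentParams(
        alpha=rng.normal(0, 1, 3),
        beta=rng.normal(0, 0.3, (3, n_cov)),
        fields=fields,
        log_w_ad=rng.normal(0, 0.3),
        log_w_as=rng.normal(0, 0.3),
        log_w_ds=rng.normal(0, 0.3),
        log_d1=rng.normal(0, 0.3),
        log_d2=rng.normal(0, 0.3),
        tau={f: float(rng.uniform(0.5, 5)) for f in FIELD_NAMES},
    )


def brute_force_log_posterior(params, records, prior, structure):
    """Fully independent term-by-term reference implementation: loops over
    records and areas with explicit formulas, no shared code paths."""
    age_mean = float(records["mother_age"].mean())
    w_ad, w_as, w_ds = (
        math.exp(params.log_w_ad),
        math.exp(params.log_w_as),
        math.exp(params.log_w_ds),
    )
    d1, d2 = math.exp(params.log_d1), math.exp(params.log_d2)
    d3 = math.exp(-(params.log_d1 + params.log_d2))
    total = 0.0
    # likelihood, one child x disease at a time
    for _, row in records.iterrows():
        i = int(row["area"])
        x = [
            row["residence"] == "urban",
            row["education"] == "primary",
            row["education"] == "secondary_plus",
            row["wealth"] == "poorer_middle",
            row["wealth"] == "richer_richest",
            row["sex"] == "female",
            row["age_band"] == "m12_23",
            row["age_band"] == "m24_59",
            row["mother_age"] - age_mean,
            row["year"] == 2013,
            row["year"] == 2018,
        ]
        x = [float(v) for v in x]
        f = params.fields
        spatial = [
            w_ad * f["u12"][i] + w_as * f["u13"][i] + d1 * f["u"][i] + f["s1"][i],
            f["u12"][i] / w_ad + w_ds * f["u23"][i] + d2 * f["u"][i] + f["s2"][i],
            f["u13"][i] / w_as + f["u23"][i] / w_ds + d3 * f["u"][i] + f["s3"][i],
        ]
        for d, disease in enumerate(DISEASES):
            eta = (
                params.alpha[d]
                + sum(params.beta[d][c] * x[c] for c in range(len(x)))
                + spatial[d]
            )
            p = 1.0 / (1.0 + math.exp(-eta))
            total += math.log(p) if row[disease] == 1 else math.log(1.0 - p)
    # ICAR priors + gamma hyperpriors
    q = structure.precision_pattern
    rank = structure.n_areas - structure.rank_deficiency
    for name in FIELD_NAMES:
        vec = params.fields[name]
        quad = 0.0
        for a in range(len(vec)):
            for b in range(len(vec)):
                quad += vec[a] * q[a, b] * vec[b]
        tau = params.tau[name]
        total += 0.5 * rank * math.log(tau) - 0.5 * tau * quad
        total += gamma_dist.logpdf(tau, prior.tau_shape, scale=1.0 / prior.tau_rate)
    for lw in (params.log_w_ad, params.log_w_as, params.log_w_ds,
               params.log_d1, params.log_d2):
        total += -0.5 * (lw / prior.log_weight_sd) ** 2
    for d in range(3):
        total += -0.5 * (params.alpha[d] / prior.alpha_sd) ** 2
        for c in range(params.beta.shape[1]):
            total += -0.5 * (params.beta[d][c] / prior.beta_sd) ** 2
    return total


class TestLinearPredictor:
    def test_zero_params_give_zero(self, small_dataset):
        records, _, config = small_dataset
        params = SharedComponentParams.zeros(config.graph.n_areas, 11)
        _, info = build_design(records, year_dummies="full")
        eta = linear_predictor(params, records.iloc[0], "ari", info)
        assert eta == 0.0

    def test_pairwise_weight_asymmetry_in_assembly(self, small_dataset):
        """u12=1 with weight 2 adds +2 to ARI, +0.5 to diarrhoea, 0 to
        stunting at that area."""
        records, _, config = small_dataset
        n = config.graph.n_areas
        params = SharedComponentParams.zeros(n, 11)
        params.log_w_ad = np.log(2.0)
        rec = records.iloc[0]
        i = int(rec["area"])
        params.fields["u12"] = np.zeros(n)
        params.fields["u12"][i] = 1.0
        _, info = build_design(records, year_dummies="full")
        assert linear_predictor(params, rec, "ari", info) == pytest.approx(2.0)
        assert linear_predictor(params, rec, "diarrhoea", info) == pytest.approx(0.5)
        assert linear_predictor(params, rec, "stunting", info) == pytest.approx(0.0)

    def test_vectorized_matches_scalar_oracle(self, small_dataset, rng):
        records, _, config = small_dataset
        sub = records.head(100)
        x, info = build_design(sub, year_dummies="full")
        params = random_params(config.graph.n_areas, 11, rng)
        etas = linear_predictors(params, x, sub["area"].to_numpy())
        for j in [0, 17, 55, 99]:
            for d in range(3):
                scalar = linear_predictor(params, sub.iloc[j], d, info)
                assert etas[j, d] == pytest.approx(scalar, abs=1e-12)


class TestLogPosterior:
    def test_matches_brute_force_oracle(self, small_dataset, rng):
        records, _, config = small_dataset
        sub = records.head(20).reset_index(drop=True)
        structure = icar_precision(config.graph)
        prior = PriorSpec()
        params = random_params(config.graph.n_areas, 11, rng)
        ours = log_posterior(
            params, sub, prior, structure, year_dummies="full",
            age_center=float(sub["mother_age"].mean()),
        )
        ref = brute_force_log_posterior(params, sub, prior, structure)
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_single_record_zero_params_likelihood(self, small_dataset):
        """All-zero parameters give pi = 1/2 per disease: the likelihood
        part is exactly 3 log(1/2)."""
        records, _, config = small_dataset
        structure = icar_precision(config.graph)
        prior = PriorSpec()
        params = SharedComponentParams.zeros(config.graph.n_areas, 11)
        params.tau = {f: 1.0 for f in FIELD_NAMES}
        one = records.head(1)
        lp = log_posterior(params, one, prior, structure, year_dummies="full")
        prior_only = log_posterior(
            params, one.head(0), prior, structure, year_dummies="full"
        )
        assert lp - prior_only == pytest.approx(3 * np.log(0.5), abs=1e-10)

    def test_level_shift_invariance_of_icar_quadratic(self, small_dataset, rng):
        """Adding a constant within a component leaves x'Qx unchanged."""
        records, _, config = small_dataset
        structure = icar_precision(config.graph)
        prior = PriorSpec()
        params = random_params(config.graph.n_areas, 11, rng)
        base = log_posterior(
            params, records.head(0), prior, structure, year_dummies="full"
        )
        shifted = random_params(config.graph.n_areas, 11, np.random.default_rng(0))
        for f in FIELD_NAMES:
            shifted.fields[f] = params.fields[f] + 0.37
        shifted.alpha = params.alpha
        shifted.beta = params.beta
        shifted.tau = params.tau
        for w in WEIGHT_NAMES:
            setattr(shifted, w, getattr(params, w))
        after = log_posterior(
            shifted, records.head(0), prior, structure, year_dummies="full"
        )
        assert after == pytest.approx(base, abs=1e-8)


class TestRecenter:
    def test_recentering_preserves_linear_predictors(self, small_dataset, rng):
        records, _, config = small_dataset
        structure = icar_precision(config.graph)
        params = random_params(config.graph.n_areas, 11, rng, centered=False)
        sub = records.head(50)
        x, info = build_design(sub, year_dummies="full")
        before = linear_predictors(params, x, sub["area"].to_numpy())
        centred = recenter(params, structure)
        after = linear_predictors(centred, x, sub["area"].to_numpy())
        np.testing.assert_allclose(after, before, atol=1e-12)
        for f in FIELD_NAMES:
            assert abs(centred.fields[f].sum()) < 1e-10


class TestConjugateTau:
    def test_zero_field_reduces_to_prior_rate(self, path3, rng):
        structure = icar_precision(path3)
        prior = PriorSpec(tau_shape=2.0, tau_rate=1.0)
        draws = [
            conjugate_tau_update(np.zeros(3), structure, prior, rng)
            for _ in range(4000)
        ]
        # posterior is Gamma(2 + (3-1)/2, 1); check mean within 3 se
        expected_mean = (2.0 + 1.0) / 1.0
        se = np.sqrt(3.0) / np.sqrt(len(draws))
        assert abs(np.mean(draws) - expected_mean) < 3 * se

    def test_path3_quadratic_form_by_hand(self, path3, rng):
        """Field (1, 0, -1) on the path has x'Qx = 2 and rank n-k = 2."""
        structure = icar_precision(path3)
        prior = PriorSpec(tau_shape=1.0, tau_rate=1.0)
        field = np.array([1.0, 0.0, -1.0])
        shape, rate = 1.0 + 1.0, 1.0 + 1.0  # shape + rank/2, rate + quad/2
        draws = np.array(
            [conjugate_tau_update(field, structure, prior, rng) for _ in range(5000)]
        )
        ks = kstest(draws, gamma_dist(shape, scale=1 / rate).cdf)
        assert ks.pvalue > 0.01

    def test_gibbs_tau_marginal_matches_analytic_posterior(self, path3):
        """On the conjugate sub-problem (field held fixed) the sampler's
        tau draws are exactly the analytic Gamma posterior."""
        structure = icar_precision(path3)
        prior = PriorSpec(tau_shape=3.0, tau_rate=2.0)
        rng = np.random.default_rng(77)
        field = np.array([0.5, 0.1, -0.6])
        quad = float(field @ structure.precision_pattern @ field)
        draws = np.array(
            [conjugate_tau_update(field, structure, prior, rng) for _ in range(5000)]
        )
        analytic = gamma_dist(3.0 + 1.0, scale=1.0 / (2.0 + quad / 2))
        assert kstest(draws, analytic.cdf).pvalue > 0.01


class TestFit:
    def test_unknown_area_rejected(self, small_dataset):
        records, _, _ = small_dataset
        tiny = lattice_graph(1, 2, 0)
        with pytest.raises(Exception, match="area"):
            fit(records, tiny, settings=McmcSettings(n_iter=10, burn_in=5))

    def test_same_seed_reproduces_chain(self, small_dataset):
        records, _, config = small_dataset
        sub = records.head(600)
        s = McmcSettings(n_iter=60, burn_in=20, thin=1, seed=123)
        a = fit(sub, config.graph, settings=s)
        b = fit(sub, config.graph, settings=s)
        np.testing.assert_array_equal(a.alpha, b.alpha)
        np.testing.assert_array_equal(a.fields, b.fields)
        np.testing.assert_array_equal(a.log_weights, b.log_weights)

    def test_intercept_only_recovers_marginal_logit(self):
        """With all latent components off, the intercept posterior centres
        on the logit of the observed prevalence (the closed-form MLE)."""
        graph = lattice_graph(2, 2, 0)
        cfg = SimulationConfig(
            graph=graph,
            children_per_area=1000,
            alpha=np.array([-2.0, -1.0, -1.5]),
            beta=np.zeros((3, 11)),
            precisions={f: 1e8 for f in FIELD_NAMES},
            seed=8,
        )
        records, _ = simulate_dataset(cfg)
        records = records.assign(
            residence="rural", education="none", wealth="poorest", sex="male",
            age_band="lt12", mother_age=29.0, year=2008,
        )
        chain = fit(
            records, graph,
            settings=McmcSettings(n_iter=800, burn_in=300, thin=1, seed=3),
            model=ModelSpec(pairwise=False, overall=False, specific=False),
        )
        prev = records[list(DISEASES)].mean().to_numpy()
        mle = np.log(prev / (1 - prev))
        post = chain.alpha.mean(axis=0)
        mc_se = np.sqrt(1.0 / (len(records) * prev * (1 - prev)))
        np.testing.assert_array_less(np.abs(post - mle), 4 * mc_se + 0.02)

    def test_prior_recovery_with_no_records(self):
        """Zero records leave the posterior equal to the prior; the tau
        chain must match the prior mean."""
        import comorbmap.records as rec_mod

        graph = lattice_graph(2, 2, 0)
        empty = pd.DataFrame(columns=list(rec_mod.RECORD_COLUMNS))
        prior = PriorSpec(tau_shape=5.0, tau_rate=1.0)
        chain = fit(
            empty, graph, prior=prior,
            settings=McmcSettings(n_iter=3000, burn_in=500, thin=1, seed=9),
        )
        tau_means = chain.tau.mean(axis=0)
        # prior mean 5, sd sqrt(5); generous MC tolerance
        assert np.all(np.abs(tau_means - 5.0) < 0.6)

    def test_zero_case_disease_warns_and_fits(self, small_dataset):
        records, _, config = small_dataset
        crippled = records.head(400).copy()
        crippled["ari"] = 0
        with pytest.warns(UserWarning, match="zero cases"):
            chain = fit(
                crippled, config.graph,
                settings=McmcSettings(n_iter=40, burn_in=10, thin=1, seed=2),
            )
        assert chain.n_draws > 0

    def test_exchangeable_specific_fields_variant_runs(self, small_dataset):
        """The iid-normal option for the disease-specific fields fits and
        keeps those fields unconstrained (no sum-to-zero projection)."""
        records, _, config = small_dataset
        chain = fit(
            records.head(900), config.graph,
            settings=McmcSettings(n_iter=80, burn_in=30, thin=2, seed=5),
            model=ModelSpec(specific_prior="exchangeable"),
        )
        assert chain.n_draws > 0
        # shared fields remain centred; specific ones need not be
        k = chain.field_names.index("u12")
        assert abs(chain.fields[-1, k].sum()) < 1e-8

    def test_chain_save_load_round_trip(self, tmp_path, small_dataset):
        records, _, config = small_dataset
        chain = fit(
            records.head(500), config.graph,
            settings=McmcSettings(n_iter=30, burn_in=10, thin=2, seed=4),
        )
        chain.save(tmp_path / "chain")
        back = PosteriorChain.load(tmp_path / "chain")
        np.testing.assert_allclose(back.alpha, chain.alpha)
        np.testing.assert_allclose(back.fields, chain.fields)
        np.testing.assert_allclose(back.deviance, chain.deviance)
        assert back.field_names == chain.field_names
        assert back.design_info.columns == chain.design_info.columns


def _constant_chain(n_draws, n_areas=4, p=2, beta_value=0.0):
    from comorbmap.design import DesignInfo

    f_names = ("s1", "s2", "s3")
    return PosteriorChain(
        alpha=np.zeros((n_draws, 3)),
        beta=np.full((n_draws, 3, p), beta_value),
        fields=np.zeros((n_draws, 3, n_areas)),
        log_weights=np.zeros((n_draws, 5)),
        tau=np.ones((n_draws, 3)),
        deviance=np.zeros(n_draws),
        field_names=f_names,
        design_info=DesignInfo(columns=("urban", "female"), age_center=29.0),
        model=ModelSpec(pairwise=False, overall=False, specific=True),
        settings=McmcSettings(n_iter=2 * n_draws, burn_in=0, thin=2),
        acceptance_rates={},
        component_labels=tuple([0] * n_areas),
    )


class TestSummaries:
    def test_zero_beta_draws_give_unit_odds_ratio(self):
        table = odds_ratios(_constant_chain(50))
        assert (table["odds_ratio"] == 1.0).all()
        assert (table["cri_low"] == 1.0).all()
        assert (table["cri_high"] == 1.0).all()

    def test_constant_log2_draws_give_or_two(self):
        table = odds_ratios(_constant_chain(50, beta_value=np.log(2.0)))
        assert np.allclose(table["odds_ratio"], 2.0)

    def test_all_zero_fields_give_zero_effects(self):
        table = spatial_effect_summaries(_constant_chain(10))
        assert (table["mean"] == 0.0).all()
        exp_table = spatial_effect_summaries(_constant_chain(10), exp_scale=True)
        assert (exp_table["mean"] == 1.0).all()

    def test_single_draw_chain_summaries_equal_draw(self, small_dataset):
        records, _, config = small_dataset
        chain = fit(
            records.head(400), config.graph,
            settings=McmcSettings(n_iter=12, burn_in=10, thin=2, seed=6),
        )
        assert chain.n_draws == 1
        table = spatial_effect_summaries(chain)
        params = chain.params_at(0)
        eff = params.area_effects(chain.model)
        sub = table[table["component"] == "ari_total"]
        np.testing.assert_allclose(sub["mean"].to_numpy(), eff[0], atol=1e-12)
        np.testing.assert_allclose(sub["cri_low"].to_numpy(), eff[0], atol=1e-12)
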