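"""Monte Carlo propagation, distribution summaries and Spearman sensitivity."""

import math

import numpy as np
import pytest
from scipy import stats

from pahrisk import (
    DistributionSpec,
    RiskDistribution,
    ScenarioDistributions,
    analytic_mean_risk,
    load_fixture,
    monte_carlo_risk,
    sample,
    spearman_sensitivity,
    summarize_distribution,
)

SEED = 0


def scenario_dists(fixture, seed=SEED, n_trials=10_000, **overrides):
    specs = dict(load_fixture(fixture))
    specs.update(overrides)
    return ScenarioDistributions(specs=specs, n_trials=n_trials, seed=seed)


class TestSampler:
    def test_point_spec_constant(self):
        rng = np.random.default_rng(SEED)
        spec = DistributionSpec.uniform(153, 153)
        assert sample(spec, 4, rng).tolist() == [153, 153, 153, 153]

    def test_lognormal_moment_matching(self):
        """Arithmetic mean/SD are recovered from moment-matched draws."""
        spec = DistributionSpec.lognormal(52, 119)
        draws = sample(spec, 1_000_000, np.random.default_rng(SEED))
        se = 119 / math.sqrt(draws.size)
        assert abs(draws.mean() - 52) < 3 * se
        assert draws.std(ddof=1) == pytest.approx(119, rel=0.05)

    def test_log_space_closed_form(self):
        spec = DistributionSpec.lognormal(52, 119)
        mu, sigma = spec.log_params()
        assert sigma**2 == pytest.approx(math.log(1 + (119 / 52) ** 2), rel=1e-12)
        assert mu == pytest.approx(math.log(52) - sigma**2 / 2, rel=1e-12)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            DistributionSpec(family="triangular", min=0, max=1)
        with pytest.raises(ValueError):
            DistributionSpec.lognormal(-1, 2)
        with pytest.raises(ValueError):
            DistributionSpec.uniform(5, 4)

    def test_strictly_positive_draws(self):
        draws = sample(DistributionSpec.lognormal(0.0157, 0.0297), 50_000,
                       np.random.default_rng(SEED))
        assert (draws > 0).all()


class TestMonteCarlo:
    def test_seed_determinism(self):
        a = monte_carlo_risk(scenario_dists("table4"))
        b = monte_carlo_risk(scenario_dists("table4"))
        assert np.array_equal(a.draws, b.draws)
        assert all(np.array_equal(a.inputs[v], b.inputs[v]) for v in a.inputs)

    def test_degenerate_all_point_equals_deterministic(self):
        from pahrisk import IngestionScenario, ingestion_risk

        dists = scenario_dists(
            "table5", IR=DistributionSpec.uniform(37, 37), n_trials=100
        )
        rd = monte_carlo_risk(dists)
        expected = ingestion_risk(
            IngestionScenario(cs_mg_per_kg=0.0998, ir_mg_per_day=37, ef_days_per_year=153)
        ).risk
        assert np.allclose(rd.draws, expected, rtol=1e-12)

    def test_missing_variable_named(self):
        specs = dict(load_fixture("table5"))
        del specs["IR"]
        with pytest.raises(ValueError, match="IR"):
            ScenarioDistributions(specs=specs)

    def test_max_concentration_scenario_mean(self):
        """Mean risk agrees with the product-of-means expectation; expressed
        per 100,000 it rounds to 0.02."""
        dists = scenario_dists("table5")
        rd = monte_carlo_risk(dists)
        analytic = analytic_mean_risk(dists)
        assert abs(rd.mean - analytic) < 4 * rd.mc_standard_error()
        assert round(rd.mean * 1e5, 2) == 0.02

    def test_field_concentration_scenario_mean(self):
        dists = scenario_dists("table4")
        rd = monte_carlo_risk(dists)
        analytic = analytic_mean_risk(dists)  # ~3.12e-8
        assert analytic == pytest.approx(3.1227e-8, rel=1e-4)
        assert abs(rd.mean - analytic) < 4 * rd.mc_standard_error()

    def test_concentration_scaling_under_shared_seed(self):
        base = monte_carlo_risk(scenario_dists("table5"))
        scaled = monte_carlo_risk(
            scenario_dists("table5", Cs=DistributionSpec.uniform(0.2994, 0.2994))
        )
        assert np.allclose(scaled.draws, 3.0 * base.draws, rtol=1e-12)

    def test_single_varying_input_matches_closed_form_cdf(self):
        """With only IR varying the risk is a scaled lognormal; the empirical
        CDF of 10,000 draws stays within KS distance 0.02 of it."""
        dists = scenario_dists("table5")
        rd = monte_carlo_risk(dists)
        mu, sigma = dists.specs["IR"].log_params()
        c = analytic_mean_risk(dists) / 52.0  # risk per unit IR
        ks = stats.kstest(rd.draws, "lognorm", args=(sigma, 0, math.exp(mu) * c))
        assert ks.statistic < 0.02


class TestSummaries:
    def test_constant_draws(self):
        rd = RiskDistribution(draws=np.full(100, 3.0e-7), inputs={}, seed=0)
        assert rd.percentile(5) == rd.percentile(95) == 3.0e-7

    def test_percentile_domain(self):
        rd = RiskDistribution(draws=np.arange(10.0), inputs={}, seed=0)
        with pytest.raises(ValueError):
            rd.percentile(0)
        with pytest.raises(ValueError):
            rd.percentile(100)

    def test_max_concentration_scenario_upper_tail(self):
        rd = monte_carlo_risk(scenario_dists("table5"))
        summary = summarize_distribution(rd)
        p95 = summary["percentiles"][95.0]
        # closed-form 95th pct of the scaled lognormal IR is ~7.4e-7
        assert 6.7e-7 <= p95 <= 7.5e-7
        assert summary["prob_exceeds"][1e-5] < 0.001

    def test_exceedance_monotone(self):
        rd = monte_carlo_risk(scenario_dists("table4"))
        probs = [rd.prob_exceeds(t) for t in (1e-9, 1e-8, 1e-7, 1e-6)]
        assert probs == sorted(probs, reverse=True)


class TestSensitivity:
    def test_hand_computed_rank_formula(self):
        """rho = 1 - 6*sum(d^2)/(n(n^2-1)) on a 5-tuple without ties."""
        x = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        y = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        rd = RiskDistribution(
            draws=np.tile(y, 2), inputs={"A": np.tile(x, 2), "B": np.tile(y, 2)}, seed=0
        )
        result = spearman_sensitivity(rd)
        assert result.rho["A"] == pytest.approx(0.5, abs=1e-12)
        assert result.rho["B"] == pytest.approx(1.0)

    def test_single_driver_has_unit_rho(self):
        """When risk is a monotone transform of one input, its rho is 1."""
        rng = np.random.default_rng(SEED)
        ir = rng.lognormal(3.0, 1.3, 500)
        noise = rng.uniform(0, 1, 500)        # varies but does not enter risk
        fixed = np.full(500, 80.0)
        rd = RiskDistribution(
            draws=1e-9 * ir, inputs={"IR": ir, "noise": noise, "BW": fixed}, seed=SEED
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            result = spearman_sensitivity(rd)
        assert result.rho["IR"] == pytest.approx(1.0)
        assert abs(result.rho["noise"]) < 0.1
        assert result.excluded == ("BW",)

    def test_study_rank_order_and_magnitudes(self):
        """IR dominates, then Cs, then EF (reference run: 0.71 / 0.61 / 0.11)."""
        dists = scenario_dists("table4", EF=DistributionSpec.uniform(153, 365))
        with pytest.warns(UserWarning):
            result = spearman_sensitivity(monte_carlo_risk(dists))
        assert result.ranking[:3] == ("IR", "Cs", "EF")
        assert result.rho["IR"] == pytest.approx(0.71, abs=0.15)
        assert result.rho["Cs"] == pytest.approx(0.61, abs=0.15)
        assert result.rho["EF"] == pytest.approx(0.11, abs=0.15)

    def test_invariant_under_monotone_transform(self):
        dists = scenario_dists("table4", EF=DistributionSpec.uniform(153, 365))
        rd = monte_carlo_risk(dists)
        transformed = RiskDistribution(
            draws=np.log(rd.draws),
            inputs={k: np.exp(v / np.max(v)) for k, v in rd.inputs.items()},
            seed=rd.seed,
        )
        with pytest.warns(UserWarning):
            a = spearman_sensitivity(rd)
        with pytest.warns(UserWarning):
            b = spearman_sensitivity(transformed)
        for v in ("Cs", "IR", "EF"):
            assert b.rho[v] == pytest.approx(a.rho[v], abs=1e-12)
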