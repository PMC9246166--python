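"""Three-pathway ILCR closed forms, distribution fitting, Monte Carlo risk."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from soilpah.ilcr import (
    ExposureParams,
    fit_best_distribution,
    ilcr_pathways,
    monte_carlo_ilcr,
    risk_category,
)


class TestExposureParams:
    def test_defaults(self):
        p = ExposureParams()
        assert (p.bw, p.ef, p.ed) == (62.0, 180.0, 24.0)
        assert (p.ir_inhalation, p.ir_ingestion) == (20.0, 100.0)
        assert (p.sa, p.af, p.at, p.abs_dermal) == (5700.0, 0.07, 25550.0, 0.13)
        assert p.pef == 1.36e9
        assert (p.csf_inhalation, p.csf_ingestion, p.csf_dermal) == (3.85, 7.3, 25.0)

    def test_positive_validation(self):
        with pytest.raises(ValueError):
            ExposureParams(bw=0.0)


class TestPathways:
    def test_zero_concentration(self):
        r = ilcr_pathways(0.0)
        assert r.ingestion == r.dermal == r.inhalation == r.total == 0.0

    def test_dermal_to_ingestion_ratio(self):
        r = ilcr_pathways(123.4)
        assert r.dermal / r.ingestion == pytest.approx(1.776, abs=5e-4)

    def test_inhalation_to_ingestion_ratio(self):
        r = ilcr_pathways(123.4)
        assert r.inhalation / r.ingestion == pytest.approx(7.8e-5, rel=0.01)

    def test_pathway_ordering(self):
        r = ilcr_pathways(50.0)
        assert r.dermal > r.ingestion > r.inhalation

    @settings(derandomize=True, max_examples=100)
    @given(c=st.floats(1e-3, 1e4), k=st.floats(1.01, 100))
    def test_strictly_linear_in_concentration(self, c, k):
        r1, r2 = ilcr_pathways(c), ilcr_pathways(k * c)
        assert r2.total == pytest.approx(k * r1.total, rel=1e-9)
        assert r2.total > r1.total

    def test_total_is_pathway_sum(self):
        r = ilcr_pathways(77.7)
        assert r.total == pytest.approx(r.ingestion + r.dermal + r.inhalation, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ilcr_pathways(-1.0)


class TestDistributionFitting:
    def test_lognormal_recovered_from_big_sample(self):
        mu, sigma = 4.0, 0.6
        x = np.random.default_rng(1).lognormal(mu, sigma, size=10_000)
        fit = fit_best_distribution(x)
        assert fit.family == "lognormal"
        assert fit.frozen.median() == pytest.approx(np.exp(mu), rel=0.02)

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fit_best_distribution(np.full(10, 3.3))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_best_distribution([1.0, 2.0, 3.0])

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fit_best_distribution([1.0, 2.0, 0.0, 4.0, 5.0])

    def test_pareto_uses_classical_parameterization(self):
        x = np.random.default_rng(3).pareto(2.5, size=500) + 1.0
        x *= 40.0
        fit = fit_best_distribution(x, candidates=("pareto",))
        b, loc, scale = fit.params
        assert loc == 0.0
        assert scale == pytest.approx(x.min())
        # closed-form MLE for the shape given scale = min
        assert b == pytest.approx(len(x) / np.log(x / x.min()).sum(), rel=1e-9)

    def test_urban_bapeq_fit_is_heavy_tailed(self, records):
        values = np.array([r.bapeq for r in records if r.land_use == "urban"])
        fit = fit_best_distribution(values)
        assert fit.family in {"lognormal", "gamma", "pareto", "weibull"}


class TestMonteCarlo:
    def test_point_mass_percentiles(self):
        from soilpah.ilcr import FittedDistribution

        c = 150.0
        degenerate = FittedDistribution("point", (c,), stats.uniform(loc=c, scale=0.0), 0.0, 1)
        dist = monte_carlo_ilcr(degenerate, n_iter=2000, seed=0)
        expected = ilcr_pathways(c).total
        for v in dist.percentiles.values():
            assert v == pytest.approx(expected, rel=1e-12)

    def test_doubling_concentration_doubles_percentiles(self):
        from soilpah.ilcr import FittedDistribution

        base = stats.lognorm(0.5, scale=100.0)
        doubled = stats.lognorm(0.5, scale=200.0)
        d1 = monte_carlo_ilcr(FittedDistribution("lognormal", (), base, 0.0, 2), n_iter=5000, seed=4)
        d2 = monte_carlo_ilcr(FittedDistribution("lognormal", (), doubled, 0.0, 2), n_iter=5000, seed=4)
        for q in d1.percentiles:
            assert d2.percentiles[q] == pytest.approx(2.0 * d1.percentiles[q], rel=1e-9)

    def test_percentiles_monotone(self, records):
        values = np.array([r.bapeq for r in records if r.land_use == "urban"])
        dist = monte_carlo_ilcr(fit_best_distribution(values), n_iter=5000, seed=1)
        qs = sorted(dist.percentiles)
        vals = [dist.percentiles[q] for q in qs]
        assert (np.diff(vals) >= 0).all()
        assert dist.percentiles[95.0] >= dist.percentiles[50.0]

    def test_seed_stability_of_p95(self, records):
        values = np.array([r.bapeq for r in records if r.land_use == "urban"])
        fit = fit_best_distribution(values)
        p95 = [monte_carlo_ilcr(fit, n_iter=10_000, seed=s).p95 for s in (1, 2)]
        assert abs(p95[0] - p95[1]) / p95[0] <= 0.10

    def test_minimum_iterations_enforced(self, records):
        values = np.array([r.bapeq for r in records if r.land_use == "urban"])
        with pytest.raises(ValueError):
            monte_carlo_ilcr(fit_best_distribution(values), n_iter=10, seed=0)


class TestRiskCategory:
    @pytest.mark.parametrize(
        "value, category",
        [
            (5e-7, "safe"),
            (9.6e-6, "low risk"),
            (2e-4, "marginal safety"),
            (1e-6, "low risk"),
            (1e-4, "low risk"),
        ],
    )
    def test_bands(self, value, category):
        assert risk_category(value) == category

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            risk_category(-1e-7)
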