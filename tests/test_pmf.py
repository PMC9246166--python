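"""Uncertainty model, weighted factorization, normalization and labelling."""

import warnings

import numpy as np
import pytest

from soilpah.concentrations import ConcentrationMatrix
from soilpah.pmf import (
    UncertaintyMatrix,
    build_uncertainty,
    equation_uncertainty,
    fit_pmf,
    label_sources,
    normalize_profiles,
    scan_factors,
    source_contribution_percent,
)
from soilpah.synthetic import simulate_dataset

from conftest import best_permutation_cosines


class TestEquationUncertainty:
    @pytest.mark.parametrize(
        "x, mdl, ef, expected",
        [
            (2.0, 6.0, 0.1, 5.0),  # below MDL: (5/6)*6
            (30.0, 4.0, 0.1, 5.0),  # above MDL: sqrt(3^2 + 4^2)
            (6.0, 6.0, 0.1, 5.0),  # boundary x == MDL uses the below-MDL branch
        ],
    )
    def test_hand_cases(self, x, mdl, ef, expected):
        assert equation_uncertainty(x, mdl, ef) == pytest.approx(expected)

    def test_build_uncertainty_positive(self, four_source_dataset):
        X, _ = four_source_dataset
        unc = build_uncertainty(X)
        assert unc.values.shape == X.values.shape
        assert (unc.values > 0).all()

    def test_nonpositive_mdl_rejected(self, four_source_dataset):
        X, _ = four_source_dataset
        bad = X.catalog  # catalog guards MDL > 0 at construction
        with pytest.raises(ValueError):
            bad.with_overrides(mdl=0.0)

    def test_uncertainty_matrix_validation(self):
        with pytest.raises(ValueError):
            UncertaintyMatrix(np.array([[1.0, 0.0]]))


class TestFitPmf:
    def test_rank_one_exact(self, catalog):
        g = np.array([4.0, 1.0, 2.5, 7.0])[:, None]
        f = np.linspace(1, 2, 16)[None, :]
        X = g @ f
        m = fit_pmf(X, np.full_like(X, 0.5), p=1, n_starts=5, seed=0)
        assert m.Q <= 1e-6 * X.size
        np.testing.assert_allclose(m.G @ m.F, X, rtol=1e-4)

    def test_noise_free_two_source_recovery(self, separated_two_source_library):
        """Exact data from separated profiles with pure anchor samples is recovered."""
        lib = separated_two_source_library
        rng = np.random.default_rng(7)
        G = rng.lognormal(np.log([300.0, 100.0]), 0.7, size=(20, 2))
        G[0] = [400.0, 0.0]
        G[1] = [0.0, 150.0]
        X, truth = simulate_dataset(20, library=lib, error_fraction=0.0, mdl=0.0, seed=1, contributions=G)
        unc = build_uncertainty(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_pmf(X, unc, p=2, n_starts=10, seed=1, max_iter=30000)
        assert m.Q <= 1e-6 * X.values.size
        norm = normalize_profiles(m)
        cos, _ = best_permutation_cosines(norm.f, lib.profiles)
        assert min(cos) >= 0.999

    def test_q_matches_brute_force_oracle(self, four_source_dataset):
        X, _ = four_source_dataset
        unc = build_uncertainty(X)
        m = fit_pmf(X, unc, p=4, n_starts=3, seed=2, max_iter=500)
        recon = m.G @ m.F
        q_brute = 0.0
        for i in range(X.values.shape[0]):
            for j in range(X.values.shape[1]):
                q_brute += ((X.values[i, j] - recon[i, j]) / unc.values[i, j]) ** 2
        assert m.Q == pytest.approx(q_brute, rel=1e-8)
        assert m.recompute_q() == pytest.approx(m.Q, rel=1e-8)

    def test_objective_monotone_decreasing(self, four_source_dataset):
        X, _ = four_source_dataset
        unc = build_uncertainty(X)
        m = fit_pmf(X, unc, p=3, n_starts=2, seed=5, max_iter=400)
        diffs = np.diff(m.q_trace)
        assert (diffs <= 1e-9 * np.abs(m.q_trace[:-1])).all()

    def test_joint_scaling_invariance(self, four_source_dataset):
        """Scaling X and U together leaves Q unchanged and scales the product."""
        X, _ = four_source_dataset
        unc = build_uncertainty(X)
        m1 = fit_pmf(X.values, unc.values, p=2, n_starts=2, seed=3, max_iter=300)
        c = 7.0
        m2 = fit_pmf(c * X.values, c * unc.values, p=2, n_starts=2, seed=3, max_iter=300)
        assert m2.Q == pytest.approx(m1.Q, rel=1e-6)
        np.testing.assert_allclose(m2.G @ m2.F, c * (m1.G @ m1.F), rtol=1e-6)

    def test_deterministic_for_seed(self, four_source_dataset):
        X, _ = four_source_dataset
        unc = build_uncertainty(X)
        m1 = fit_pmf(X, unc, p=2, n_starts=3, seed=11, max_iter=200)
        m2 = fit_pmf(X, unc, p=2, n_starts=3, seed=11, max_iter=200)
        np.testing.assert_array_equal(m1.G, m2.G)
        np.testing.assert_array_equal(m1.F, m2.F)

    def test_invalid_inputs_rejected(self, four_source_dataset):
        X, _ = four_source_dataset
        unc = build_uncertainty(X)
        with pytest.raises(ValueError):
            fit_pmf(X, unc, p=17)
        with pytest.raises(ValueError):
            fit_pmf(np.zeros((5, 16)), np.ones((5, 16)), p=2)
        with pytest.raises(ValueError):
            fit_pmf(X.values, -unc.values, p=2)


@pytest.fixture(scope="module")
def fitted(four_source_dataset):
    X, truth = four_source_dataset
    unc = build_uncertainty(X)
    model = fit_pmf(X, unc, p=4, n_starts=20, seed=0)
    return X, truth, normalize_profiles(model), model


class TestNormalizationAndLabels:

    def test_profile_rows_sum_to_one(self, fitted):
        _, _, norm, _ = fitted
        np.testing.assert_allclose(norm.f.sum(axis=1), 1.0, atol=1e-9)

    def test_reconstruction_identity(self, fitted):
        _, _, norm, model = fitted
        np.testing.assert_allclose(norm.S @ norm.f, model.G @ model.F, rtol=1e-10)

    def test_permutation_invariance(self, fitted):
        _, _, norm, model = fitted
        perm = [2, 0, 3, 1]
        recon = norm.S[:, perm] @ norm.f[perm, :]
        np.testing.assert_allclose(recon, model.G @ model.F, rtol=1e-10)

    def test_labels_recovered_on_synthetic_truth(self, fitted, library):
        _, truth, norm, _ = fitted
        labels = label_sources(norm, library)
        cos, perm = best_permutation_cosines(norm.f, library.profiles)
        expected = [library.names[perm[k]] for k in range(4)]
        assert [lab.name for lab in labels] == expected
        assert not any(lab.low_confidence for lab in labels)

    def test_exact_reference_is_self_labelled(self, library):
        from soilpah.pmf import NormalizedModel

        norm = NormalizedModel(S=np.ones((3, 4)), f=library.profiles.copy(), catalog=library.catalog)
        labels = label_sources(norm, library)
        assert [lab.name for lab in labels] == list(library.names)
        assert all(lab.similarity >= 0.999 for lab in labels)

    def test_unmatched_factor_flagged(self, library):
        from soilpah.pmf import NormalizedModel

        f = np.zeros((1, 16))
        f[0, library.catalog.index("Naph")] = 0.0
        # a profile orthogonal-ish to every reference: all mass on a compound
        # that no reference emphasizes is impossible here, so use a spike on Acy
        f[0, library.catalog.index("Acy")] = 1.0
        norm = NormalizedModel(S=np.ones((2, 1)), f=f, catalog=library.catalog)
        labels = label_sources(norm, library)
        assert labels[0].low_confidence

    def test_contribution_percent_sums_to_100(self, fitted):
        _, _, norm, _ = fitted
        pct = source_contribution_percent(norm)
        assert pct.sum() == pytest.approx(100.0, abs=1e-6)
        assert (pct >= 0).all()

    def test_equal_columns_give_equal_percent(self, catalog):
        from soilpah.pmf import NormalizedModel

        f = np.full((2, 16), 1 / 16)
        S = np.full((5, 2), 3.0)
        norm = NormalizedModel(S=S, f=f, catalog=catalog)
        np.testing.assert_allclose(source_contribution_percent(norm), [50.0, 50.0])


class TestFactorScan:
    def test_recommends_true_factor_count(self, four_source_dataset):
        X, _ = four_source_dataset
        unc = build_uncertainty(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scan = scan_factors(X, unc, p_min=3, p_max=8, n_starts=10, seed=0)
        assert scan.recommended_p == 4
        assert scan.models[4].r_squared >= 0.91

    def test_r_squared_non_decreasing_in_p(self, four_source_dataset):
        X, _ = four_source_dataset
        unc = build_uncertainty(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scan = scan_factors(X, unc, p_min=3, p_max=6, n_starts=10, seed=0)
        r2 = scan.table["r_squared"].to_numpy()
        assert (np.diff(r2) >= -0.01).all()

    def test_p_max_validated(self, four_source_dataset):
        X, _ = four_source_dataset
        unc = build_uncertainty(X)
        with pytest.raises(ValueError):
            scan_factors(X, unc, p_min=3, p_max=17)
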