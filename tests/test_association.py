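"""Eigengenes and LASSO module selection."""

from __future__ import annotations

import numpy as np
import pytest

from overlapnet.association import (
    EigengeneMatrix,
    cv_select_lambda,
    eigengene,
    eigengene_matrix,
    fit_lasso,
    lambda_max,
    select_modules,
)
from overlapnet.data import LfcMatrix
from overlapnet.hlc import AffiliationMatrix


def _lfc(values) -> LfcMatrix:
    values = np.asarray(values, dtype=float)
    return LfcMatrix(
        gene_ids=[f"g{i}" for i in range(values.shape[0])],
        genotype_ids=[f"a{j}" for j in range(values.shape[1])],
        values=values,
    )


def _aff(module_genes: dict[str, list[str]], gene_ids: list[str]) -> AffiliationMatrix:
    values = np.zeros((len(gene_ids), len(module_genes)), dtype=np.int8)
    pos = {g: i for i, g in enumerate(gene_ids)}
    for k, genes in enumerate(module_genes.values()):
        for g in genes:
            values[pos[g], k] = 1
    return AffiliationMatrix(
        gene_ids=gene_ids,
        module_ids=list(module_genes),
        values=values,
        module_genes=module_genes,
    )


class TestEigengene:
    def test_identical_rows_give_standardized_profile(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0])
        l1 = _lfc([profile, profile * 2 + 1, profile * 0.5 - 3])
        v = eigengene(l1, ["g0", "g1", "g2"])
        z = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(v, z / np.linalg.norm(z), atol=1e-10)

    def test_antisymmetric_pair_uses_first_gene_sign(self):
        row = np.array([1.0, -2.0, 0.5, 3.0])
        l1 = _lfc([row, -row])
        v = eigengene(l1, ["g0", "g1"])
        z0 = (row - row.mean()) / row.std()
        assert float(z0 @ v) > 0  # sign fixed against the first gene's row
        # rank-1: the profile is exactly ± the standardized row
        np.testing.assert_allclose(np.abs(v), np.abs(z0) / np.linalg.norm(z0), atol=1e-10)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(0)
        l1 = _lfc(rng.standard_normal((6, 8)))
        genes = [f"g{i}" for i in range(6)]
        v1 = eigengene(l1, genes)
        v2 = eigengene(l1, genes[::-1])
        np.testing.assert_allclose(v1, v2, atol=1e-10)

    def test_zero_variance_gene_rejected(self):
        l1 = _lfc([[1, 1, 1], [1, 2, 3]])
        with pytest.raises(ValueError, match="g0"):
            eigengene(l1, ["g0", "g1"])

    def test_matrix_shape_and_overlap_semantics(self):
        rng = np.random.default_rng(1)
        l1 = _lfc(rng.standard_normal((5, 7)))
        f = _aff({"M1": ["g0", "g1", "g2"], "M2": ["g2", "g3", "g4"]}, [f"g{i}" for i in range(5)])
        m = eigengene_matrix(l1, f)
        assert m.values.shape == (7, 2)
        assert m.module_ids == ["M1", "M2"]
        # overlapping gene g2 contributes to both columns
        np.testing.assert_allclose(
            m.values[:, 0], eigengene(l1, ["g0", "g1", "g2"]), atol=1e-12
        )
        np.testing.assert_allclose(
            m.values[:, 1], eigengene(l1, ["g2", "g3", "g4"]), atol=1e-12
        )


def _orthonormal_design(rng, m=24, c=6):
    """Columns orthonormal after internal standardization: build from a QR
    of centered noise, then rescale so standardization reproduces them."""
    q, _ = np.linalg.qr(rng.standard_normal((m, c + 1)))
    q = q[:, 1:]  # drop the near-constant direction
    q = q - q.mean(axis=0)
    q = q / q.std(axis=0)
    return q


class TestFitLasso:
    def test_lambda_at_or_above_lambda_max_gives_all_zero(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        lam = lambda_max(x, y)
        assert np.all(fit_lasso(x, y, lam) == 0.0)
        assert np.all(fit_lasso(x, y, lam * 1.5) == 0.0)
        # just below lambda_max at least one coefficient activates
        assert np.any(fit_lasso(x, y, lam * 0.99) != 0.0)

    def test_orthonormal_lambda_zero_is_ols(self):
        rng = np.random.default_rng(3)
        q = _orthonormal_design(rng)
        xs = q / np.sqrt(q.shape[0])  # unit-norm columns
        y = rng.standard_normal(q.shape[0])
        y = y - y.mean()
        alpha = fit_lasso(q, y, 0.0)
        # fit_lasso standardizes internally: columns of q already standardized
        beta_ols = np.linalg.lstsq(q, y, rcond=None)[0]
        np.testing.assert_allclose(alpha, beta_ols, atol=1e-8)

    def test_orthonormal_soft_threshold_closed_form(self):
        """With orthonormal (in the x'x = I sense) predictors the minimizer of
        ||y - Xa||^2 + lam*||a||_1 is soft thresholding of x_j'y at lam/2."""
        rng = np.random.default_rng(4)
        m = 24
        q, _ = np.linalg.qr(rng.standard_normal((m, 6)))  # q'q = I
        y = rng.standard_normal(m)
        for lam in (0.1, 0.5, 1.2):
            from overlapnet.association import coordinate_descent

            alpha = coordinate_descent(q, y, lam)
            beta = q.T @ y
            expected = np.sign(beta) * np.maximum(np.abs(beta) - lam / 2, 0.0)
            np.testing.assert_allclose(alpha, expected, atol=1e-8)

    def test_kkt_conditions_random_problems(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            m, c = int(rng.integers(10, 40)), int(rng.integers(2, 12))
            x = rng.standard_normal((m, c))
            y = rng.standard_normal(m)
            lam = float(rng.uniform(0.05, 2.0) * lambda_max(x, y))
            alpha = fit_lasso(x, y, lam)
            xs = (x - x.mean(0)) / x.std(0)
            grad = xs.T @ ((y - y.mean()) - xs @ alpha)
            inactive = alpha == 0
            assert np.all(np.abs(grad[inactive]) <= lam / 2 + 1e-6)
            active = ~inactive
            if active.any():
                np.testing.assert_allclose(
                    grad[active], lam / 2 * np.sign(alpha[active]), atol=1e-6
                )

    def test_agrees_with_sklearn_lasso(self):
        """Independent cross-check: sklearn minimizes (1/2m)||y-Xa||^2 +
        alpha*||a||_1, i.e. our objective at lam = 2m*alpha."""
        sklearn_linear = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(6)
        m, c = 30, 8
        x = rng.standard_normal((m, c))
        y = x[:, 0] - 2 * x[:, 3] + 0.1 * rng.standard_normal(m)
        xs = (x - x.mean(0)) / x.std(0)
        yc = y - y.mean()
        for sk_alpha in (0.01, 0.1, 0.5):
            model = sklearn_linear.Lasso(alpha=sk_alpha, fit_intercept=False, tol=1e-12, max_iter=100000)
            model.fit(xs, yc)
            ours = fit_lasso(x, y, lam=2 * m * sk_alpha)
            np.testing.assert_allclose(ours, model.coef_, atol=1e-6)


class TestCvSelectLambda:
    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((30, 6))
        y = rng.standard_normal(30)
        f1 = cv_select_lambda(x, y, k_folds=5, seed=42)
        f2 = cv_select_lambda(x, y, k_folds=5, seed=42)
        assert f1.chosen_lambda == f2.chosen_lambda
        np.testing.assert_array_equal(f1.coefficients, f2.coefficients)

    def test_noiseless_two_column_signal_recovered(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((40, 8))
        y = 2.0 * x[:, 1] - 1.5 * x[:, 5]
        fit = cv_select_lambda(x, y, k_folds=10, seed=0, module_ids=[f"M{j}" for j in range(8)])
        active = {j for j, a in enumerate(fit.coefficients) if a != 0}
        assert {1, 5} <= active

    def test_pure_noise_keeps_model_small(self):
        """On pure-noise responses the lambda-min rule should usually select
        (near-)maximal shrinkage: few active modules, lambda high on the grid."""
        rng = np.random.default_rng(9)
        small = 0
        for rep in range(20):
            x = rng.standard_normal((30, 10))
            y = rng.standard_normal(30)
            fit = cv_select_lambda(x, y, k_folds=5, seed=rep)
            if (fit.coefficients != 0).sum() <= 2:
                small += 1
        assert small >= 14  # majority behavior

    def test_active_set_monotone_along_path_on_average(self):
        """The number of active coefficients grows (weakly) as lambda falls
        along the fitted path."""
        rng = np.random.default_rng(10)
        x = rng.standard_normal((40, 6))
        y = x[:, 0] + 0.5 * rng.standard_normal(40)
        from overlapnet.association import _standardize, coordinate_descent, lambda_grid

        xs, yc, _ = _standardize(x, y)
        lam_hi = lambda_max(x, y)
        sizes = []
        alpha = np.zeros(6)
        for lam in lambda_grid(lam_hi, n_lambda=30):
            alpha = coordinate_descent(xs, yc, lam, alpha0=alpha)
            sizes.append(int((alpha != 0).sum()))
        assert sizes[0] == 0
        assert sizes == sorted(sizes)

    def test_m_smaller_than_folds_rejected(self):
        rng = np.random.default_rng(11)
        with pytest.raises(ValueError, match="k_folds"):
            cv_select_lambda(rng.standard_normal((5, 3)), rng.standard_normal(5), k_folds=10)


class TestSelectModules:
    def _fits(self, coefs_by_trait, module_ids):
        from overlapnet.association import LassoFit

        fits = []
        for trait, coefs in coefs_by_trait.items():
            fits.append(
                LassoFit(
                    trait_name=trait,
                    lambda_grid=np.array([1.0]),
                    cv_mse_mean=np.array([0.0]),
                    cv_mse_se=np.array([0.0]),
                    chosen_lambda=1.0,
                    coefficients=np.asarray(coefs, dtype=float),
                    intercept=0.0,
                    module_ids=module_ids,
                    fold_seed=0,
                )
            )
        return fits

    def test_all_zero_fits_give_empty_selection(self):
        f = _aff({"M1": ["g1", "g2", "g3"]}, ["g1", "g2", "g3"])
        sel = select_modules(self._fits({"t1": [0.0]}, ["M1"]), f)
        assert sel.selected_genes == []

    def test_single_module_single_trait_attribution(self):
        f = _aff({"M1": ["g1", "g2", "g3"], "M2": ["g4", "g5", "g6"]}, [f"g{i}" for i in range(1, 7)])
        sel = select_modules(self._fits({"t1": [0.7, 0.0], "t2": [0.0, 0.0]}, ["M1", "M2"]), f)
        assert sel.selected_genes == ["g1", "g2", "g3"]
        assert sel.gene_traits["g1"] == ["t1"]

    def test_module_shared_by_two_traits_listed_once(self):
        f = _aff({"M1": ["g1", "g2", "g3"]}, ["g1", "g2", "g3"])
        sel = select_modules(
            self._fits({"t1": [0.5], "t2": [-0.3]}, ["M1"]), f
        )
        assert sel.selected_genes == ["g1", "g2", "g3"]
        assert sel.gene_traits["g2"] == ["t1", "t2"]
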