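import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import evdeconv as ev
from evdeconv.deconvolution import SolverOptions, solve
from evdeconv.io import ValidationError

from conftest import make_pair


def _orthonormal_pair(n=40, p=3, rng_seed=0):
    rng = np.random.default_rng(rng_seed)
    q, _ = np.linalg.qr(rng.normal(size=(n, p)))
    return q


class TestMatchAndNormalize:
    def test_output_is_zero_mean_unit_variance(self, blood_signature):
        rng = np.random.default_rng(0)
        mixture = pd.Series(
            rng.lognormal(2, 1, len(blood_signature.gene_ids)), index=blood_signature.gene_ids
        )
        pair = ev.match_and_normalize(mixture, blood_signature)
        assert abs(pair.mixture.mean()) < 1e-9
        assert pair.mixture.std() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(pair.basis.mean(axis=0), 0, atol=1e-9)

    def test_standardization_idempotent_on_prestandardized(self, blood_signature):
        rng = np.random.default_rng(1)
        y = rng.normal(size=len(blood_signature.gene_ids))
        y = (y - y.mean()) / y.std()
        # shift to nonnegative TPM-like values then back: z-scoring is invariant to affine maps
        mixture = pd.Series(10 + 2 * y, index=blood_signature.gene_ids)
        pair = ev.match_and_normalize(mixture, blood_signature)
        np.testing.assert_allclose(pair.mixture, y, atol=1e-9)

    def test_constant_mixture_rejected(self, blood_signature):
        mixture = pd.Series(3.0, index=blood_signature.gene_ids)
        with pytest.raises(ValidationError, match="constant"):
            ev.match_and_normalize(mixture, blood_signature)

    def test_matched_fraction_reported(self, blood_signature):
        genes = blood_signature.gene_ids
        keep = genes[: len(genes) - 20]
        rng = np.random.default_rng(2)
        mixture = pd.Series(rng.lognormal(2, 1, len(keep)), index=keep)
        pair = ev.match_and_normalize(mixture, blood_signature)
        assert pair.matched_fraction == pytest.approx((len(genes) - 20) / len(genes))

    def test_too_few_matched_genes_errors_with_count(self, blood_signature):
        mixture = pd.Series([1.0, 2.0, 3.0], index=blood_signature.gene_ids[:3])
        with pytest.raises(ValidationError, match="3"):
            ev.match_and_normalize(mixture, blood_signature)


class TestNuSvr:
    def test_recovers_two_component_mixture(self):
        q = _orthonormal_pair(60, 2)
        basis = q * 100
        mixture = 0.6 * basis[:, 0] + 0.4 * basis[:, 1]
        pair = make_pair(basis, mixture)
        coef, nu, trace = ev.solve_nu_svr(pair)
        rel, _ = ev.to_relative(coef)
        np.testing.assert_allclose(rel, [0.6, 0.4], atol=0.02)

    def test_single_column_mixture_dominates(self, blood_signature):
        mixture = blood_signature.data.iloc[:, 0]
        res = ev.deconvolve_sample(mixture, blood_signature, SolverOptions(method="svr"))
        assert res.relative_fractions[0] >= 0.95

    def test_chosen_nu_is_argmin_of_trace(self):
        rng = np.random.default_rng(4)
        basis = rng.normal(size=(50, 3))
        mixture = basis @ [0.5, 0.3, 0.2] + rng.normal(0, 0.1, 50)
        coef, nu, trace = ev.solve_nu_svr(make_pair(basis, mixture))
        valid = trace.dropna()
        assert nu == valid.loc[valid["rmse"].idxmin(), "nu"]


class TestNnls:
    def test_orthonormal_exact(self):
        q = _orthonormal_pair()
        mixture = 0.3 * q[:, 0] + 0.7 * q[:, 1]
        coef = ev.solve_nnls(make_pair(q, mixture))
        np.testing.assert_allclose(coef, [0.3, 0.7, 0.0], atol=1e-10)

    def test_negative_mixture_pins_to_zero(self):
        q = _orthonormal_pair(30, 1)
        coef = ev.solve_nnls(make_pair(q, -q[:, 0]))
        np.testing.assert_allclose(coef, [0.0], atol=1e-12)

    def test_matches_grid_search_oracle_two_subsets(self):
        rng = np.random.default_rng(5)
        basis = rng.normal(size=(25, 2))
        mixture = basis @ [0.42, 0.17] + rng.normal(0, 0.05, 25)
        pair = make_pair(basis, mixture)
        coef = ev.solve_nnls(pair)
        # brute force over a 0.001-step nonnegative grid
        grid = np.arange(0, 1.0001, 0.001)
        best, best_sse = None, np.inf
        for a in grid:
            resid = pair.mixture - a * pair.basis[:, 0]
            b = max(0.0, float(pair.basis[:, 1] @ resid / (pair.basis[:, 1] @ pair.basis[:, 1])))
            sse = float(np.sum((pair.mixture - a * pair.basis[:, 0] - b * pair.basis[:, 1]) ** 2))
            if sse < best_sse:
                best, best_sse = (a, b), sse
        np.testing.assert_allclose(coef, best, atol=1e-3)


class TestQp:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_nonneg_matches_nnls(self, seed):
        rng = np.random.default_rng(seed)
        basis = rng.normal(size=(30, 4))
        mixture = basis @ rng.uniform(0, 1, 4) + rng.normal(0, 0.2, 30)
        pair = make_pair(basis, mixture)
        np.testing.assert_allclose(ev.solve_qp(pair, "nonneg"), ev.solve_nnls(pair), atol=1e-6)

    def test_sum_to_one_feasible_optimum(self):
        q = _orthonormal_pair(40, 2)
        mixture = 0.5 * q[:, 0] + 0.5 * q[:, 1]
        coef = ev.solve_qp(make_pair(q, mixture), "nonneg-sum-to-one")
        np.testing.assert_allclose(coef, [0.5, 0.5], atol=1e-6)

    def test_sum_to_one_constraint_holds(self):
        rng = np.random.default_rng(6)
        basis = rng.normal(size=(30, 3))
        mixture = rng.normal(size=30)
        coef = ev.solve_qp(make_pair(basis, mixture), "nonneg-sum-to-one")
        assert coef.sum() == pytest.approx(1.0, abs=1e-8)
        assert (coef >= -1e-12).all()


class TestOls:
    def test_normal_equations_satisfied(self):
        rng = np.random.default_rng(7)
        basis = rng.normal(size=(20, 4))
        mixture = rng.normal(size=20)
        pair = make_pair(basis, mixture)
        coef = ev.solve_ols(pair)
        np.testing.assert_allclose(basis.T @ (basis @ coef - pair.mixture), 0, atol=1e-8)

    def test_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            basis = rng.normal(size=(20, 4))
            mixture = rng.normal(size=20)
            pair = make_pair(basis, mixture)
            np.testing.assert_allclose(
                ev.solve_ols(pair), np.linalg.pinv(basis) @ pair.mixture, atol=1e-8
            )

    def test_noiseless_reconstruction_is_exact(self):
        rng = np.random.default_rng(9)
        basis = rng.normal(size=(25, 3))
        mixture = basis @ [1.0, -2.0, 0.5]
        pair = make_pair(basis, mixture)
        coef = ev.solve_ols(pair)
        _, rmse = ev.reconstruction_fit(pair, coef)
        assert rmse <= 1e-8


class TestRlr:
    def test_zero_noise_equals_ols(self):
        rng = np.random.default_rng(10)
        basis = rng.normal(size=(40, 3))
        mixture = basis @ [0.2, 0.5, 0.3]
        pair = make_pair(basis, mixture)
        np.testing.assert_allclose(ev.solve_rlr(pair), ev.solve_ols(pair), atol=1e-6)

    def test_outlier_resistance_beats_ols(self):
        rng = np.random.default_rng(11)
        truth = np.array([0.6, 0.4, 0.0])
        basis = rng.normal(size=(100, 3))
        mixture = basis @ truth + rng.normal(0, 0.05, 100)
        outliers = rng.choice(100, size=10, replace=False)
        mixture[outliers] += rng.choice([-8, 8], size=10)
        pair = make_pair(basis, mixture)
        err_rlr = np.abs(ev.solve_rlr(pair) - truth).max()
        err_ols = np.abs(ev.solve_ols(pair) - truth).max()
        assert err_rlr < err_ols

    def test_gaussian_noise_close_to_ols(self):
        rng = np.random.default_rng(12)
        basis = rng.normal(size=(200, 3))
        mixture = basis @ [0.3, 0.3, 0.4] + rng.normal(0, 0.1, 200)
        pair = make_pair(basis, mixture)
        se = 0.1 / np.sqrt(200)  # order of the coefficient standard error
        assert np.abs(ev.solve_rlr(pair) - ev.solve_ols(pair)).max() < 2 * se * 5


class TestRidge:
    def test_lambda_zero_equals_ols(self):
        rng = np.random.default_rng(13)
        basis = rng.normal(size=(30, 4))
        mixture = rng.normal(size=30)
        pair = make_pair(basis, mixture)
        coef, lam = ev.solve_ridge(pair, ridge_lambda=0.0)
        assert lam == 0.0
        np.testing.assert_allclose(coef, ev.solve_ols(pair), atol=1e-8)

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(14)
        basis = rng.normal(size=(25, 3))
        mixture = rng.normal(size=25)
        pair = make_pair(basis, mixture)
        for lam in (0.1, 1.0, 10.0):
            coef, _ = ev.solve_ridge(pair, ridge_lambda=lam)
            oracle = np.linalg.solve(basis.T @ basis + lam * np.eye(3), basis.T @ pair.mixture)
            np.testing.assert_allclose(coef, oracle, atol=1e-8)

    def test_shrinkage_monotone_in_lambda(self):
        rng = np.random.default_rng(15)
        basis = rng.normal(size=(30, 3))
        mixture = basis @ [1.0, 2.0, -1.0] + rng.normal(0, 0.1, 30)
        pair = make_pair(basis, mixture)
        norms = [
            np.linalg.norm(ev.solve_ridge(pair, ridge_lambda=lam)[0])
            for lam in (0.0, 1.0, 100.0, 1e5)
        ]
        assert norms == sorted(norms, reverse=True)

    def test_negative_lambda_rejected(self):
        basis = np.eye(3)
        pair = make_pair(basis, np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            ev.solve_ridge(pair, ridge_lambda=-1.0)


class TestPostProcessing:
    @pytest.mark.parametrize(
        "raw,expected,degenerate",
        [
            ((2.0, -1.0, 3.0), (0.4, 0.0, 0.6), False),
            ((0.25, 0.75), (0.25, 0.75), False),
            ((-1.0, -2.0), (0.0, 0.0), True),
        ],
    )
    def test_to_relative(self, raw, expected, degenerate):
        rel, flag = ev.to_relative(np.array(raw))
        np.testing.assert_allclose(rel, expected)
        assert flag is degenerate

    def test_to_absolute_truncates_and_scales(self):
        np.testing.assert_allclose(ev.to_absolute(np.array([2.0, -1.0, 3.0])), [2.0, 0.0, 3.0])
        raw = np.array([0.5, 1.5])
        rel1, _ = ev.to_relative(raw)
        rel2, _ = ev.to_relative(2 * raw)
        np.testing.assert_allclose(ev.to_absolute(2 * raw), 2 * ev.to_absolute(raw))
        np.testing.assert_allclose(rel1, rel2)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        raw=st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=1, max_size=12
        )
    )
    def test_relative_fractions_are_simplex_or_degenerate(self, raw):
        rel, degenerate = ev.to_relative(np.array(raw))
        assert (rel >= 0).all()
        if degenerate:
            assert rel.sum() == 0
        else:
            assert rel.sum() == pytest.approx(1.0, abs=1e-8)


class TestReconstructionFit:
    def test_identical_reconstruction(self):
        rng = np.random.default_rng(16)
        q = _orthonormal_pair(20, 2)
        mixture = q @ [1.0, 2.0]
        pair = make_pair(q, mixture)
        pcc, rmse = ev.reconstruction_fit(pair, np.array([1.0, 2.0]))
        assert pcc == pytest.approx(1.0)
        assert rmse == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_keeps_pcc_one(self):
        basis = np.array([[1.0], [2.0], [3.0], [4.0]])
        offset = 2.5
        pair = make_pair(basis, basis[:, 0] - offset)
        # reconstruction = basis * 1 = mixture + offset
        pcc, rmse = ev.reconstruction_fit(pair, np.array([1.0]))
        assert pcc == pytest.approx(1.0)
        assert rmse == pytest.approx(offset, rel=1e-9)

    def test_anticorrelated_reconstruction(self):
        q = _orthonormal_pair(20, 1)
        pair = make_pair(q, q[:, 0])
        pcc, _ = ev.reconstruction_fit(pair, np.array([-1.0]))
        assert pcc == pytest.approx(-1.0)

    def test_pcc_invariant_to_affine_mixture_rescaling(self, blood_signature):
        rng = np.random.default_rng(17)
        mixture = pd.Series(
            rng.lognormal(2, 1, len(blood_signature.gene_ids)), index=blood_signature.gene_ids
        )
        r1 = ev.deconvolve_sample(mixture, blood_signature, SolverOptions(method="nnls"))
        r2 = ev.deconvolve_sample(3.7 * mixture, blood_signature, SolverOptions(method="nnls"))
        assert r1.pcc == pytest.approx(r2.pcc, abs=1e-9)


class TestDeconvolve:
    def test_cohort_contract_and_determinism(self, blood_signature, tmp_path):
        spec = ev.GeneratorSpec(noise_sigma=0.1, unmodeled_fraction=0.1, n_background_genes=200)
        cohort, _ = ev.generate_cohort(blood_signature, 10, spec, np.random.default_rng(20))
        outs = []
        for run in (1, 2):
            results, failures = ev.deconvolve(cohort, blood_signature, SolverOptions(method="nnls"))
            assert not failures
            assert len(results) == 10
            for res in results:
                assert res.degenerate or res.relative_fractions.sum() == pytest.approx(1, abs=1e-8)
                assert (res.relative_fractions >= 0).all()
            path = tmp_path / f"run{run}.tsv"
            ev.write_results(results, path)
            outs.append(path.read_bytes())
        assert outs[0] == outs[1]

    @pytest.mark.parametrize("method", ["nnls", "qp", "ols", "svr", "rlr", "ridge"])
    def test_noiseless_recovery_all_solvers(self, blood_signature, method):
        spec = ev.GeneratorSpec(noise_sigma=0.0, unmodeled_fraction=0.0, n_background_genes=0)
        cohort, truth = ev.generate_cohort(blood_signature, 2, spec, np.random.default_rng(21))
        tol = 0.02 if method == "svr" else 1e-6
        for sample_id in cohort.sample_ids:
            res = ev.deconvolve_sample(
                cohort.sample(sample_id), blood_signature, SolverOptions(method=method)
            )
            np.testing.assert_allclose(
                res.relative_fractions, truth.loc[sample_id].to_numpy(), atol=tol
            )
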