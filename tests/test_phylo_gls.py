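import dendropy
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import linalg

from plumadrum.phylo_gls import (
    collinearity_screen,
    gls_fit,
    lambda_transform,
    mass_correct,
    pgls_ml,
    phylo_covariance,
    read_newick,
    transform_variables,
)
from plumadrum.synthetic_data import simulate_tree


def tree_from_string(s):
    return dendropy.Tree.get(data=s, schema="newick")


class TestPhyloCovariance:
    def test_two_tip_star(self):
        tree = tree_from_string("(A:1,B:1);")
        c = phylo_covariance(tree, ["A", "B"])
        assert np.allclose(c, np.eye(2))

    def test_three_tip_example(self):
        tree = tree_from_string("((A:1,B:1):1,C:2);")
        c = phylo_covariance(tree, ["A", "B", "C"])
        assert np.allclose(np.diag(c), 2.0)
        assert c[0, 1] == pytest.approx(1.0)
        assert c[0, 2] == pytest.approx(0.0)

    def test_positive_semidefinite_random_tree(self):
        tree = simulate_tree(25, seed=42)
        names = [l.taxon.label for l in tree.leaf_node_iter()]
        c = phylo_covariance(tree, names)
        eig = np.linalg.eigvalsh(c)
        assert eig.min() >= -1e-10

    def test_missing_species_listed(self):
        tree = tree_from_string("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError, match="Zzz"):
            phylo_covariance(tree, ["A", "Zzz"])

    def test_pruning_extra_tips(self):
        tree = tree_from_string("((A:1,B:1):1,(C:1.5,D:0.5):0.5);")
        c = phylo_covariance(tree, ["A", "C"])
        assert c.shape == (2, 2)
        assert c[0, 1] == pytest.approx(0.0)

    def test_name_normalization(self):
        tree = tree_from_string("((Picus_viridis:1,B:1):1,C:2);")
        c = phylo_covariance(tree, ["picus viridis", "B", "C"])
        assert c.shape == (3, 3)

    def test_newick_roundtrip(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A:1,B:1):1,C:2);\n")
        tree = read_newick(path)
        assert len(tree.leaf_nodes()) == 3


class TestLambdaTransform:
    def test_lambda_one_unchanged(self):
        c = np.array([[2.0, 1.0], [1.0, 2.0]])
        assert np.allclose(lambda_transform(c, 1.0), c)

    def test_lambda_zero_star(self):
        c = np.array([[2.0, 1.0], [1.0, 2.0]])
        assert np.allclose(lambda_transform(c, 0.0), np.diag([2.0, 2.0]))

    def test_half(self):
        c = np.array([[2.0, 1.0], [1.0, 2.0]])
        assert np.allclose(
            lambda_transform(c, 0.5), [[2.0, 0.5], [0.5, 2.0]]
        )

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_out_of_range(self, bad):
        with pytest.raises(ValueError):
            lambda_transform(np.eye(2), bad)


class TestGlsFit:
    def test_identity_covariance_reduces_to_ols(self):
        rng = np.random.default_rng(0)
        x = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
        y = rng.normal(size=30)
        fit = gls_fit(x, y, np.eye(30))
        ols = sm.OLS(y, x).fit()
        assert np.allclose(fit.beta, ols.params, atol=1e-12)
        assert np.allclose(fit.se, ols.bse, atol=1e-12)
        assert np.allclose(fit.pvalues, ols.pvalues, atol=1e-12)

    def test_hand_algebra_intercept_only(self):
        fit = gls_fit(np.ones((3, 1)), np.array([1.0, 2.0, 3.0]), np.eye(3))
        assert fit.beta[0] == pytest.approx(2.0)
        assert fit.sigma2_ml == pytest.approx(2.0 / 3.0)

    def test_four_taxon_explicit_arithmetic_oracle(self):
        c = np.array(
            [
                [1.0, 0.6, 0.2, 0.2],
                [0.6, 1.0, 0.2, 0.2],
                [0.2, 0.2, 1.0, 0.7],
                [0.2, 0.2, 0.7, 1.0],
            ]
        )
        x = np.array([[1, 0.5], [1, -0.3], [1, 1.2], [1, 0.1]])
        y = np.array([0.2, -0.1, 1.0, 0.3])
        vinv = np.linalg.inv(c)
        beta_expected = np.linalg.solve(x.T @ vinv @ x, x.T @ vinv @ y)
        fit = gls_fit(x, y, c)
        assert np.allclose(fit.beta, beta_expected, atol=1e-12)
        e = y - x @ beta_expected
        assert fit.sigma2_ml == pytest.approx(e @ vinv @ e / 4, abs=1e-12)

    def test_cholesky_whitened_ols_oracle(self):
        rng = np.random.default_rng(1)
        tree = simulate_tree(10, seed=5)
        names = [l.taxon.label for l in tree.leaf_node_iter()]
        c = phylo_covariance(tree, names)
        for lam in (0.0, 0.3, 1.0):
            v = lambda_transform(c, lam)
            x = np.column_stack([np.ones(10), rng.normal(size=(10, 2))])
            y = rng.normal(size=10)
            l_chol = np.linalg.cholesky(v)
            xw = linalg.solve_triangular(l_chol, x, lower=True)
            yw = linalg.solve_triangular(l_chol, y, lower=True)
            ols = sm.OLS(yw, xw).fit()
            fit = gls_fit(x, y, v)
            assert np.allclose(fit.beta, ols.params, atol=1e-8)
            assert np.allclose(fit.se, ols.bse, atol=1e-8)

    def test_singular_design_raises(self):
        x = np.ones((5, 2))
        with pytest.raises(ValueError):
            gls_fit(x, np.arange(5.0), np.eye(5))


class TestPglsMl:
    def test_structural_degrees_of_freedom(self):
        # 132 species, 5 predictors + intercept -> 5 and 126 d.f.
        tree = simulate_tree(132, seed=2)
        names = [l.taxon.label for l in tree.leaf_node_iter()]
        c = phylo_covariance(tree, names)
        rng = np.random.default_rng(3)
        x = np.column_stack([np.ones(132), rng.normal(size=(132, 5))])
        fit = pgls_ml(x, rng.normal(size=132), c)
        assert fit.df == (5, 126)

    def test_fixed_lambda_respected(self):
        tree = simulate_tree(12, seed=4)
        names = [l.taxon.label for l in tree.leaf_node_iter()]
        c = phylo_covariance(tree, names)
        rng = np.random.default_rng(5)
        x = np.column_stack([np.ones(12), rng.normal(size=12)])
        fit = pgls_ml(x, rng.normal(size=12), c, lam=0.4)
        assert fit.lam == 0.4

    @pytest.mark.parametrize("lam_true,bound", [(0.0, 0.15), (1.0, 0.85)])
    def test_lambda_recovery_endpoints(self, lam_true, bound):
        tree = simulate_tree(100, seed=6)
        names = [l.taxon.label for l in tree.leaf_node_iter()]
        c = phylo_covariance(tree, names)
        l_chol = np.linalg.cholesky(
            lambda_transform(c, lam_true) + 1e-12 * np.eye(100)
        )
        rng = np.random.default_rng(7)
        x = np.ones((100, 1))
        lams = []
        for _ in range(20):
            y = l_chol @ rng.standard_normal(100)
            lams.append(pgls_ml(x, y, c).lam)
        mean = np.mean(lams)
        if lam_true == 0.0:
            assert mean < bound
        else:
            assert mean > bound

    def test_ignoring_phylogeny_inflates_type_one_error(self):
        # forcing lambda = 0 on lambda = 1 data rejects far above nominal
        tree = simulate_tree(60, seed=8)
        names = [l.taxon.label for l in tree.leaf_node_iter()]
        c = phylo_covariance(tree, names)
        l_chol = np.linalg.cholesky(c + 1e-12 * np.eye(60))
        rng = np.random.default_rng(9)
        rej_star, rej_phylo = 0, 0
        reps = 200
        for _ in range(reps):
            x = np.column_stack([np.ones(60), l_chol @ rng.standard_normal(60)])
            y = l_chol @ rng.standard_normal(60)
            rej_star += pgls_ml(x, y, c, lam=0.0).pvalues[1] < 0.05
            rej_phylo += pgls_ml(x, y, c, lam=1.0).pvalues[1] < 0.05
        assert rej_star / reps > 0.10  # clearly above nominal 5%
        assert rej_star > rej_phylo

    def test_model_f_against_intercept_only(self):
        # with V = I the F statistic must match the OLS overall F
        rng = np.random.default_rng(10)
        x = np.column_stack([np.ones(40), rng.normal(size=(40, 3))])
        y = x @ np.array([1.0, 0.5, 0.0, -0.2]) + rng.normal(size=40)
        fit = pgls_ml(x, y, np.eye(40), lam=1.0)  # C=I: lambda irrelevant
        ols = sm.OLS(y, x).fit()
        assert fit.fstat == pytest.approx(ols.fvalue, rel=1e-10)
        assert fit.model_pvalue == pytest.approx(ols.f_pvalue, rel=1e-8)


class TestMassCorrect:
    def test_exactly_linear_gives_zero_residuals(self):
        mass = np.linspace(1, 2, 10)
        speed = 3.0 - 0.5 * mass
        assert np.allclose(mass_correct(speed, mass), 0.0, atol=1e-12)

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(11)
        mass = rng.normal(1.5, 0.3, 50)
        speed = 1.0 - 0.3 * mass + rng.normal(0, 0.1, 50)
        assert mass_correct(speed, mass).sum() == pytest.approx(0.0, abs=1e-9)

    def test_slope_recovered(self):
        rng = np.random.default_rng(12)
        mass = rng.normal(1.5, 0.3, 2000)
        speed = 1.0 + 0.7 * mass + rng.normal(0, 0.05, 2000)
        resid = mass_correct(speed, mass)
        # residuals uncorrelated with mass -> slope was absorbed
        assert abs(np.corrcoef(resid, mass)[0, 1]) < 1e-10

    def test_zero_mass_variance_raises(self):
        with pytest.raises(ValueError):
            mass_correct(np.arange(5.0), np.ones(5))

    def test_phylogenetic_variant_identity_covariance_matches_ols(self):
        rng = np.random.default_rng(16)
        mass = rng.normal(1.5, 0.3, 20)
        speed = 1.0 - 0.3 * mass + rng.normal(0, 0.1, 20)
        ols = mass_correct(speed, mass)
        gls = mass_correct(speed, mass, covariance=np.eye(20))
        assert np.allclose(ols, gls, atol=1e-10)

    def test_phylogenetic_variant_differs_under_structure(self):
        tree = simulate_tree(20, seed=17)
        names = [l.taxon.label for l in tree.leaf_node_iter()]
        c = phylo_covariance(tree, names)
        rng = np.random.default_rng(18)
        mass = rng.normal(1.5, 0.3, 20)
        speed = 1.0 - 0.3 * mass + np.linalg.cholesky(c) @ rng.normal(size=20)
        assert not np.allclose(
            mass_correct(speed, mass), mass_correct(speed, mass, covariance=c)
        )


class TestCollinearityScreen:
    def test_duplicated_column_flagged(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        corr, flags = collinearity_screen(df)
        assert flags and flags[0][:2] == ("a", "b")
        assert flags[0][2] == pytest.approx(1.0)

    def test_independent_predictors_unflagged(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("abcd"))
        _, flags = collinearity_screen(df)
        assert flags == []

    def test_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        corr, _ = collinearity_screen(df)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)


class TestTransformVariables:
    def test_log10_of_100(self):
        df = pd.DataFrame({"x": [100.0, 10.0]})
        out, applied = transform_variables(df)
        assert out["x"].tolist() == [2.0, 1.0]
        assert applied == {}

    def test_zero_column_gets_offset(self):
        df = pd.DataFrame({"x": [0.0, 0.0]})
        out, applied = transform_variables(df, offset=0.01)
        assert np.allclose(out["x"], -2.0)
        assert applied == {"x": 0.01}

    def test_monotonicity_preserved(self):
        rng = np.random.default_rng(15)
        x = np.sort(rng.uniform(0, 10, 30))
        out, _ = transform_variables(pd.DataFrame({"x": x}))
        assert (np.diff(out["x"]) >= 0).all()

    def test_habitat_dummy_coding(self):
        df = pd.DataFrame({"habitat": ["closed", "open", "Closed"]})
        out, _ = transform_variables(df)
        assert out["habitat"].tolist() == [0, 1, 0]

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            transform_variables(pd.DataFrame({"x": [-1.0, 2.0]}))

    def test_bad_habitat_level_raises(self):
        with pytest.raises(ValueError):
            transform_variables(pd.DataFrame({"habitat": ["forest"]}))
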