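"""The ordination engine: explained fractions, pseudo-F, permutation tests."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import phylorda as pr

from conftest import lstsq_fraction


def random_instance(rng, n=12, p=4, q=2):
    return rng.normal(size=(n, p)), rng.normal(size=(n, q))


class TestExplainedFraction:
    def test_matches_least_squares_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            Y, X = random_instance(rng)
            model = pr.fit_rda(Y, X)
            assert model.explained_fraction_ == pytest.approx(
                lstsq_fraction(Y, X), abs=1e-10
            )

    def test_self_explanation_is_total(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(10, 3))
        assert pr.fit_rda(Y, Y).explained_fraction_ == pytest.approx(1.0, abs=1e-12)

    def test_single_columns_give_squared_pearson(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(15, 1))
        x = 0.5 * y + rng.normal(size=(15, 1))
        r = np.corrcoef(x[:, 0], y[:, 0])[0, 1]
        assert pr.fit_rda(y, x).explained_fraction_ == pytest.approx(r**2, abs=1e-12)

    def test_monotone_in_added_constraints(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(14, 5))
        X = rng.normal(size=(14, 4))
        fracs = [pr.fit_rda(Y, X[:, :k]).explained_inertia_ for k in range(1, 5)]
        assert all(a <= b + 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_covariables_equal_to_constraints_leave_nothing(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(10, 3))
        X = rng.normal(size=(10, 2))
        model = pr.fit_rda(Y, X, W=X)
        assert model.explained_inertia_ == pytest.approx(0.0, abs=1e-12)

    def test_redundant_dummy_block_rank(self, response_cov, eco_matrix):
        # 4 + 4 dummies over two exhaustive classifications would span rank 6,
        # but in this community the single arboreal species is also the single
        # forest species, so the two blocks share one more dimension: rank 5
        model = pr.fit_rda(response_cov, eco_matrix)
        assert model.rank_constraints_ == 5

    def test_eigenvalues_sum_to_explained(self, response_cov, eco_matrix):
        model = pr.fit_rda(response_cov, eco_matrix)
        assert model.eigenvalues_.sum() == pytest.approx(
            model.explained_inertia_, rel=1e-10
        )
        assert (np.diff(model.eigenvalues_) <= 1e-12).all()

    def test_misaligned_labels_fail(self, response_cov):
        X = pd.DataFrame(
            {"x": np.arange(17.0)}, index=[f"other{i}" for i in range(17)]
        )
        with pytest.raises(ValueError, match="misaligned"):
            pr.fit_rda(response_cov, X)

    def test_zero_inertia_fails(self):
        Y = np.ones((6, 2))
        with pytest.raises(ValueError, match="inertia"):
            pr.fit_rda(Y, np.random.default_rng(0).normal(size=(6, 1)))


class TestPseudoF:
    def test_brute_force_sums_of_squares(self):
        rng = np.random.default_rng(5)
        Y, X = rng.normal(size=(10, 3)), rng.normal(size=(10, 2))
        model = pr.fit_rda(Y, X)
        frac = lstsq_fraction(Y, X)
        expected = (frac / 2) / ((1 - frac) / (10 - 2 - 1))
        assert model.pseudo_f() == pytest.approx(expected, rel=1e-10)

    def test_zero_for_orthogonal_constraints(self):
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(12, 2))
        Yc = Y - Y.mean(axis=0)
        noise = rng.normal(size=(12, 1))
        noise -= noise.mean(axis=0)
        X = noise - Yc @ np.linalg.lstsq(Yc, noise, rcond=None)[0]
        model = pr.fit_rda(Y, X)
        assert model.pseudo_f() == pytest.approx(0.0, abs=1e-16)

    def test_f_subscript_is_constraint_rank(self, response_cov, eco_matrix):
        single = pr.fit_rda(response_cov, eco_matrix.values[["substrate_aquatic"]])
        assert single.rank_constraints_ == 1
        assert single.df_residual_ == 15


class TestPermutationTest:
    def test_reproducible_given_seed(self, response_cov, eco_matrix):
        X = eco_matrix.values[["substrate_aquatic"]]
        a = pr.permutation_test(response_cov, X, n_permutations=199, seed=9)
        b = pr.permutation_test(response_cov, X, n_permutations=199, seed=9)
        assert a.p_value == b.p_value and a.n_as_extreme == b.n_as_extreme

    def test_p_value_bounds(self, response_cov, eco_matrix):
        X = eco_matrix.values[["substrate_aquatic"]]
        res = pr.permutation_test(response_cov, X, n_permutations=199, seed=9)
        assert 1 / 200 <= res.p_value <= 1.0
        assert res.p_value == (res.n_as_extreme + 1) / 200

    def test_perfect_predictor_attains_minimal_p(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=(10, 1))  # all rows distinct
        res = pr.permutation_test(y, y, n_permutations=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100, abs=0.02)

    def test_fixture_aquatic_is_significant(self, response_cov, eco_matrix):
        X = eco_matrix.values[["substrate_aquatic"]]
        res = pr.permutation_test(response_cov, X, n_permutations=999, seed=3)
        assert res.p_value <= 0.05

    def test_singleton_clade_null_is_discrete(self, response_cov, clade_matrix):
        # a single-species clade has only 17 distinct permutation outcomes:
        # the +1 p-value cannot go below ~1/17 even for the extreme species
        X = clade_matrix.subset(["Hydrodynastini"])
        res = pr.permutation_test(response_cov, X, n_permutations=1999, seed=5)
        assert res.p_value == pytest.approx(1 / 17, abs=0.015)
        assert res.mid_p < 0.05

    def test_partial_schemes_agree_without_covariables(self, response_cov, eco_matrix):
        X = eco_matrix.values[["substrate_aquatic"]]
        a = pr.permutation_test(response_cov, X, n_permutations=99, seed=1,
                                scheme="reduced_model")
        b = pr.permutation_test(response_cov, X, n_permutations=99, seed=1,
                                scheme="unrestricted")
        assert a.p_value == b.p_value


class TestAxesAndScores:
    def test_cumulative_axis_variation_complete(self, response_cov, eco_matrix):
        model = pr.fit_rda(response_cov, eco_matrix)
        k = len(model.eigenvalues_)
        assert model.axis_variation(k) == pytest.approx(1.0, abs=1e-12)
        assert model.axis_variation(k + 5) == pytest.approx(1.0, abs=1e-12)

    def test_rank_one_constraint_single_axis(self, response_cov, eco_matrix):
        model = pr.fit_rda(response_cov, eco_matrix.values[["substrate_aquatic"]])
        assert len(model.eigenvalues_) == 1
        assert model.axis_variation(1) == pytest.approx(1.0)

    def test_complementary_dummy_arrows_antiparallel(self, response_cov, eco_matrix):
        model = pr.fit_rda(response_cov, eco_matrix)
        arrows = model.triplot_scores()["responses"]
        ovi = arrows.loc["mode_oviparous"].to_numpy()
        viv = arrows.loc["mode_viviparous"].to_numpy()
        cos = ovi @ viv / (np.linalg.norm(ovi) * np.linalg.norm(viv))
        assert cos == pytest.approx(-1.0, abs=1e-9)

    def test_fixture_triplot_correlation_signs(self, response_cov, eco_matrix,
                                               clade_matrix):
        X = pd.concat(
            [
                eco_matrix.values[["substrate_aquatic"]],
                clade_matrix.subset(
                    ["Hydrodynastini", "Hydropsini", "Xenodon"]
                ).as_coded().values,
            ],
            axis=1,
        )
        tp = pr.fit_rda(response_cov, X).triplot_scores()

        def cos(u, v):
            k = min(len(u), len(v))
            u, v = u[:k], v[:k]
            return u @ v / (np.linalg.norm(u) * np.linalg.norm(v))

        aq = tp["constraints"].loc["substrate_aquatic"].to_numpy()
        viv = tp["responses"].loc["mode_viviparous"].to_numpy()
        xen = tp["constraints"].loc["Xenodon"].to_numpy()
        assert cos(aq, viv) > 0.5      # aquatic ~ viviparity: sharp angle
        assert cos(aq, xen) < 0.0      # aquatic ~ Xenodon clade: obtuse


class TestAgainstVegan:
    def test_fixture_rda_matches_vegan(self, tmp_path, response_cov, eco_matrix):
        """Cross-check explained fraction and pseudo-F with R vegan::rda."""
        y_path, x_path = tmp_path / "Y.csv", tmp_path / "X.csv"
        response_cov.values.to_csv(y_path)
        eco_matrix.values[["substrate_aquatic"]].to_csv(x_path)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(vegan))
            Y <- read.csv("{y_path}", row.names=1)
            X <- read.csv("{x_path}", row.names=1)
            m <- rda(Y, X)
            frac <- sum(m$CCA$eig)/m$tot.chi
            F <- (sum(m$CCA$eig)/m$CCA$qrank) /
                 (sum(m$CA$eig)/(nrow(Y)-m$CCA$qrank-1))
            cat(sprintf("%.12f %.12f", frac, F))
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        frac, f_stat = map(float, out.stdout.split())
        model = pr.fit_rda(response_cov, eco_matrix.values[["substrate_aquatic"]])
        assert model.explained_fraction_ == pytest.approx(frac, abs=1e-9)
        assert model.pseudo_f() == pytest.approx(f_stat, abs=1e-9)
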