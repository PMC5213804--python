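"""Clade tests, forward selection, variance partitioning, full pipeline."""

import numpy as np
import pandas as pd
import pytest

import phylorda as pr

from conftest import lstsq_fraction


class TestMarginalCladeTests:
    def test_fixture_ranking_and_oracle(self, response_cov, clade_matrix):
        table = pr.marginal_clade_tests(
            response_cov, clade_matrix, n_permutations=199, seed=0
        ).ranked()
        assert table.index[0] == "Hydrodynastini"
        assert ((table["fraction"] >= 0) & (table["fraction"] <= 1)).all()
        # marginal fractions equal the independent least-squares oracle
        for clade in ("Hydrodynastini", "Hydropsini", "Xenodon"):
            expected = lstsq_fraction(
                response_cov.values.to_numpy(),
                clade_matrix.values[[clade]]
                .reindex(response_cov.row_labels)
                .to_numpy(float),
            )
            assert table.loc[clade, "fraction"] == pytest.approx(expected, abs=1e-10)

    def test_independent_of_column_order(self, response_cov, clade_matrix):
        reversed_cols = clade_matrix.subset(clade_matrix.column_labels[::-1])
        a = pr.marginal_clade_tests(response_cov, clade_matrix,
                                    n_permutations=99, seed=4).table
        b = pr.marginal_clade_tests(response_cov, reversed_cols,
                                    n_permutations=99, seed=4).table
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_empty_clade_set_fails(self, response_cov, clade_matrix):
        with pytest.raises(ValueError, match="empty"):
            pr.marginal_clade_tests(response_cov, clade_matrix.values.iloc[:, :0])


class TestForwardSelection:
    def test_fixture_selects_three_reported_clades(self, response_cov, clade_matrix):
        sel = pr.forward_select(
            response_cov, clade_matrix, n_permutations=999, seed=1
        )
        assert sel.selected_ == ["Hydrodynastini", "Hydropsini", "Xenodon"]
        steps = sel.steps_frame()
        # sequential contributions telescope to the selected-model fit
        cum = steps.loc[sel.selected_, "added_fraction"].sum()
        model = pr.fit_rda(response_cov, clade_matrix.subset(sel.selected_))
        assert cum == pytest.approx(model.explained_fraction_, abs=1e-10)

    def test_perfect_candidate_selected_first(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=(12, 1))
        cand = pd.DataFrame(
            {"signal": y[:, 0], "noise_a": rng.normal(size=12),
             "noise_b": rng.normal(size=12)}
        )
        sel = pr.forward_select(y, cand, n_permutations=199, seed=0)
        assert sel.selected_[0] == "signal"

    def test_orthogonal_candidates_select_nothing(self):
        rng = np.random.default_rng(11)
        Y = rng.normal(size=(14, 2))
        Yc = Y - Y.mean(axis=0)
        noise = rng.normal(size=(14, 3))
        noise -= noise.mean(axis=0)
        ortho = noise - Yc @ np.linalg.lstsq(Yc, noise, rcond=None)[0]
        cand = pd.DataFrame(ortho, columns=["c1", "c2", "c3"])
        sel = pr.forward_select(Y, cand, n_permutations=199, seed=0)
        assert sel.selected_ == []

    def test_invariant_to_candidate_order(self, response_cov, clade_matrix):
        fwd = pr.forward_select(response_cov, clade_matrix,
                                n_permutations=199, seed=2)
        rev = pr.forward_select(
            response_cov, clade_matrix.subset(clade_matrix.column_labels[::-1]),
            n_permutations=199, seed=2,
        )
        assert fwd.selected_ == rev.selected_

    def test_strict_rule_blocks_discrete_singleton(self, response_cov, clade_matrix):
        # with the +1 p-value a monotypic clade cannot pass alpha=0.05 at n=17
        sel = pr.forward_select(response_cov, clade_matrix, n_permutations=999,
                                seed=1, selection_rule="p_value")
        assert "Hydrodynastini" not in sel.selected_


class TestVariancePartition:
    def test_identities_on_fixture(self, response_cov, eco_matrix, clade_matrix):
        part = pr.variance_partition(
            response_cov,
            eco_matrix.values[["substrate_aquatic"]],
            clade_matrix.subset(["Hydrodynastini", "Hydropsini", "Xenodon"]),
        )
        assert part.unique_phylo + part.shared == pytest.approx(part.r_phylo, abs=1e-10)
        assert part.unique_eco + part.shared == pytest.approx(part.r_eco, abs=1e-10)
        total = (part.unique_phylo + part.unique_eco + part.shared
                 + part.unexplained)
        assert total == pytest.approx(1.0, abs=1e-10)
        assert part.shared > 0

    def test_identical_matrices_share_everything(self, response_cov, eco_matrix):
        X = eco_matrix.values[["substrate_aquatic"]]
        part = pr.variance_partition(response_cov, X, X)
        assert part.unique_phylo == pytest.approx(0.0, abs=1e-12)
        assert part.unique_eco == pytest.approx(0.0, abs=1e-12)
        assert part.shared == pytest.approx(part.r_eco, abs=1e-12)

    def test_zero_ecological_effect_recovers_small_unique_eco(self):
        """With b=0, pipeline-selected ecology explains ~nothing uniquely."""
        vals = []
        for r in range(15):
            ds = pr.generate_dataset(
                pr.SimConfig(n_species=20, phylo_weight=1.0, eco_weight=0.0,
                             noise_sd=0.5, eco_clustered_on_tree=False,
                             seed=3000 + r)
            )
            Y = pr.build_response_matrix(ds.rows, scaling="correlation")
            clades = pr.clade_indicators(ds.tree, min_size=2)
            sel_e = pr.forward_select(Y, ds.eco_matrix, n_permutations=199,
                                      seed=3000 + r)
            sel_p = pr.forward_select(Y, clades, n_permutations=199, seed=100 + r)
            if not sel_e.selected_ or not sel_p.selected_:
                vals.append(0.0)
                continue
            part = pr.variance_partition(
                Y, ds.eco_matrix.subset(sel_e.selected_),
                clades.subset(sel_p.selected_),
            )
            vals.append(part.unique_eco)
        assert np.median(vals) < 0.05


@pytest.fixture(scope="module")
def report(fixture_rows, fixture_tree):
    cfg = pr.AnalysisConfig(seed=7, scaling="covariance", n_permutations=199)
    return pr.run_full_cpo(fixture_rows, fixture_tree, cfg)


class TestFullPipeline:
    def test_ecology_stage_selects_only_aquatic(self, report):
        assert report["stages"]["ecology"]["selected"] == ["substrate_aquatic"]

    def test_cpo_stage_reports_selected_model(self, report):
        cpo = report["stages"]["cpo"]
        assert cpo["selected"] == ["Hydrodynastini", "Hydropsini", "Xenodon"]
        assert 0 < cpo["selected_model_fraction"] <= cpo["all_clades_fraction"] + 1e-12

    def test_partition_block_present_and_consistent(self, report):
        part = report["stages"]["pcpo"]["partition"]
        total = (part["A_unique_phylo"] + part["B_unique_eco"] + part["C_shared"]
                 + part["U_unexplained"])
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_without_ecology_partition_omitted(self, fixture_rows, fixture_tree):
        cfg = pr.AnalysisConfig(seed=7, scaling="covariance", n_permutations=99)
        report = pr.run_full_cpo(fixture_rows, fixture_tree, cfg,
                                 include_ecology=False)
        assert "ecology" not in report["stages"]
        assert "pcpo" not in report["stages"]
        assert "cpo" in report["stages"]
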