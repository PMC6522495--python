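import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from vcmnet import prioritize, simulate
from vcmnet.expression_io import ExpressionMatrix


def two_stage_matrix(values_a, values_b, gene_ids=None):
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    n = a.shape[0]
    gene_ids = gene_ids or [f"g{i}" for i in range(n)]
    return ExpressionMatrix(
        gene_ids,
        [f"A{j}" for j in range(a.shape[1])] + [f"B{j}" for j in range(b.shape[1])],
        ["A"] * a.shape[1] + ["B"] * b.shape[1],
        np.hstack([a, b]),
    )


class TestDifferentialExpression:
    def test_identical_groups_give_null_statistics(self):
        vals = np.array([[1.0, 2.0, 3.0]])
        m = two_stage_matrix(vals, vals)
        table = prioritize.differential_expression(m, ("A", "B"))
        assert table["lfc"].iloc[0] == 0.0
        assert table["t"].iloc[0] == pytest.approx(0.0)
        assert table["p"].iloc[0] == pytest.approx(1.0)
        assert not table["significant"].iloc[0]

    def test_bh_convention_on_analytic_vector(self):
        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(q, 0.04)

    def test_q_never_below_p(self, default_study):
        table = prioritize.differential_expression(
            default_study.matrix, ("hESC-VCM", "fetal-VCM")
        )
        assert (table["q"] >= table["p"] - 1e-15).all()
        sig = table["significant"]
        assert ((table.loc[sig, "q"] < 0.05) & (table.loc[sig, "lfc"].abs() >= 1)).all()

    def test_planted_strong_changes_are_called(self, default_study):
        """The generator's silent-vs-expressed candidate genes must be called."""
        table = prioritize.differential_expression(
            default_study.matrix, ("hESC-VCM", "fetal-VCM")
        )
        assert table.loc[default_study.candidates, "significant"].all()

    def test_replicate_requirement(self):
        m = two_stage_matrix([[1.0]], [[2.0, 3.0]])
        with pytest.raises(ValueError, match="2 replicate"):
            prioritize.differential_expression(m, ("A", "B"))

    def test_empirical_fdr_controlled(self):
        """At the default study design the BH union call keeps FDR <= 0.1."""
        from dataclasses import replace

        base = simulate.ExpressionSimConfig(
            modules=tuple(replace(mm, signal_sd=0.0) for mm in simulate.DEFAULT_MODULES),
            n_de=40, n_candidates=0, n_intermediate=0, n_adult_high=0,
        )
        fdrs = []
        for seed in range(5):
            study = simulate.simulate_expression(replace(base, seed=5 + seed))
            tabs = [
                prioritize.differential_expression(study.matrix, c)
                for c in simulate.DEFAULT_CONTRASTS
            ]
            called = prioritize.significant_union(tabs)
            truth = set(study.de_truth.index[study.de_truth["is_de"]])
            fdrs.append(len(called - truth) / max(len(called), 1))
        assert np.mean(fdrs) <= 0.1


class TestExpressionWindow:
    def test_boundary_zero_included(self):
        # g0's stage-A mean z is exactly 0 (symmetric values); g1 sits at
        # z ~ +1.41 in stage A, above the closed upper bound
        m = ExpressionMatrix(
            ["g0", "g1"],
            ["A0", "A1", "B0", "B1", "B2", "B3"],
            ["A", "A", "B", "B", "B", "B"],
            [[1.0, 3.0, 1.0, 3.0, 1.0, 3.0], [5.0, 5.0, 1.0, 1.0, 1.0, 1.0]],
        )
        kept = prioritize.expression_window_filter(m, "A", window=(0.0, 1.0))
        assert "g0" in kept and "g1" not in kept

    def test_unknown_stage(self, default_study):
        with pytest.raises(KeyError):
            prioritize.expression_window_filter(default_study.matrix, "nope")

    def test_planted_window_genes(self, default_study):
        kept = prioritize.expression_window_filter(default_study.matrix, "hESC-VCM")
        pass_rate = np.mean([g in kept for g in default_study.window_pass])
        fail_rate = np.mean([g not in kept for g in default_study.window_fail])
        assert pass_rate >= 0.9
        assert fail_rate >= 0.9


def run_cascade(study, enabled=("regulators", "remodelers", "de", "window")):
    de = [
        prioritize.differential_expression(study.matrix, c)
        for c in simulate.DEFAULT_CONTRASTS
    ]
    window = prioritize.expression_window_filter(study.matrix, "hESC-VCM")
    return prioritize.filter_cascade(
        study.modules.genes_in("turquoise"),
        study.gene_sets,
        de,
        window,
        enabled_filters=enabled,
        m=study.matrix,
    )


class TestFilterCascade:
    def test_all_filters_disabled_is_identity(self, default_study):
        table, report = run_cascade(default_study, enabled=())
        assert set(table.index) == set(default_study.modules.genes_in("turquoise"))
        assert report["module"] == report["window"] == len(table)

    def test_disjoint_regulators_empty_with_full_report(self, default_study):
        from vcmnet.expression_io import GeneSetCollection

        disjoint = GeneSetCollection(
            dict(default_study.gene_sets.sets, transcriptional_regulators={"NOT_A_GENE"}),
            default_study.gene_sets.go_map,
        )
        de = [
            prioritize.differential_expression(default_study.matrix, c)
            for c in simulate.DEFAULT_CONTRASTS
        ]
        window = prioritize.expression_window_filter(default_study.matrix, "hESC-VCM")
        table, report = prioritize.filter_cascade(
            default_study.modules.genes_in("turquoise"), disjoint, de, window
        )
        assert len(table) == 0
        assert [report[k] for k in prioritize.CASCADE_STAGES] == [120, 0, 0, 0, 0]

    def test_counts_nonincreasing(self, default_study):
        _, report = run_cascade(default_study)
        counts = [report[k] for k in prioritize.CASCADE_STAGES]
        assert counts == sorted(counts, reverse=True)

    def test_true_candidates_rank_first(self):
        for seed in (101, 102, 103):
            study = simulate.simulate_expression(simulate.ExpressionSimConfig(seed=seed))
            table, _ = run_cascade(study)
            assert set(table.index[:2]) == set(study.candidates)
            assert list(table["rank"][:2]) == [1, 2]

    def test_de_union_semantics(self):
        rng = np.random.default_rng(0)
        idx = pd.Index([f"g{i}" for i in range(30)], name="gene")
        tables = []
        for _ in range(2):
            sig = rng.random(30) < 0.3
            tables.append(
                pd.DataFrame(
                    {"lfc": rng.normal(size=30), "significant": sig}, index=idx
                )
            )
        union = prioritize.significant_union(tables)
        expected = set(idx[tables[0]["significant"]]) | set(idx[tables[1]["significant"]])
        assert union == expected

    def test_empty_module_rejected(self, default_study):
        with pytest.raises(ValueError, match="empty"):
            prioritize.filter_cascade([], default_study.gene_sets, [], set())

    def test_null_signal_yields_alpha_controlled_candidates(self):
        finals = []
        for seed in range(5):
            study = simulate.simulate_expression(simulate.null_config(seed=seed))
            de = [
                prioritize.differential_expression(study.matrix, c)
                for c in simulate.DEFAULT_CONTRASTS
            ]
            window = prioritize.expression_window_filter(study.matrix, "hESC-VCM")
            table, _ = prioritize.filter_cascade(
                study.matrix.gene_ids, study.gene_sets, de, window
            )
            finals.append(len(table))
        assert np.mean(finals) <= 1.0


class TestCascadePercentage:
    @pytest.mark.parametrize(
        "num,den,expected", [(117, 544, 22), (0, 7, 0), (1, 3, 33), (1, 2, 50), (5, 8, 63)]
    )
    def test_rounding_half_up(self, num, den, expected):
        assert prioritize.cascade_percentage(num, den) == expected

    def test_validation(self):
        with pytest.raises(ValueError):
            prioritize.cascade_percentage(1, 0)
        with pytest.raises(ValueError):
            prioritize.cascade_percentage(5, 4)
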