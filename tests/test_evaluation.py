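"""Leave-one-out counts, SE/SP/PPV, CV selection and the robustness sweep."""

import itertools

import pytest

from pathfill.evaluation import (
    ConfusionCounts,
    confusion_metrics,
    evaluate_pathways,
    leave_one_out,
    robustness_sweep,
    ten_fold_cv,
)
from pathfill.model import Params, Pathway, ValidationError


class TestConfusionMetrics:
    def test_exhaustive_small_table_oracle(self):
        """Match hand arithmetic on every 2x2 table with entries in 0..5."""
        for tp, fp, tn, fn in itertools.product(range(6), repeat=4):
            se, sp, ppv = confusion_metrics(ConfusionCounts(tp, fp, tn, fn))
            assert se == (tp / (tp + fn) if tp + fn else None)
            assert sp == (tn / (tn + fp) if tn + fp else None)
            assert ppv == (tp / (tp + fp) if tp + fp else None)

    def test_reference_examples(self):
        se, _, ppv = confusion_metrics(ConfusionCounts(9, 1, 90, 0))
        assert ppv == pytest.approx(0.9)
        assert se == pytest.approx(1.0)
        se, _, _ = confusion_metrics(ConfusionCounts(TP=5, FP=0, TN=0, FN=5))
        assert se == pytest.approx(0.5)

    def test_undefined_flagged_not_zero(self):
        se, sp, ppv = confusion_metrics(ConfusionCounts(0, 0, 0, 0))
        assert se is None and sp is None and ppv is None


class TestLeaveOneOut:
    def test_planted_pathway_fully_recovered(self, default_dataset,
                                             default_analysis, params):
        pw = default_dataset.pathways[0]
        c = leave_one_out(pw, default_analysis.rank_fn(), params,
                          default_analysis.n_target_genes)
        assert c.TP == pw.size
        assert c.FN == 0
        assert c.total == default_analysis.n_target_genes

    def test_tp_plus_fn_equals_pathway_size(self, default_dataset,
                                            default_analysis, params):
        pw = default_dataset.pathways[0]
        c = leave_one_out(pw, default_analysis.rank_fn(),
                          params.with_(gamma=1),
                          default_analysis.n_target_genes)
        assert c.TP + c.FN == pw.size

    def test_no_evidence_means_no_recall(self, params):
        pw = Pathway("p", frozenset({"a", "b"}))
        c = leave_one_out(pw, lambda seeds, prm: [], params, 100)
        assert (c.TP, c.FN, c.FP) == (0, 2, 0)

    def test_gamma_zero_empty_output(self, default_dataset, default_analysis):
        pw = default_dataset.pathways[0]
        c = leave_one_out(pw, default_analysis.rank_fn(),
                          Params(gamma=0), default_analysis.n_target_genes)
        assert (c.TP, c.FP) == (0, 0)

    def test_singleton_pathway_rejected(self, params):
        with pytest.raises(ValidationError):
            leave_one_out(Pathway("p", frozenset({"a"})),
                          lambda s, prm: [], params, 10)


class TestEvaluatePathways:
    @staticmethod
    def fake_rank_fn(recall_map):
        """Recalls held-out genes listed per pathway-seed pattern."""
        from pathfill.model import RankedCandidate

        def fn(seeds, prm):
            out = []
            for i, gene in enumerate(sorted(recall_map - set(seeds)), start=1):
                out.append(
                    RankedCandidate("q", gene, 0.1, None, 0.1, 1, i)
                )
            return out

        return fn

    def test_averages_are_unweighted_means(self, default_dataset,
                                           default_analysis, params):
        pw = default_dataset.pathways[0]
        rep = evaluate_pathways([pw], default_analysis.rank_fn(), params,
                                default_analysis.n_target_genes)
        r = rep.per_pathway[pw.pathway_id]
        assert rep.SE_avg == r.SE and rep.PPV_avg == r.PPV

    def test_permutation_invariance(self, params):
        universe = {"a", "b", "c", "d"}
        fn = self.fake_rank_fn(universe)
        pws = [
            Pathway("p1", frozenset({"a", "b"})),
            Pathway("p2", frozenset({"c", "d"})),
        ]
        r1 = evaluate_pathways(pws, fn, params, 50)
        r2 = evaluate_pathways(pws[::-1], fn, params, 50)
        assert r1.SE_avg == r2.SE_avg
        assert r1.PPV_avg == r2.PPV_avg

    def test_singletons_skipped(self, params):
        fn = self.fake_rank_fn({"a", "b"})
        pws = [Pathway("p1", frozenset({"a", "b"})),
               Pathway("solo", frozenset({"z"}))]
        rep = evaluate_pathways(pws, fn, params, 50)
        assert set(rep.per_pathway) == {"p1"}

    def test_all_singletons_error(self, params):
        with pytest.raises(ValidationError):
            evaluate_pathways([Pathway("solo", frozenset({"z"}))],
                              lambda s, prm: [], params, 50)


class TestTenFoldCV:
    def test_single_grid_point_returned(self, default_dataset,
                                        default_analysis, params):
        best = ten_fold_cv([default_dataset.pathways[0]], [params],
                           default_analysis.rank_fn(),
                           default_analysis.n_target_genes, seed=3)
        assert best == params

    def test_informative_point_beats_degenerate(self, default_dataset,
                                                default_analysis, params):
        """gamma=0 predicts nothing (PPV undefined) and must lose."""
        degenerate = params.with_(gamma=0)
        best = ten_fold_cv(
            [default_dataset.pathways[0]], [degenerate, params],
            default_analysis.rank_fn(),
            default_analysis.n_target_genes, seed=3,
        )
        assert best == params

    def test_same_seed_same_selection(self, default_dataset, default_analysis,
                                      params):
        grid = [params.with_(system_error=v) for v in (0.0, 0.06)]
        picks = [
            ten_fold_cv([default_dataset.pathways[0]], grid,
                        default_analysis.rank_fn(),
                        default_analysis.n_target_genes, seed=11)
            for _ in range(2)
        ]
        assert picks[0] == picks[1]

    def test_fold_count_reduced_with_warning(self, default_dataset,
                                             default_analysis, params, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            ten_fold_cv([default_dataset.pathways[0]], [params],
                        default_analysis.rank_fn(),
                        default_analysis.n_target_genes, seed=3)
        assert any("reducing fold count" in r.message for r in caplog.records)


class TestRobustnessSweep:
    def test_zero_rate_reproduces_baseline_exactly(self, default_dataset,
                                                   default_analysis, params):
        points = robustness_sweep(
            [default_dataset.pathways[0]], default_analysis.rank_fn(),
            params, "system_error", [-1.0, 0.0, 1.0],
            default_analysis.n_target_genes,
        )
        assert [p.change_rate for p in points] == [-1.0, 0.0, 1.0]
        assert points[1].ppv_change_rate == 0.0

    def test_minus_one_evaluates_at_zero(self, default_dataset,
                                         default_analysis, params):
        points = robustness_sweep(
            [default_dataset.pathways[0]], default_analysis.rank_fn(),
            params, "system_error", [-1.0],
            default_analysis.n_target_genes,
        )
        assert points[0].value == 0.0

    def test_unknown_parameter_rejected(self, default_dataset,
                                        default_analysis, params):
        with pytest.raises(ValidationError):
            robustness_sweep([default_dataset.pathways[0]],
                             default_analysis.rank_fn(), params,
                             "gamma", [0.0], default_analysis.n_target_genes)

    def test_out_of_range_rate_rejected(self, default_dataset,
                                        default_analysis, params):
        with pytest.raises(ValidationError):
            robustness_sweep([default_dataset.pathways[0]],
                             default_analysis.rank_fn(), params,
                             "beta", [1.5], default_analysis.n_target_genes)
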