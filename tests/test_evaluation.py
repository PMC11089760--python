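import numpy as np
import pandas as pd
import pytest

from lncda.evaluation import (
    GoldStandard,
    evaluate_rank,
    f1_sweep,
    jaccard_top,
    label_rank,
    max_f1,
    pr_aupr,
    roc_auc,
    set_recovery,
)

from _oracles import mann_whitney_auc


def make_rank(scores, lncs=None):
    n = len(scores)
    lncs = lncs or [f"l{i}" for i in range(n)]
    rank = pd.DataFrame(
        {"lncrna": lncs, "disease": ["d1"] * n, "score": scores}
    )
    return rank.sort_values(
        ["score", "lncrna", "disease"], ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)


def labeled(scores, labels):
    n = len(scores)
    df = pd.DataFrame(
        {"lncrna": [f"l{i}" for i in range(n)], "disease": ["d1"] * n,
         "score": scores, "label": [bool(x) for x in labels]}
    )
    return df.sort_values(
        ["score", "lncrna", "disease"], ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)


class TestLabelRank:
    def test_tags_gold_pairs(self):
        rank = make_rank([0.9, 0.1], lncs=["l1", "l2"])
        gold = GoldStandard.from_pairs({("l1", "d1")})
        lab = label_rank(rank, gold)
        assert list(lab["label"]) == [True, False]

    def test_empty_gold_rejected(self):
        with pytest.raises(ValueError):
            GoldStandard.from_pairs(set())

    def test_unmatched_gold_pairs_warn(self, caplog):
        rank = make_rank([0.5], lncs=["l1"])
        gold = GoldStandard.from_pairs({("l1", "d1"), ("lX", "dX")})
        with caplog.at_level("WARNING"):
            lab = label_rank(rank, gold)
        assert "1 gold pair" in caplog.text
        assert int(lab["label"].sum()) == 1

    def test_label_count_conservation(self):
        rng = np.random.default_rng(0)
        lncs = [f"l{i}" for i in range(30)]
        rank = make_rank(rng.random(30), lncs=lncs)
        chosen = {(l, "d1") for l in rng.choice(lncs, 8, replace=False)}
        lab = label_rank(rank, GoldStandard.from_pairs(chosen))
        assert int(lab["label"].sum()) == len(chosen)


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc(labeled([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]))
        assert auc == 1.0

    def test_constant_scores_random_performance(self):
        _, auc = roc_auc(labeled([0.5] * 6, [1, 0, 1, 0, 1, 0]))
        assert auc == pytest.approx(0.5)

    def test_hand_computed_case(self):
        _, auc = roc_auc(labeled([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]))
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(labeled([0.5, 0.4], [1, 1]))

    def test_matches_mann_whitney_on_random_labelings(self):
        """Spot-check; the 500-labeling sweep runs in the acceptance suite."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            _, auc = roc_auc(labeled(scores, labels))
            assert auc == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-9
            )


class TestPrAupr:
    def test_all_positive_is_one(self):
        _, aupr = pr_aupr(labeled([0.9, 0.5, 0.1], [1, 1, 1]))
        assert aupr == pytest.approx(1.0)

    def test_single_positive_ranked_first(self):
        points, aupr = pr_aupr(labeled([0.9, 0.5, 0.1], [1, 0, 0]))
        assert (1.0, 1.0) in points
        assert aupr == pytest.approx(1.0)

    def test_hand_constructed_curve(self):
        points, aupr = pr_aupr(labeled([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]))
        assert points == [(0.0, 1.0), (0.5, 1.0), (1.0, 2 / 3)]
        assert aupr == pytest.approx(0.5 + 0.5 * (1 + 2 / 3) / 2)

    def test_no_positive_rejected(self):
        with pytest.raises(ValueError):
            pr_aupr(labeled([0.5], [0]))

    def test_aupr_at_least_prevalence(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(4, 50))
            scores = rng.random(n)
            labels = rng.random(n) < rng.uniform(0.1, 0.9)
            if not labels.any():
                continue
            _, aupr = pr_aupr(labeled(scores, labels))
            assert aupr >= labels.mean() - 1e-12

    def test_positives_ranked_last_still_bounded_by_prevalence(self):
        _, aupr = pr_aupr(labeled([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1]))
        assert aupr >= 0.5


class TestF1Sweep:
    def test_confusion_matrix_arithmetic(self):
        # threshold 0.5: TP=2 FP=1 FN=1 -> P=R=F1=2/3
        lab = labeled([0.9, 0.8, 0.6, 0.3], [1, 0, 1, 1])
        sweep = f1_sweep(lab, thresholds=[0.5])
        row = sweep.iloc[0]
        assert row["precision"] == pytest.approx(2 / 3)
        assert row["recall"] == pytest.approx(2 / 3)
        assert row["f1"] == pytest.approx(2 / 3)

    def test_threshold_above_all_scores_gives_zero_f1(self):
        sweep = f1_sweep(labeled([0.4, 0.2], [1, 0]), thresholds=[0.9])
        assert sweep["f1"].iloc[0] == 0.0

    def test_single_threshold_grid_max(self):
        lab = labeled([0.9, 0.1], [1, 0])
        sweep = f1_sweep(lab, thresholds=[0.5])
        best, at = max_f1(sweep)
        assert (best, at) == (1.0, 0.5)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            f1_sweep(labeled([0.5], [1]), thresholds=[])

    def test_default_grid_includes_distinct_scores(self):
        lab = labeled([0.42, 0.17], [1, 0])
        sweep = f1_sweep(lab)
        assert {0.42, 0.17} <= set(sweep["threshold"])

    def test_max_invariant_to_grid_refinement(self):
        rng = np.random.default_rng(5)
        scores = rng.random(40)
        labels = rng.random(40) < 0.3
        labels[np.argmax(scores)] = True
        lab = labeled(scores, labels)
        best_default, _ = max_f1(f1_sweep(lab))
        fine = np.union1d(np.linspace(0.01, 0.99, 197), np.unique(scores))
        best_fine, _ = max_f1(f1_sweep(lab, thresholds=fine))
        assert best_default == pytest.approx(best_fine, abs=1e-12)


class TestJaccardTop:
    def test_identical_ranks(self):
        rank = make_rank([0.9, 0.5, 0.1])
        assert jaccard_top(rank, rank, 0.5) == 1.0

    def test_disjoint_tops(self):
        a = make_rank([0.9, 0.8, 0.1, 0.0])
        b = make_rank([0.0, 0.1, 0.8, 0.9])
        assert jaccard_top(a, b, 0.5) == 0.0

    def test_partial_overlap(self):
        # tops {a,b,c} vs {c,d,e} -> 1/5
        lncs = list("abcde")
        a = make_rank([5, 4, 3, 2, 1], lncs=lncs)
        b = make_rank([1, 2, 3, 4, 5], lncs=lncs)
        assert jaccard_top(a, b, 0.6) == pytest.approx(1 / 5)

    def test_mismatched_universes_rejected(self):
        a = make_rank([0.5], lncs=["l1"])
        b = make_rank([0.5], lncs=["l2"])
        with pytest.raises(ValueError):
            jaccard_top(a, b, 1.0)


class TestSetRecovery:
    def test_set_equal_to_global_top(self):
        rank = make_rank([0.9, 0.8, 0.2, 0.1])
        top2 = set(zip(rank.lncrna[:2], rank.disease[:2]))
        table = set_recovery(rank, {"top": top2}, fractions=[0.5])
        assert table.loc["top", "top_0.5"] == 1.0

    def test_monotone_in_fraction(self):
        rng = np.random.default_rng(1)
        rank = make_rank(rng.random(40))
        tagged = set(
            zip(rank.lncrna[rng.choice(40, 10, replace=False)],
                ["d1"] * 10)
        )
        table = set_recovery(rank, {"s": tagged},
                             fractions=[0.1, 0.2, 0.3, 0.5, 1.0])
        vals = table.loc["s"].to_numpy()
        assert (np.diff(vals) >= 0).all()
        assert vals[-1] == 1.0

    def test_empty_set_rejected(self):
        rank = make_rank([0.5])
        with pytest.raises(ValueError):
            set_recovery(rank, {"s": set()})

    def test_pairs_outside_universe_rejected(self):
        rank = make_rank([0.5], lncs=["l1"])
        with pytest.raises(ValueError):
            set_recovery(rank, {"s": {("lX", "d1")}})


class TestReport:
    def test_end_to_end_report(self, tmp_path):
        rank = make_rank([0.9, 0.8, 0.7, 0.6])
        gold = GoldStandard.from_pairs({("l0", "d1"), ("l2", "d1")})
        report = evaluate_rank(rank, gold)
        assert report.auc == pytest.approx(0.75)
        assert 0 <= report.aupr <= 1
        assert report.max_f1 == max(report.f1_table["f1"])
        report.write(tmp_path / "eval")
        assert (tmp_path / "eval.summary.tsv").exists()
        assert "auc=" in report.summary()
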