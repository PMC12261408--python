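"""AUROC/AUPRC against independent oracles, and the experiment runners."""

import itertools

import numpy as np
import pytest

import atcpred as ap
from atcpred.errors import ValidationError
from atcpred.evaluation import curve_points, write_results


def brute_force_auroc(scores, labels):
    """Exhaustive pairwise count: P(pos > neg) + 0.5 * P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def brute_force_auprc(scores, labels):
    """Exhaustive threshold sweep, step-curve (no interpolation)."""
    n_pos = sum(labels)
    thresholds = sorted(set(scores), reverse=True)
    area, prev_recall = 0.0, 0.0
    for t in thresholds:
        tp = sum(1 for s, l in zip(scores, labels) if s >= t and l == 1)
        fp = sum(1 for s, l in zip(scores, labels) if s >= t and l == 0)
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


class TestMetricOracles:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0),
            ([0.9, 0.8, 0.2, 0.1], [1, 0, 1, 0], 0.75),
            ([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0], 0.5),
        ],
    )
    def test_auroc_examples(self, scores, labels, expected):
        assert ap.auroc(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_auprc_perfect_separation(self):
        assert ap.auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_auprc_interleaved_matches_sweep_oracle(self):
        scores, labels = [0.9, 0.8, 0.2, 0.1], [1, 0, 1, 0]
        assert ap.auprc(scores, labels) == pytest.approx(
            brute_force_auprc(scores, labels), abs=1e-12
        )

    def test_single_positive_ranked_last(self):
        # recall jumps 0 -> 1 at the final threshold where precision = 1/N
        n = 5
        scores = [0.9, 0.8, 0.7, 0.6, 0.1]
        labels = [0, 0, 0, 0, 1]
        assert ap.auprc(scores, labels) == pytest.approx(1 / n)

    def test_random_instances_match_both_oracles(self):
        rng = np.random.default_rng(12)
        for trial in range(200):
            n = int(rng.integers(4, 51))
            scores = rng.choice([0.1, 0.25, 0.5, 0.7, 0.9], size=n) if trial % 3 == 0 \
                else rng.random(n)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0], labels[-1] = 1, 0
            scores, labels = scores.tolist(), labels.tolist()
            assert ap.auroc(scores, labels) == pytest.approx(
                brute_force_auroc(scores, labels), abs=1e-9)
            assert ap.auprc(scores, labels) == pytest.approx(
                brute_force_auprc(scores, labels), abs=1e-9)

    def test_agreement_with_sklearn(self):
        from sklearn.metrics import average_precision_score, roc_auc_score

        rng = np.random.default_rng(13)
        for _ in range(25):
            scores = rng.random(30)
            labels = rng.integers(0, 2, size=30)
            if labels.sum() in (0, 30):
                labels[0], labels[-1] = 1, 0
            assert ap.auroc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)
            assert ap.auprc(scores, labels) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-12)

    def test_auroc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(14)
        scores = rng.random(40)
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[-1] = 1, 0
        base = ap.auroc(scores, labels)
        for transform in (np.exp, lambda s: 3 * s - 7, lambda s: s**3):
            assert ap.auroc(transform(scores), labels) == pytest.approx(base, abs=1e-12)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValidationError):
            ap.auroc([0.1, 0.2], [1, 1])
        with pytest.raises(ValidationError):
            ap.auprc([0.1, 0.2], [0, 0])


class TestCrossValidate:
    def test_mean_sd_arithmetic_and_determinism(self, tiny_problem, small_model_cfg,
                                                fast_train_cfg):
        table, sims, atc = tiny_problem
        res = ap.cross_validate(table, sims, atc, small_model_cfg, fast_train_cfg,
                                n_folds=5, seed=3)
        assert len(res.fold_auroc) == 5
        assert res.mean_auroc == pytest.approx(sum(res.fold_auroc) / 5)
        assert res.sd_auroc == pytest.approx(np.std(res.fold_auroc, ddof=1))
        again = ap.cross_validate(table, sims, atc, small_model_cfg, fast_train_cfg,
                                  n_folds=5, seed=3)
        assert again.fold_auroc == res.fold_auroc
        assert all(0 <= v <= 1 for v in res.fold_auroc + res.fold_auprc)

    def test_permuted_labels_are_a_null_control(self, tiny_problem, small_model_cfg,
                                                fast_train_cfg):
        table, sims, atc = tiny_problem
        null = ap.cross_validate(table, sims, atc, small_model_cfg, fast_train_cfg,
                                 n_folds=3, seed=5, permute_labels=True)
        assert len(null.fold_auroc) == 3  # runs end to end; AUROC level checked at scale


class TestStudies:
    def test_feature_combination_enumerates_subsets(self, tiny_problem, small_model_cfg,
                                                    fast_train_cfg):
        table, sims, atc = tiny_problem
        subsets = [("CS",), ("DDI", "SE"), ("CS", "DDI", "SE")]
        results = ap.feature_combination_study(
            subsets, table, sims, atc, small_model_cfg, fast_train_cfg,
            n_folds=2, seed=6)
        assert [r.tag for r in results] == ["CS", "DDI+SE", "CS+DDI+SE"]
        with pytest.raises(ValidationError):
            ap.feature_combination_study([()], table, sims, atc,
                                         small_model_cfg, fast_train_cfg)

    def test_robustness_baseline_reproduces_cross_validate(self, tiny_problem,
                                                           small_model_cfg,
                                                           fast_train_cfg):
        table, sims, atc = tiny_problem
        sweep = ap.robustness_study([0.0], table, sims, atc, small_model_cfg,
                                    fast_train_cfg, n_folds=2, seed=7)
        plain = ap.cross_validate(table, sims, atc, small_model_cfg, fast_train_cfg,
                                  n_folds=2, seed=7, tag="baseline")
        assert sweep[0].fold_auroc == plain.fold_auroc

    def test_robustness_fraction_bounds(self, tiny_problem, small_model_cfg,
                                        fast_train_cfg):
        table, sims, atc = tiny_problem
        with pytest.raises(ValidationError):
            ap.robustness_study([0.7], table, sims, atc, small_model_cfg, fast_train_cfg)


class TestExports:
    def test_curve_points_monotone(self):
        pts = curve_points([1, 0, 1, 0, 1], [0.9, 0.8, 0.7, 0.3, 0.2])
        roc, pr = pts["roc"], pts["pr"]
        assert (roc["fpr"].diff().dropna() >= 0).all()
        assert (roc["tpr"].diff().dropna() >= 0).all()
        assert roc["tpr"].iloc[-1] == 1.0 and roc["fpr"].iloc[-1] == 1.0
        assert (pr["recall"].diff().dropna() >= 0).all()

    def test_write_results_roundtrip(self, tmp_path):
        import json

        import pandas as pd

        res = ap.EvalResult(level=2, tag="demo", fold_auroc=[0.8, 0.9],
                            fold_auprc=[0.7, 0.8])
        write_results([res], tmp_path / "r.json", tmp_path / "r.csv")
        data = json.loads((tmp_path / "r.json").read_text())
        assert data[0]["auroc_mean"] == pytest.approx(0.85)
        df = pd.read_csv(tmp_path / "r.csv")
        assert set(df["metric"]) == {"auroc", "auprc"}
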