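"""Fold plans, metrics, chance level, the experiment driver, leakage guard."""

import numpy as np
import pytest
from scipy import stats

from ppafuse import (
    AnnConfig,
    ExperimentConfig,
    chance_level,
    compute_metrics,
    generate_cohort,
    make_fold_plan,
    misclassification_report,
    misclassified_overlap,
    preset_specs,
    run_experiment,
    sem,
)

BALANCED_60 = np.array(["TD"] * 30 + ["ASD"] * 30)


def fast_cfg(**kw):
    """Experiment config scaled for unit tests (few thresholds, small net)."""
    defaults = dict(
        p_grid=(0.01, 0.05),
        ann=AnnConfig(max_epochs=300),
        seed=0,
    )
    defaults.update(kw)
    return ExperimentConfig(**defaults)


class TestFoldPlan:
    def test_study_counts_36_12_12(self):
        plan = make_fold_plan(BALANCED_60, k=5, seed=0)
        for fold in plan.folds:
            assert len(fold["train"]) == 36
            assert len(fold["val"]) == 12
            assert len(fold["test"]) == 12
            for split in ("train", "val", "test"):
                labs = BALANCED_60[fold[split]]
                assert (labs == "TD").sum() == (labs == "ASD").sum()

    def test_test_sets_partition_cohort(self):
        plan = make_fold_plan(BALANCED_60, k=5, seed=3)
        all_test = np.concatenate([f["test"] for f in plan.folds])
        assert sorted(all_test.tolist()) == list(range(60))

    def test_same_seed_same_plan(self):
        a = make_fold_plan(BALANCED_60, k=5, seed=9)
        b = make_fold_plan(BALANCED_60, k=5, seed=9)
        for fa, fb in zip(a.folds, b.folds):
            for split in ("train", "val", "test"):
                np.testing.assert_array_equal(fa[split], fb[split])

    def test_unbalanced_remainder_distributed(self):
        labels = np.array(["TD"] * 13 + ["ASD"] * 11)
        plan = make_fold_plan(labels, k=5, seed=0)
        sizes = [len(f["test"]) for f in plan.folds]
        assert sum(sizes) == 24
        assert max(sizes) - min(sizes) <= 2

    def test_tiny_class_rejected(self):
        labels = np.array(["TD"] * 10 + ["ASD"] * 3)
        with pytest.raises(ValueError, match="subjects"):
            make_fold_plan(labels, k=5)


class TestMetrics:
    def test_all_correct(self):
        y = np.array(["TD", "ASD", "TD", "ASD"])
        assert compute_metrics(y, y) == (100.0, 100.0, 100.0)

    def test_all_asd_predictor(self):
        y_true = np.array(["TD", "TD", "ASD", "ASD"])
        y_pred = np.array(["ASD"] * 4)
        acc, sens, spec = compute_metrics(y_true, y_pred)
        assert (acc, sens, spec) == (50.0, 100.0, 0.0)

    def test_against_bruteforce_confusion_counts(self, rng):
        for _ in range(20):
            y_true = rng.choice(["TD", "ASD"], size=30)
            if len(set(y_true)) < 2:
                continue
            y_pred = rng.choice(["TD", "ASD"], size=30)
            acc, sens, spec = compute_metrics(y_true, y_pred)
            tp = sum(1 for t, p in zip(y_true, y_pred) if t == p == "ASD")
            tn = sum(1 for t, p in zip(y_true, y_pred) if t == p == "TD")
            n_asd = (y_true == "ASD").sum()
            n_td = (y_true == "TD").sum()
            assert acc == pytest.approx(100 * (tp + tn) / 30)
            assert sens == pytest.approx(100 * tp / n_asd)
            assert spec == pytest.approx(100 * tn / n_td)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([], [])

    def test_sem_matches_bruteforce(self, rng):
        vals = rng.normal(size=5)
        manual = np.sqrt(np.sum((vals - vals.mean()) ** 2) / 4) / np.sqrt(5)
        assert sem(vals) == pytest.approx(manual)


class TestChanceLevel:
    def test_exact_binomial_tail_oracle(self):
        # brute-force: smallest k with sum_{j>=k} C(n,j) 2^-n <= alpha
        for n in (20, 60, 100):
            ks = np.arange(n + 1)
            pmf = np.array([stats.binom.pmf(k, n, 0.5) for k in ks])
            tails = np.array([pmf[k:].sum() for k in ks])
            k_min = ks[tails <= 0.05][0]
            assert chance_level(n) == pytest.approx(100 * k_min / n)

    def test_approaches_fifty_for_large_n(self):
        assert chance_level(10_000) < 51.0
        assert chance_level(60) > chance_level(600) > chance_level(6000)

    def test_monotone_decreasing_in_alpha(self):
        levels = [chance_level(60, a) for a in (0.01, 0.05, 0.2, 0.5)]
        assert levels == sorted(levels, reverse=True)
        assert levels[-1] >= 50.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            chance_level(1)
        with pytest.raises(ValueError):
            chance_level(60, 0.0)


@pytest.fixture(scope="module")
def small_cohort():
    td, asd = preset_specs("both")
    return generate_cohort(12, td, asd, duration=10.0, fs=250.0, seed=5)


class TestRunExperiment:
    def test_report_covers_all_kinds_and_modes(self, small_cohort):
        res = run_experiment(small_cohort.recordings, fast_cfg(seed=5))
        kinds = set(res.report()["kind"])
        assert kinds == {"PSD", "PPA", "feature_fusion", "score_fusion"}
        rep = res.report()
        assert ((rep["accuracy"] >= 0) & (rep["accuracy"] <= 100)).all()

    def test_deterministic_digest(self, small_cohort):
        cfg = fast_cfg(seed=5, fusion=())
        a = run_experiment(small_cohort.recordings, cfg)
        b = run_experiment(small_cohort.recordings, cfg)
        assert a.digest == b.digest
        assert a.report().equals(b.report())

    def test_no_test_set_leakage(self, small_cohort):
        """Permuting test labels and features changes no selection/weights.

        Uses a single-fold plan so the perturbed subjects appear in no
        training or validation set anywhere; their labels and features may
        then change arbitrarily without altering any fitted quantity.
        """
        from dataclasses import replace

        import ppafuse
        from ppafuse.evaluation import FoldPlan

        cfg = fast_cfg(seed=5, fusion=())
        fm = {
            kind: ppafuse.extract_feature_matrix(small_cohort.recordings, kind)
            for kind in ("PSD", "PPA")
        }
        labels = fm["PSD"].labels
        fold0 = make_fold_plan(labels, cfg.k, cfg.seed).folds[0]
        plan = FoldPlan(k=1, folds=(fold0,), seed=cfg.seed)
        base = run_experiment(
            small_cohort.recordings, cfg, plan=plan, feature_matrices=fm
        )
        te = fold0["test"]
        fm_perm = {}
        for kind, m in fm.items():
            values = m.values.copy()
            values[te] += 100.0  # corrupt test features
            lab = m.labels.copy()
            lab[te] = lab[te][::-1]  # permute test labels
            fm_perm[kind] = replace(m, values=values, labels=lab)
        perm = run_experiment(
            small_cohort.recordings, cfg, plan=plan, feature_matrices=fm_perm
        )
        assert base.digest == perm.digest  # selections and weights identical


class TestMisclassification:
    def make_scores(self, p_asd_by_subject):
        import pandas as pd

        return pd.DataFrame(
            {
                "subject": list(p_asd_by_subject),
                "fold": 0,
                "kind": "PSD",
                "split": "test",
                "p_td": [1 - p for p in p_asd_by_subject.values()],
                "p_asd": list(p_asd_by_subject.values()),
            }
        )

    def test_verdicts_and_single_overlap(self):
        labels = {"s1": "TD", "s2": "TD", "s3": "ASD", "s4": "ASD"}
        # model A errs on s1 and s3; model B errs on s2 and s3
        rep_a = misclassification_report(
            self.make_scores({"s1": 0.9, "s2": 0.1, "s3": 0.2, "s4": 0.8}), labels
        )
        rep_b = misclassification_report(
            self.make_scores({"s1": 0.1, "s2": 0.9, "s3": 0.3, "s4": 0.7}), labels
        )
        assert misclassified_overlap(rep_a, rep_b) == {"s3"}

    def test_identical_models_full_overlap(self):
        labels = {"s1": "TD", "s2": "ASD"}
        rep = misclassification_report(
            self.make_scores({"s1": 0.8, "s2": 0.3}), labels
        )
        assert misclassified_overlap(rep, rep) == {"s1", "s2"}

    def test_perfect_model_empty_error_set(self):
        labels = {"s1": "TD", "s2": "ASD"}
        rep = misclassification_report(
            self.make_scores({"s1": 0.2, "s2": 0.9}), labels
        )
        assert not misclassified_overlap(rep, rep)

    def test_tie_score_counts_as_asd(self):
        labels = {"s1": "TD"}
        rep = misclassification_report(self.make_scores({"s1": 0.5}), labels)
        assert rep.loc[0, "predicted"] == "ASD"
        assert not rep.loc[0, "correct"]
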