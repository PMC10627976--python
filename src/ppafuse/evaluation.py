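"""Nested fivefold cross-validation, tuning on validation data, and metrics.

The experiment driver mirrors the classification protocol the package is
built around: subjects are split into five mutually exclusive, stratified
test folds; within each fold the remaining subjects are divided 3:1 per
class into training and validation sets (36/12/12 for a balanced cohort of
60).  Per fold, feature normalisation and t-test selection are fitted on
the training subjects only; the p-value threshold (swept over
0.005-0.05) and the score-fusion weight are chosen by validation accuracy
alone; test subjects are touched exactly once, for the final metrics.

Metrics are percentages: accuracy, sensitivity (ASD recall) and
specificity (TD recall), each reported as mean +/- SEM over folds.  The
empirical chance level is the smallest accuracy whose one-sided binomial
tail probability under a fair coin is at most alpha.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ann import AnnConfig, TrainedModel, predict_labels, predict_scores, train_ann
from .fusion import (
    DEFAULT_WEIGHT_GRID,
    FusionWeights,
    fuse_features,
    fuse_scores,
    sweep_fusion_weight,
)
from .selection import select_by_threshold, ttest_rank, zscore_apply, zscore_fit
from .spectral import DEFAULT_BANDS, BandScheme, FeatureMatrix, extract_feature_matrix
from .signal_io import Recording, SensorLayout

__all__ = [
    "DEFAULT_P_GRID",
    "FoldPlan",
    "ExperimentConfig",
    "ExperimentResult",
    "make_fold_plan",
    "compute_metrics",
    "sem",
    "chance_level",
    "sweep_pvalue_threshold",
    "run_experiment",
    "misclassification_report",
    "misclassified_overlap",
]

#: p-value thresholds 0.005 to 0.05 in steps of 0.005.
DEFAULT_P_GRID = tuple(np.round(np.arange(0.005, 0.0501, 0.005), 10))


@dataclass(frozen=True)
class FoldPlan:
    """Subject-exclusive train/validation/test partition for each fold."""

    k: int
    folds: tuple[dict, ...]  # each: {"train": idx, "val": idx, "test": idx}
    seed: int

    def __post_init__(self) -> None:
        all_test = np.concatenate([f["test"] for f in self.folds])
        if len(all_test) != len(set(all_test.tolist())):
            raise ValueError("test sets must be mutually exclusive")
        for f in self.folds:
            union = np.concatenate([f["train"], f["val"], f["test"]])
            if len(union) != len(set(union.tolist())):
                raise ValueError("train/val/test must be disjoint within a fold")


def make_fold_plan(labels, k: int = 5, seed: int = 0, val_fraction: float = 0.25) -> FoldPlan:
    """Stratified k-fold plan with a nested train/validation split.

    Each class's subjects are shuffled (seeded) and dealt round-robin into
    ``k`` test folds; per fold, the remaining subjects of each class are
    split into validation (``val_fraction``, default 1/4) and training.
    With 30+30 subjects and k=5 this yields 18+18 train, 6+6 validation,
    6+6 test per fold.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes = sorted(set(labels.tolist()))
    per_class_chunks: dict[str, list[np.ndarray]] = {}
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if len(idx) < k:
            raise ValueError(f"class {c!r} has {len(idx)} subjects < k={k}")
        idx = rng.permutation(idx)
        per_class_chunks[c] = [idx[i::k] for i in range(k)]
    folds = []
    for f in range(k):
        train, val, test = [], [], []
        for c in classes:
            test_c = per_class_chunks[c][f]
            rest = np.concatenate(
                [per_class_chunks[c][j] for j in range(k) if j != f]
            )
            rest = rng.permutation(rest)
            n_val = max(1, int(round(len(rest) * val_fraction)))
            val.append(rest[:n_val])
            train.append(rest[n_val:])
            test.append(test_c)
        folds.append(
            {
                "train": np.sort(np.concatenate(train)),
                "val": np.sort(np.concatenate(val)),
                "test": np.sort(np.concatenate(test)),
            }
        )
    return FoldPlan(k=k, folds=tuple(folds), seed=seed)


def compute_metrics(y_true, y_pred) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) in percent.

    Sensitivity is the fraction of ASD subjects correctly identified,
    specificity the fraction of TD subjects.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    correct = y_true == y_pred
    acc = 100.0 * correct.mean()
    asd = y_true == "ASD"
    td = y_true == "TD"
    sens = 100.0 * correct[asd].mean() if asd.any() else np.nan
    spec = 100.0 * correct[td].mean() if td.any() else np.nan
    return float(acc), float(sens), float(spec)


def sem(values) -> float:
    """Standard error of the mean: sample sd / sqrt(n)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return np.nan
    return float(values.std(ddof=1) / np.sqrt(len(values)))


def chance_level(n: int, alpha: float = 0.05) -> float:
    """Empirical chance level (%) for n subjects at significance alpha.

    The smallest accuracy k/n whose one-sided tail probability under
    Binomial(n, 1/2) is at most alpha, computed by exact tail summation.
    Tends to 50% as n grows.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    ks = np.arange(n + 1)
    tail = stats.binom.sf(ks - 1, n, 0.5)  # P(X >= k)
    k_min = ks[tail <= alpha][0]
    return float(100.0 * k_min / n)


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything the experiment driver needs besides the cohort."""

    kinds: tuple[str, ...] = ("PSD", "PPA")
    fusion: tuple[str, ...] = ("feature", "score")
    p_grid: tuple[float, ...] = DEFAULT_P_GRID
    weight_grid: tuple[float, ...] = DEFAULT_WEIGHT_GRID
    k: int = 5
    ann: AnnConfig = field(default_factory=AnnConfig)
    scheme: BandScheme = DEFAULT_BANDS
    layout: SensorLayout | None = None
    subset: str = "all"
    seed: int = 0


@dataclass
class KindResult:
    """Per-feature-kind outcome: tuned threshold, fold metrics, scores."""

    kind: str
    p_threshold: float
    val_accuracy_by_threshold: np.ndarray
    fold_metrics: pd.DataFrame  # fold, accuracy, sensitivity, specificity
    n_selected: float  # mean selected-feature count over folds
    scores: pd.DataFrame  # subject, fold, kind, split, p_td, p_asd
    fusion_weight: float | None = None
    digest: str = ""

    def summary(self) -> dict:
        m = self.fold_metrics
        out = {
            "kind": self.kind,
            "p_threshold": self.p_threshold,
            "n_selected": self.n_selected,
            "accuracy": float(m["accuracy"].mean()),
            "accuracy_sem": sem(m["accuracy"]),
            "sensitivity": float(m["sensitivity"].mean()),
            "sensitivity_sem": sem(m["sensitivity"]),
            "specificity": float(m["specificity"].mean()),
            "specificity_sem": sem(m["specificity"]),
        }
        if self.fusion_weight is not None:
            out["fusion_weight"] = self.fusion_weight
        return out


@dataclass
class ExperimentResult:
    """All per-kind results, the fold plan and a reproducibility digest."""

    config: ExperimentConfig
    plan: FoldPlan
    kinds: dict[str, KindResult]

    def report(self) -> pd.DataFrame:
        """Summary table: one row per feature kind / fusion mode."""
        return pd.DataFrame([r.summary() for r in self.kinds.values()])

    def score_table(self) -> pd.DataFrame:
        return pd.concat([r.scores for r in self.kinds.values()], ignore_index=True)

    @property
    def digest(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.kinds):
            h.update(self.kinds[name].digest.encode())
        return h.hexdigest()


def _ann_seed(master: int, kind: str, fold: int) -> int:
    # stable across processes (python's str hash is salted per run)
    kind_code = int.from_bytes(hashlib.sha256(kind.encode()).digest()[:4], "big")
    ss = np.random.SeedSequence([master, kind_code, fold])
    return int(ss.generate_state(1)[0] % 2**31)


def _fit_fold(fm: FeatureMatrix, fold: dict, threshold: float, ann_cfg: AnnConfig):
    """Normalise, select and train within one fold at one threshold.

    Returns (model, selected_indices, zscore params) — model is None when
    the selection is empty at this threshold.
    """
    tr, va = fold["train"], fold["val"]
    z = zscore_fit(fm, tr)
    sel = select_by_threshold(ttest_rank(fm, tr), threshold)
    if sel.n_selected == 0:
        return None, sel.selected_indices, z
    cols = sel.selected_indices
    X_tr = zscore_apply(fm, z, tr)[:, cols]
    X_va = zscore_apply(fm, z, va)[:, cols]
    model = train_ann(X_tr, fm.labels[tr], X_va, fm.labels[va], ann_cfg)
    return model, cols, z


def sweep_pvalue_threshold(
    fm: FeatureMatrix,
    plan: FoldPlan,
    p_grid: tuple[float, ...] = DEFAULT_P_GRID,
    ann: AnnConfig = AnnConfig(),
    seed: int = 0,
):
    """Choose the p-value threshold by mean validation accuracy.

    Trains one model per (threshold, fold); a threshold whose selection is
    empty in some fold scores zero validation accuracy there.  Ties are
    broken toward the smaller threshold (grid order).  Returns the chosen
    threshold, the per-threshold mean validation accuracies, and the cache
    of fitted fold states ``{(threshold, fold): (model, cols, z)}`` so the
    winning models can be reused on the test sets without refitting.
    """
    if len(p_grid) == 0:
        raise ValueError("empty threshold grid")
    cache: dict[tuple[float, int], tuple] = {}
    val_acc = np.zeros(len(p_grid))
    for ti, threshold in enumerate(p_grid):
        accs = []
        for fi, fold in enumerate(plan.folds):
            cfg = AnnConfig(**{**ann.__dict__, "seed": _ann_seed(seed, fm.kind_tag, fi)})
            model, cols, z = _fit_fold(fm, fold, threshold, cfg)
            cache[(threshold, fi)] = (model, cols, z)
            if model is None:
                accs.append(0.0)
                continue
            X_va = zscore_apply(fm, z, fold["val"])[:, cols]
            pred = predict_labels(predict_scores(model, X_va))
            accs.append(float(np.mean(pred == fm.labels[fold["val"]])))
        val_acc[ti] = np.mean(accs)
    best = int(np.argmax(val_acc))  # first maximiser -> smaller threshold on ties
    if val_acc[best] == 0.0 and all(
        cache[(p_grid[best], fi)][0] is None for fi in range(plan.k)
    ):
        raise ValueError("all thresholds yield empty selections in every fold")
    return float(p_grid[best]), val_acc, cache


def _score_rows(fm, model, cols, z, rows, kind, fold_i, split):
    X = zscore_apply(fm, z, rows)[:, cols]
    scores = predict_scores(model, X)
    df = pd.DataFrame(
        {
            "subject": [fm.subject_ids[i] for i in rows],
            "fold": fold_i,
            "kind": kind,
            "split": split,
            "p_td": scores[:, 0],
            "p_asd": scores[:, 1],
        }
    )
    return df


def _evaluate_kind(fm: FeatureMatrix, plan: FoldPlan, cfg: ExperimentConfig) -> KindResult:
    threshold, val_acc, cache = sweep_pvalue_threshold(
        fm, plan, cfg.p_grid, cfg.ann, cfg.seed
    )
    rows, metrics, n_sel = [], [], []
    digest = hashlib.sha256()
    for fi, fold in enumerate(plan.folds):
        model, cols, z = cache[(threshold, fi)]
        if model is None:
            continue
        digest.update(np.asarray(cols).tobytes())
        for key in sorted(model.weights):
            digest.update(model.weights[key].tobytes())
        n_sel.append(len(cols))
        for split in ("train", "val", "test"):
            rows.append(_score_rows(fm, model, cols, z, fold[split], fm.kind_tag, fi, split))
        te = fold["test"]
        pred = predict_labels(
            predict_scores(model, zscore_apply(fm, z, te)[:, cols])
        )
        acc, sens, spec = compute_metrics(fm.labels[te], pred)
        metrics.append({"fold": fi, "accuracy": acc, "sensitivity": sens, "specificity": spec})
    return KindResult(
        kind=fm.kind_tag,
        p_threshold=threshold,
        val_accuracy_by_threshold=val_acc,
        fold_metrics=pd.DataFrame(metrics),
        n_selected=float(np.mean(n_sel)) if n_sel else 0.0,
        scores=pd.concat(rows, ignore_index=True),
        digest=digest.hexdigest(),
    )


def _score_fusion(
    res_psd: KindResult, res_ppa: KindResult, labels_by_subject: dict, cfg: ExperimentConfig
) -> KindResult:
    """Fuse the two models' score tables with a validation-tuned weight."""

    def split_scores(res, split):
        s = res.scores[res.scores["split"] == split]
        return s.sort_values(["fold", "subject"]).reset_index(drop=True)

    va_psd, va_ppa = split_scores(res_psd, "val"), split_scores(res_ppa, "val")
    labels_va = np.array([labels_by_subject[s] for s in va_psd["subject"]])
    weights, _ = sweep_fusion_weight(va_psd, va_ppa, labels_va, cfg.weight_grid)

    te_psd, te_ppa = split_scores(res_psd, "test"), split_scores(res_ppa, "test")
    fused = fuse_scores(te_psd, te_ppa, weights)
    fused["split"] = "test"
    metrics = []
    for fi, grp in fused.groupby("fold"):
        y_true = np.array([labels_by_subject[s] for s in grp["subject"]])
        pred = predict_labels(grp[["p_td", "p_asd"]].to_numpy())
        acc, sens, spec = compute_metrics(y_true, pred)
        metrics.append({"fold": fi, "accuracy": acc, "sensitivity": sens, "specificity": spec})
    digest = hashlib.sha256(
        (res_psd.digest + res_ppa.digest + f"{weights.w}").encode()
    ).hexdigest()
    return KindResult(
        kind="score_fusion",
        p_threshold=np.nan,
        val_accuracy_by_threshold=np.empty(0),
        fold_metrics=pd.DataFrame(metrics),
        n_selected=res_psd.n_selected + res_ppa.n_selected,
        scores=fused,
        fusion_weight=weights.w,
        digest=digest,
    )


def run_experiment(
    cohort: list[Recording],
    cfg: ExperimentConfig = ExperimentConfig(),
    plan: FoldPlan | None = None,
    feature_matrices: dict[str, FeatureMatrix] | None = None,
) -> ExperimentResult:
    """Full nested-CV pipeline for every requested feature kind and fusion.

    Per kind: extract features, then per fold normalise/select/train on
    training subjects, tune the p-threshold on validation accuracy, and
    score the untouched test subjects.  Feature-level fusion concatenates
    the normalised PSD and PPA columns and re-runs selection on the fused
    matrix; score-level fusion combines the two single-kind score tables
    with a validation-tuned weight.

    ``plan`` and ``feature_matrices`` may be supplied to reuse a fold plan
    or precomputed features (the matrices must match the cohort's subject
    order).
    """
    feature_matrices = dict(feature_matrices or {})
    for kind in ("PSD", "PPA"):
        needed = kind in cfg.kinds or cfg.fusion
        if needed and kind not in feature_matrices:
            feature_matrices[kind] = extract_feature_matrix(
                cohort, kind, cfg.scheme, cfg.layout, cfg.subset
            )
    any_fm = next(iter(feature_matrices.values()))
    labels = any_fm.labels
    if plan is None:
        plan = make_fold_plan(labels, cfg.k, cfg.seed)
    labels_by_subject = dict(zip(any_fm.subject_ids, labels))

    results: dict[str, KindResult] = {}
    for kind in cfg.kinds:
        results[kind] = _evaluate_kind(feature_matrices[kind], plan, cfg)
    if "feature" in cfg.fusion:
        fused_fm = fuse_features(feature_matrices["PSD"], feature_matrices["PPA"])
        results["feature_fusion"] = _evaluate_kind(fused_fm, plan, cfg)
        results["feature_fusion"].kind = "feature_fusion"
    if "score" in cfg.fusion:
        if not {"PSD", "PPA"} <= set(results):
            raise ValueError("score fusion needs both PSD and PPA results")
        results["score_fusion"] = _score_fusion(
            results["PSD"], results["PPA"], labels_by_subject, cfg
        )
    return ExperimentResult(config=cfg, plan=plan, kinds=results)


def misclassification_report(scores: pd.DataFrame, labels_by_subject: dict) -> pd.DataFrame:
    """Per-subject verdicts from a (test-split) score table.

    For each subject: mean P(ASD) over its rows, the true label, the
    predicted label under the 0.5 rule and whether it is correct.
    """
    rows = []
    for subject, grp in scores.groupby("subject", sort=False):
        p_asd = float(grp["p_asd"].mean())
        truth = labels_by_subject[subject]
        pred = "ASD" if p_asd >= 0.5 else "TD"
        rows.append(
            {
                "subject": subject,
                "label": truth,
                "mean_p_asd": p_asd,
                "predicted": pred,
                "correct": pred == truth,
            }
        )
    return pd.DataFrame(rows).sort_values("subject").reset_index(drop=True)


def misclassified_overlap(report_a: pd.DataFrame, report_b: pd.DataFrame) -> set:
    """Subjects misclassified by both models (set intersection)."""
    bad_a = set(report_a.loc[~report_a["correct"], "subject"])
    bad_b = set(report_b.loc[~report_b["correct"], "subject"])
    return bad_a & bad_b
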