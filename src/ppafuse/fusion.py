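"""Feature-level and score-level fusion of the PSD and PPA models.

Two complementary spectral descriptions of the same recording — band power
(PSD) and preferred phase angle (PPA) — can be combined either before
classification, by concatenating the normalised feature vectors into one
(feature-level fusion), or after, by a convex combination of the two
classifiers' posterior score tables (score-level fusion):

    fused P(class) = w * P_psd(class) + (1 - w) * P_ppa(class)

with the weight ``w`` swept over {0.1, ..., 0.9} and chosen on validation
data only.  Fusion is worthwhile when the two models err on different
subjects; the complementarity check quantifies this as the Pearson
correlation of their training scores, which should be near zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ann import predict_labels
from .spectral import FeatureMatrix

__all__ = [
    "DEFAULT_WEIGHT_GRID",
    "FusionWeights",
    "make_score_table",
    "fuse_features",
    "fuse_scores",
    "sweep_fusion_weight",
    "complementarity_check",
]

#: Empirical weight grid for the PSD model (PPA gets the complement).
DEFAULT_WEIGHT_GRID = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))

SCORE_COLUMNS = ["subject", "fold", "kind", "p_td", "p_asd"]


@dataclass(frozen=True)
class FusionWeights:
    """Chosen PSD weight ``w`` (PPA weight is ``1 - w``) and the grid used."""

    w: float
    grid: tuple[float, ...] = DEFAULT_WEIGHT_GRID

    def __post_init__(self) -> None:
        if not 0 <= self.w <= 1:
            raise ValueError("weight must lie in [0, 1]")
        if any(not 0 < g < 1 for g in self.grid):
            raise ValueError("grid weights must lie strictly inside (0, 1)")


def make_score_table(subjects, scores: np.ndarray, kind: str, fold: int = 0) -> pd.DataFrame:
    """Assemble a tidy score table: subject, fold, kind, P(TD), P(ASD)."""
    scores = np.asarray(scores, dtype=float)
    return pd.DataFrame(
        {
            "subject": list(subjects),
            "fold": fold,
            "kind": kind,
            "p_td": scores[:, 0],
            "p_asd": scores[:, 1],
        }
    )


def fuse_features(fm_psd: FeatureMatrix, fm_ppa: FeatureMatrix) -> FeatureMatrix:
    """Concatenate normalised PSD and PPA feature columns (PSD first).

    Both matrices must describe the same subjects in the same order; the
    fused descriptors keep each column's origin kind, so selection reports
    on the fused matrix can still attribute features.
    """
    if fm_psd.subject_ids != fm_ppa.subject_ids:
        raise ValueError("subject sets/order differ between the two matrices")
    if not np.array_equal(fm_psd.labels, fm_ppa.labels):
        raise ValueError("labels differ between the two matrices")
    return FeatureMatrix(
        values=np.hstack([fm_psd.values, fm_ppa.values]),
        descriptors=pd.concat(
            [fm_psd.descriptors, fm_ppa.descriptors], ignore_index=True
        ),
        labels=fm_psd.labels,
        subject_ids=list(fm_psd.subject_ids),
        kind_tag="fused",
    )


def _as_scores(table) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        return table[["p_td", "p_asd"]].to_numpy(dtype=float)
    return np.asarray(table, dtype=float)


def fuse_scores(scores_psd, scores_ppa, w: float | FusionWeights):
    """Weighted sum of two posterior score tables.

    ``fused = w * P_psd + (1 - w) * P_ppa`` per subject and class; rows
    still sum to 1 by convexity.  Accepts (n, 2) arrays or tidy score
    DataFrames (which must agree on subject and fold).
    """
    if isinstance(w, FusionWeights):
        w = w.w
    if not 0 <= w <= 1:
        raise ValueError("weight must lie in [0, 1]")
    a, b = _as_scores(scores_psd), _as_scores(scores_ppa)
    if a.shape != b.shape:
        raise ValueError("score tables have different shapes")
    if isinstance(scores_psd, pd.DataFrame) and isinstance(scores_ppa, pd.DataFrame):
        if not (
            scores_psd["subject"].tolist() == scores_ppa["subject"].tolist()
            and scores_psd["fold"].tolist() == scores_ppa["fold"].tolist()
        ):
            raise ValueError("score tables do not describe the same subjects/folds")
        out = scores_psd.copy()
        out["kind"] = "score_fusion"
        out[["p_td", "p_asd"]] = w * a + (1 - w) * b
        return out
    return w * a + (1 - w) * b


def sweep_fusion_weight(
    scores_psd,
    scores_ppa,
    labels,
    grid: tuple[float, ...] = DEFAULT_WEIGHT_GRID,
) -> tuple[FusionWeights, np.ndarray]:
    """Pick the grid weight maximising accuracy on the given labelled scores.

    Intended for validation-set scores only.  Ties are broken by grid
    order (first maximiser wins).  Returns the chosen weights and the
    per-grid-point accuracies.
    """
    if len(grid) == 0:
        raise ValueError("empty weight grid")
    labels = np.asarray(labels)
    accs = np.empty(len(grid))
    for i, w in enumerate(grid):
        fused = fuse_scores(_as_scores(scores_psd), _as_scores(scores_ppa), w)
        accs[i] = float(np.mean(predict_labels(fused) == labels))
    best = int(np.argmax(accs))  # argmax returns the first maximiser
    return FusionWeights(w=float(grid[best]), grid=tuple(grid)), accs


def complementarity_check(
    psd_train_scores: list[np.ndarray],
    ppa_train_scores: list[np.ndarray],
) -> tuple[np.ndarray, float]:
    """Pearson correlation of paired training P(ASD) scores per repetition.

    One coefficient per repetition (paired vectors of per-subject training
    scores from the two models).  Near-zero mean correlation indicates the
    models are complementary and fusion is warranted; a repetition where
    either vector is constant has no defined correlation and is recorded
    as NaN and excluded from the mean.

    Returns
    -------
    coefficients : ndarray
        One value per repetition (NaN where undefined) — histogram-ready.
    mean : float
        Mean over the defined coefficients.
    """
    if len(psd_train_scores) != len(ppa_train_scores):
        raise ValueError("need the same number of repetitions for both models")
    coeffs = np.empty(len(psd_train_scores))
    for i, (a, b) in enumerate(zip(psd_train_scores, ppa_train_scores)):
        a = _as_scores(a)
        b = _as_scores(b)
        a = a[:, 1] if a.ndim == 2 else a
        b = b[:, 1] if b.ndim == 2 else b
        if len(a) != len(b) or len(a) < 2:
            raise ValueError("paired score vectors of length >= 2 required")
        if np.std(a) == 0 or np.std(b) == 0:
            coeffs[i] = np.nan
        else:
            coeffs[i] = float(np.corrcoef(a, b)[0, 1])
    defined = coeffs[~np.isnan(coeffs)]
    mean = float(defined.mean()) if len(defined) else np.nan
    return coeffs, mean
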