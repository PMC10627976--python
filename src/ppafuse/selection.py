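"""Per-feature z-score normalisation and t-test feature ranking.

Both operations take explicit row (subject) index sets so that a
cross-validation driver can fit them on training subjects only and apply
them to held-out subjects — the API makes test-set leakage a type error
rather than a discipline.

Phase-angle features are treated as plain reals in (-pi, pi] here; a linear
t-test can in principle miss wrap-around class differences, a limitation of
the linear treatment that circular statistics would avoid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectral import FeatureMatrix

__all__ = [
    "ZScoreParams",
    "SelectionResult",
    "zscore_fit",
    "zscore_apply",
    "ttest_rank",
    "select_by_threshold",
]


@dataclass(frozen=True)
class ZScoreParams:
    """Per-feature mean and sample standard deviation from the fit rows.

    Features constant on the fit rows get sd := 1 (so they normalise to
    exactly zero) and are flagged in ``constant``.
    """

    mean: np.ndarray
    sd: np.ndarray
    constant: np.ndarray  # boolean mask of zero-variance features


@dataclass
class SelectionResult:
    """t statistics, p-values and the thresholded, ranked selection.

    ``selected_indices`` holds exactly the features with ``p < threshold``,
    ordered by ascending p (ties broken by ascending column index).
    """

    t_stats: np.ndarray
    p_values: np.ndarray
    threshold: float | None = None
    selected_indices: np.ndarray | None = None

    @property
    def n_selected(self) -> int:
        return 0 if self.selected_indices is None else len(self.selected_indices)


def _rows_values(fm: FeatureMatrix | np.ndarray, rows) -> np.ndarray:
    values = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm)
    return values if rows is None else values[np.asarray(rows, dtype=int)]


def zscore_fit(fm: FeatureMatrix | np.ndarray, fit_rows=None) -> ZScoreParams:
    """Fit per-feature mean/sd on the given rows (sample sd, ddof=1)."""
    X = _rows_values(fm, fit_rows)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit z-score parameters")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    constant = sd == 0
    sd = np.where(constant, 1.0, sd)
    return ZScoreParams(mean=mean, sd=sd, constant=constant)


def zscore_apply(fm: FeatureMatrix | np.ndarray, params: ZScoreParams, rows=None) -> np.ndarray:
    """Normalise the given rows with previously fitted parameters."""
    X = _rows_values(fm, rows)
    return (X - params.mean) / params.sd


def ttest_rank(
    fm: FeatureMatrix | np.ndarray,
    rows=None,
    labels: np.ndarray | None = None,
    equal_var: bool = True,
) -> SelectionResult:
    """Two-sample two-sided t-test per feature between TD and ASD rows.

    Only the given rows enter the test; pass training-subject indices to
    keep held-out data untouched.  Student's pooled-variance test by
    default (``equal_var=False`` switches to Welch's).
    """
    if labels is None:
        if not isinstance(fm, FeatureMatrix):
            raise ValueError("labels required when fm is a bare array")
        labels = fm.labels
    labels = np.asarray(labels)
    X = _rows_values(fm, rows)
    y = labels if rows is None else labels[np.asarray(rows)]
    a = X[y == "TD"]
    b = X[y == "ASD"]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"need >= 2 subjects per class, got TD={len(a)}, ASD={len(b)}"
        )
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    # identical class samples give 0/0; that is "no evidence": t=0, p=1
    t = np.nan_to_num(np.asarray(t), nan=0.0)
    p = np.where(np.isnan(p), 1.0, np.asarray(p))
    return SelectionResult(t_stats=t, p_values=p)


def select_by_threshold(sel: SelectionResult, threshold: float) -> SelectionResult:
    """Keep features with ``p < threshold``, ranked by ascending p.

    Ties in p are broken by ascending column index for determinism.  An
    empty selection is returned as-is; downstream consumers must handle it.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    p = sel.p_values
    candidates = np.flatnonzero(p < threshold)
    order = np.lexsort((candidates, p[candidates]))
    return SelectionResult(
        t_stats=sel.t_stats,
        p_values=p,
        threshold=threshold,
        selected_indices=candidates[order],
    )
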