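"""Re-derive scoring tables from a cohort by bootstrapped logistic regression.

The pipeline mirrors how the packaged tables were built:

1. continuous features are min-max scaled to [0, 1] on the full cohort;
2. logistic regression (maximum likelihood, negligible ridge for numerical
   stability) is fit on bootstrap resamples (n = 100 by default, sampling
   with replacement at the cohort size) and evaluated on the out-of-bag
   patients (AUC, accuracy, precision, recall at the 0.5 probability
   operating point);
3. coefficients are averaged across replicates and the scaling factors are
   folded back so the exported weights apply to raw feature values; the
   decision threshold on the score scale is minus the mean raw intercept;
4. features are chosen by a two-stage exhaustive search — every non-empty
   subset of the fractal features first, then, with that choice fixed,
   every subset of the clinical features — maximizing mean out-of-bag AUC,
   with ties resolved toward smaller subsets; candidates must pass a
   univariate screen (two-sample t-test for continuous features, Fisher's
   exact test for binary ones) at p < 0.05.

The cohort container is a pandas DataFrame with one row per patient.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import chain, combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .exceptions import ValidationError
from .scoring import ScoringTable

logger = logging.getLogger(__name__)

#: Inverse regularization strength: C = 1e8 is a ridge of 1e-8, i.e. plain
#: maximum likelihood up to numerical stabilization.
_LOGISTIC_C = 1e8
_SEPARATION_COEF_LIMIT = 15.0


@dataclass(frozen=True)
class ModelFitResult:
    """Averaged bootstrapped logistic fit on the raw feature scale."""

    features: tuple[str, ...]
    mean_weights: tuple[float, ...]
    threshold: float
    per_bootstrap: tuple[tuple[float, float, float, float], ...]  # AUC, acc, prec, rec
    mean_auc: float
    auc_ci: tuple[float, float]
    n_boot: int
    seed: int

    def weights_dict(self) -> dict[str, float]:
        return dict(zip(self.features, self.mean_weights))


@dataclass(frozen=True)
class SearchResult:
    selected_fractal: tuple[str, ...]
    selected_clinical: tuple[str, ...]
    objective: float
    audit: tuple[tuple[tuple[str, ...], float], ...]


def _binary_labels(cohort: pd.DataFrame, label: str, positive_label=None) -> np.ndarray:
    col = cohort[label]
    classes = sorted(col.unique(), key=str)
    if len(classes) != 2:
        raise ValidationError(
            f"label {label!r} must have exactly 2 classes, got {list(classes)}"
        )
    if positive_label is None:
        positive_label = classes[-1]
    return (col == positive_label).to_numpy(dtype=int)


def _is_binary(col: pd.Series) -> bool:
    return set(pd.unique(col)) <= {0, 1, 0.0, 1.0, False, True}


def feature_bounds(cohort: pd.DataFrame, features: Sequence[str]) -> dict[str, tuple[float, float]]:
    """Full-cohort min-max bounds per feature; binary 0/1 features get (0, 1)."""
    bounds = {}
    for f in features:
        if _is_binary(cohort[f]):
            bounds[f] = (0.0, 1.0)
        else:
            bounds[f] = (float(cohort[f].min()), float(cohort[f].max()))
    return bounds


def _scale_design(
    cohort: pd.DataFrame,
    features: Sequence[str],
    bounds: dict[str, tuple[float, float]],
) -> np.ndarray:
    cols = []
    for f in features:
        lo, hi = bounds[f]
        x = cohort[f].to_numpy(dtype=float)
        cols.append((x - lo) / (hi - lo) if hi > lo else np.zeros_like(x))
    return np.column_stack(cols)


def fit_logistic(
    cohort: pd.DataFrame,
    features: Sequence[str],
    label: str,
    positive_label=None,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> tuple[dict[str, float], float]:
    """Maximum-likelihood logistic fit on [0,1]-scaled continuous features.

    Returns per-scaled-feature weights and the intercept.  Constant features
    are dropped with a warning (weight 0); perfect or quasi-perfect
    separation is flagged with a warning but the fit is returned.
    """
    if cohort[list(features)].isna().any().any():
        raise ValidationError("modeled columns must not contain missing values")
    y = _binary_labels(cohort, label, positive_label)
    if y.min() == y.max():
        raise ValidationError(f"label {label!r} has a single class in this sample")
    if bounds is None:
        bounds = feature_bounds(cohort, features)
    kept = [f for f in features if bounds[f][1] > bounds[f][0] or _is_binary(cohort[f])]
    dropped = [f for f in features if f not in kept]
    for f in dropped:
        warnings.warn(f"dropping constant feature {f!r} from logistic fit", stacklevel=2)
    X = _scale_design(cohort, kept, bounds)
    clf = LogisticRegression(C=_LOGISTIC_C, solver="lbfgs", max_iter=2000, tol=1e-10)
    clf.fit(X, y)
    coefs = {f: float(w) for f, w in zip(kept, clf.coef_[0])}
    for f in dropped:
        coefs[f] = 0.0
    if coefs and max(abs(w) for w in coefs.values()) > _SEPARATION_COEF_LIMIT:
        warnings.warn(
            "very large logistic coefficients: data may be perfectly separated",
            stacklevel=2,
        )
    return {f: coefs[f] for f in features}, float(clf.intercept_[0])


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve = P(score+ > score-) + 0.5 P(tie)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValidationError("roc_auc requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _fold_to_raw(
    weights: dict[str, float],
    intercept: float,
    bounds: dict[str, tuple[float, float]],
) -> tuple[dict[str, float], float]:
    """Fold [0,1] scaling factors into the weights so they apply to raw values."""
    raw_w = {}
    raw_b = intercept
    for f, w in weights.items():
        lo, hi = bounds[f]
        span = hi - lo
        if span > 0:
            raw_w[f] = w / span
            raw_b -= w * lo / span
        else:
            raw_w[f] = 0.0
    return raw_w, raw_b


def bootstrap_model(
    cohort: pd.DataFrame,
    features: Sequence[str],
    label: str,
    n_boot: int = 100,
    seed: int = 0,
    positive_label=None,
    resample: bool = True,
) -> ModelFitResult:
    """Bootstrapped logistic model with out-of-bag evaluation.

    Each replicate refits on a with-replacement resample of the cohort
    (replicate seed = master seed + replicate index) and is evaluated on the
    out-of-bag patients; replicates whose resample or out-of-bag set is
    single-class are redrawn (at most ``10 * n_boot`` attempts overall).
    Weights are averaged across replicates on the raw scale; the threshold
    is minus the mean raw-scale intercept, so score > threshold is
    equivalent to fitted probability > 0.5 under the averaged model.

    ``resample=False`` disables resampling (each replicate fits the full
    cohort and is evaluated in-sample), giving an identity check against a
    single fit.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    features = list(features)
    y_all = _binary_labels(cohort, label, positive_label)
    if y_all.min() == y_all.max():
        raise ValidationError(f"label {label!r} has a single class")
    bounds = feature_bounds(cohort, features)
    n = len(cohort)
    raw_w_sum = np.zeros(len(features))
    raw_b_sum = 0.0
    metrics = []
    attempts = 0
    done = 0
    rep = 0
    while done < n_boot:
        if attempts >= 10 * n_boot:
            raise ValidationError(
                f"exceeded {10 * n_boot} resampling attempts without "
                f"{n_boot} two-class replicates"
            )
        rng = np.random.default_rng(seed + rep)
        rep += 1
        attempts += 1
        if resample:
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
        else:
            idx = np.arange(n)
            oob = np.arange(n)
        y_in, y_oob = y_all[idx], y_all[oob]
        if y_in.min() == y_in.max() or len(oob) == 0 or y_oob.min() == y_oob.max():
            logger.info("redrawing single-class bootstrap replicate %d", rep - 1)
            continue
        sample = cohort.iloc[idx]
        w, b = fit_logistic(sample, features, label, positive_label, bounds=bounds)
        raw_w, raw_b = _fold_to_raw(w, b, bounds)
        raw_w_sum += np.array([raw_w[f] for f in features])
        raw_b_sum += raw_b
        X_oob = _scale_design(cohort.iloc[oob], features, bounds)
        scores = X_oob @ np.array([w[f] for f in features]) + b
        auc = roc_auc(scores, y_oob)
        pred = (scores > 0).astype(int)
        tp = int(((pred == 1) & (y_oob == 1)).sum())
        fp = int(((pred == 1) & (y_oob == 0)).sum())
        fn = int(((pred == 0) & (y_oob == 1)).sum())
        acc = float((pred == y_oob).mean())
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        metrics.append((auc, acc, prec, rec))
        done += 1
    aucs = np.array([m[0] for m in metrics])
    mean_w = raw_w_sum / n_boot
    mean_b = raw_b_sum / n_boot
    return ModelFitResult(
        features=tuple(features),
        mean_weights=tuple(float(w) for w in mean_w),
        threshold=float(-mean_b),
        per_bootstrap=tuple(tuple(float(v) for v in m) for m in metrics),
        mean_auc=float(aucs.mean()),
        auc_ci=(float(np.percentile(aucs, 2.5)), float(np.percentile(aucs, 97.5))),
        n_boot=n_boot,
        seed=seed,
    )


def univariate_screen(cohort: pd.DataFrame, feature: str, label: str, positive_label=None) -> float:
    """Two-sided univariate test of association between one feature and the label.

    Binary 0/1 features use Fisher's exact test on the 2x2 table; continuous
    features use the equal-variance two-sample t-test.
    """
    y = _binary_labels(cohort, label, positive_label)
    x = cohort[feature].to_numpy(dtype=float)
    g0, g1 = x[y == 0], x[y == 1]
    if len(g0) == 0 or len(g1) == 0:
        raise ValidationError("both label groups must be non-empty")
    if _is_binary(cohort[feature]):
        table = [
            [int((g1 == 1).sum()), int((g1 == 0).sum())],
            [int((g0 == 1).sum()), int((g0 == 0).sum())],
        ]
        return float(sps.fisher_exact(table, alternative="two-sided")[1])
    if np.all(g0 == g0[0]) and np.all(g1 == g1[0]) and g0[0] == g1[0]:
        return 1.0
    t, p = sps.ttest_ind(g0, g1, equal_var=True)
    return float(p) if np.isfinite(p) else 1.0


def _subsets(names: Sequence[str], include_empty: bool):
    rng = range(0 if include_empty else 1, len(names) + 1)
    return chain.from_iterable(combinations(names, k) for k in rng)


def greedy_search(
    cohort: pd.DataFrame,
    fractal_features: Sequence[str],
    clinical_features: Sequence[str],
    label: str,
    n_boot: int = 100,
    seed: int = 0,
    positive_label=None,
    screen_alpha: float = 0.05,
) -> SearchResult:
    """Two-stage exhaustive feature search maximizing mean out-of-bag AUC.

    Stage 1 evaluates every non-empty subset of the fractal features; stage
    2, with the stage-1 winner fixed, evaluates every subset (including the
    empty one) of the clinical features.  Candidates are pre-filtered by the
    univariate screen at ``screen_alpha``; if no fractal feature passes, all
    are retained with a warning (stage 1 must select something).  Ties go to
    the smaller subset, then lexicographic order.
    """
    fractal_features = list(fractal_features)
    clinical_features = list(clinical_features)
    if not fractal_features:
        raise ValidationError("fractal feature list must be non-empty")
    if set(fractal_features) & set(clinical_features):
        raise ValidationError("fractal and clinical feature lists must be disjoint")

    def passes(f):
        return univariate_screen(cohort, f, label, positive_label) < screen_alpha

    frac_cands = [f for f in fractal_features if passes(f)]
    if not frac_cands:
        warnings.warn(
            "no fractal feature passes the univariate screen; retaining all",
            stacklevel=2,
        )
        frac_cands = fractal_features
    clin_cands = [f for f in clinical_features if passes(f)]

    audit: list[tuple[tuple[str, ...], float]] = []

    def evaluate(subset: tuple[str, ...]) -> float:
        fit = bootstrap_model(
            cohort, list(subset), label, n_boot=n_boot, seed=seed,
            positive_label=positive_label,
        )
        audit.append((subset, fit.mean_auc))
        return fit.mean_auc

    stage1 = [(sub, evaluate(sub)) for sub in _subsets(frac_cands, include_empty=False)]
    sel_frac, _ = min(
        stage1, key=lambda sa: (-sa[1], len(sa[0]), sa[0])
    )
    stage2 = [
        (sub, evaluate(sel_frac + sub)) for sub in _subsets(clin_cands, include_empty=True)
    ]
    sel_clin, objective = min(stage2, key=lambda sa: (-sa[1], len(sa[0]), sa[0]))
    return SearchResult(
        selected_fractal=tuple(sel_frac),
        selected_clinical=tuple(sel_clin),
        objective=float(objective),
        audit=tuple(audit),
    )


def export_scoring_table(
    fit: ModelFitResult,
    name: str,
    positive_class: str,
    negative_class: str,
) -> ScoringTable:
    """Serialize a fitted model as a raw-scale scoring table.

    Scoring the training cohort through the exported table reproduces the
    fitted model's per-patient classifications exactly (same linear rule).
    """
    return ScoringTable(
        name=name,
        terms=tuple(zip(fit.features, fit.mean_weights)),
        threshold=fit.threshold,
        positive_class=positive_class,
        negative_class=negative_class,
    )
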