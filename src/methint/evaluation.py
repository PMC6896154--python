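"""Case/control separability: LOOCV classification, ROC/AUC, PCA, strata.

The ROC curve is built by a threshold sweep over unique scores and the AUC by
the trapezoid rule, which (with tied scores grouped per threshold) equals the
midrank Mann-Whitney pairwise formula.  AUC significance uses the normal
approximation of the Mann-Whitney U with tie correction (one-sided,
H1: AUC > 0.5); an exact permutation alternative is available for small n.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)

DEFAULT_CLASSIFIER = {"kind": "random_forest", "n_trees": 500}


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# LOOCV scoring
# ---------------------------------------------------------------------------

def _fit_score(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    spec: Mapping,
    seed: int,
) -> float:
    kind = spec.get("kind", "random_forest")
    if kind == "random_forest":
        clf = RandomForestClassifier(
            n_estimators=int(spec.get("n_trees", 500)),
            max_features="sqrt",
            random_state=seed,
        )
        clf.fit(x_train, y_train)
        proba = clf.predict_proba(x_test.reshape(1, -1))[0]
        case_col = list(clf.classes_).index(1)
        return float(proba[case_col])  # vote fraction for the case class
    if kind == "nearest_centroid":
        mu_case = x_train[y_train == 1].mean(axis=0)
        mu_ctrl = x_train[y_train == 0].mean(axis=0)
        d_case = float(np.linalg.norm(x_test - mu_case))
        d_ctrl = float(np.linalg.norm(x_test - mu_ctrl))
        return d_ctrl - d_case  # higher = closer to the case centroid
    raise EvaluationError(f"unknown classifier kind: {kind!r}")


def loocv_scores(
    features: np.ndarray,
    labels: Sequence[int] | np.ndarray,
    classifier_spec: Mapping | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Leave-one-out case scores: sample i scored by a model never shown i.

    ``features`` is sample x feature; ``labels`` is 1 = case, 0 = control.
    Deterministic given seed and classifier_spec.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise EvaluationError("features must be sample x feature aligned to labels")
    if np.isnan(X).any():
        raise EvaluationError("features contain NaN; impute or drop first")
    counts = np.bincount(y, minlength=2)
    if counts[0] < 2 or counts[1] < 2:
        raise EvaluationError(
            "each class needs >= 2 samples so every training fold keeps both"
        )
    spec = dict(DEFAULT_CLASSIFIER if classifier_spec is None else classifier_spec)
    n = y.size
    scores = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        scores[i] = _fit_score(X[mask], y[mask], X[i], spec, seed)
        mask[i] = True
    return scores


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(
    scores: Sequence[float] | np.ndarray, labels: Sequence[int] | np.ndarray
) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) by threshold sweep, AUC by trapezoid.

    Tied scores collapse onto one ROC vertex, so the trapezoid area equals
    the midrank pairwise convention.  Curve starts at (0,0), ends at (1,1).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise EvaluationError("both classes must be present for ROC")
    order = np.argsort(-s, kind="mergesort")
    s_sorted, y_sorted = s[order], y[order]
    # one vertex per distinct threshold
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], s_sorted.size - 1]
    tp = np.cumsum(y_sorted == 1)[distinct]
    fp = np.cumsum(y_sorted == 0)[distinct]
    tpr = np.r_[0.0, tp / n1]
    fpr = np.r_[0.0, fp / n0]
    auc = float(np.trapezoid(tpr, fpr))
    points = np.column_stack([fpr, tpr])
    return points, auc


def auc_p_value(
    scores: Sequence[float] | np.ndarray,
    labels: Sequence[int] | np.ndarray,
    method: str = "normal",
    max_exact: int = 20,
) -> float:
    """One-sided p for H1: AUC > 0.5.

    ``method='normal'`` uses the Mann-Whitney U normal approximation with tie
    correction; ``method='exact'`` enumerates all label assignments (small n
    only) and is exact under exchangeability.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise EvaluationError("both classes must be present")
    _, auc = roc_auc(s, y)
    u = auc * n1 * n0

    if method == "exact":
        n = n1 + n0
        if n > max_exact:
            raise EvaluationError(f"exact permutation limited to n <= {max_exact}")
        count = 0
        total = 0
        for case_idx in itertools.combinations(range(n), n1):
            perm = np.zeros(n, dtype=int)
            perm[list(case_idx)] = 1
            _, a = roc_auc(s, perm)
            total += 1
            if a >= auc - 1e-12:
                count += 1
        return count / total
    if method != "normal":
        raise EvaluationError(f"unknown method {method!r}")

    n = n1 + n0
    mu = n1 * n0 / 2.0
    _, tie_counts = np.unique(s, return_counts=True)
    tie_term = np.sum(tie_counts.astype(float) ** 3 - tie_counts)
    if n > 1:
        sigma_sq = n1 * n0 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    else:  # pragma: no cover - guarded above
        sigma_sq = 0.0
    if sigma_sq <= 0:
        return 0.5  # all scores tied: no evidence either way
    z = (u - mu) / np.sqrt(sigma_sq)
    return float(stats.norm.sf(z))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAProjection:
    coordinates: np.ndarray  # sample x component
    variance_ratio: np.ndarray
    components: np.ndarray  # component x feature, orthonormal rows


def pca_project(features: np.ndarray, n_components: int = 2) -> PCAProjection:
    """Column-centered SVD projection, components by decreasing variance."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise EvaluationError("PCA needs >= 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    u, sv, vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, sv.size)
    total_var = float(np.sum(sv**2))
    ratio = (sv[:k] ** 2 / total_var) if total_var > 0 else np.zeros(k)
    return PCAProjection(u[:, :k] * sv[:k], ratio, vt[:k])


# ---------------------------------------------------------------------------
# stratified evaluation
# ---------------------------------------------------------------------------

def stratify_covariate(values: pd.Series, name: str) -> pd.Series:
    """Map raw covariate values to stratum levels.

    Age is dichotomized at 50 (``>50`` vs ``<=50``); stage III and IV merge
    into ``III_IV``; other covariates stratify on their observed levels.
    """
    if name == "age":
        return pd.Series(
            np.where(values.astype(float) > 50, ">50", "<=50"), index=values.index
        )
    if name == "stage":
        return values.astype(str).replace({"III": "III_IV", "IV": "III_IV"})
    return values.astype(str)


@dataclass
class StratumReport:
    auc: float
    p_value: float
    n: int
    n_case: int
    n_control: int


def stratified_evaluate(
    features: np.ndarray,
    labels: Sequence[int] | np.ndarray,
    covariate: pd.Series,
    covariate_name: str,
    classifier_spec: Mapping | None = None,
    seed: int = 0,
    min_per_class: int = 3,
) -> dict[str, StratumReport]:
    """LOOCV + ROC within each covariate stratum.

    Strata with fewer than ``min_per_class`` samples in either class are
    skipped with a warning.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    levels = stratify_covariate(covariate.reset_index(drop=True), covariate_name)
    reports: dict[str, StratumReport] = {}
    for level in sorted(levels.unique()):
        mask = (levels == level).to_numpy()
        n_case = int((y[mask] == 1).sum())
        n_ctrl = int((y[mask] == 0).sum())
        if n_case < min_per_class or n_ctrl < min_per_class:
            logger.warning(
                "stratum %s=%s skipped (%d case / %d control)",
                covariate_name, level, n_case, n_ctrl,
            )
            continue
        scores = loocv_scores(X[mask], y[mask], classifier_spec, seed)
        _, auc = roc_auc(scores, y[mask])
        p = auc_p_value(scores, y[mask])
        reports[str(level)] = StratumReport(auc, p, int(mask.sum()), n_case, n_ctrl)
    return reports


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    feature_set_name: str
    sample_ids: list[str]
    scores: np.ndarray
    roc_points: np.ndarray
    auc: float
    auc_p_value: float
    strata: dict[str, dict[str, StratumReport]] = field(default_factory=dict)
    pca: PCAProjection | None = None

    def to_dict(self) -> dict:
        out = {
            "feature_set": self.feature_set_name,
            "auc": self.auc,
            "auc_p_value": self.auc_p_value,
            "scores": {s: float(v) for s, v in zip(self.sample_ids, self.scores)},
            "strata": {
                cov: {
                    level: {
                        "auc": r.auc,
                        "p_value": r.p_value,
                        "n": r.n,
                        "n_case": r.n_case,
                        "n_control": r.n_control,
                    }
                    for level, r in levels.items()
                }
                for cov, levels in self.strata.items()
            },
        }
        if self.pca is not None:
            out["pca_variance_ratio"] = [float(v) for v in self.pca.variance_ratio]
        return out


def evaluate_feature_set(
    name: str,
    features: np.ndarray,
    labels: Sequence[int] | np.ndarray,
    sample_ids: Sequence[str],
    covariates: pd.DataFrame | None = None,
    stratify: Sequence[str] = (),
    classifier_spec: Mapping | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Full evaluation: LOOCV scores, ROC/AUC + p, PCA, optional strata."""
    scores = loocv_scores(features, labels, classifier_spec, seed)
    points, auc = roc_auc(scores, labels)
    p = auc_p_value(scores, labels)
    strata: dict[str, dict[str, StratumReport]] = {}
    if covariates is not None:
        for cov in stratify:
            if cov not in covariates.columns:
                logger.warning("covariate %s absent from sample sheet; skipped", cov)
                continue
            strata[cov] = stratified_evaluate(
                features, labels, covariates[cov], cov, classifier_spec, seed
            )
    return EvaluationReport(
        name, list(sample_ids), scores, points, auc, p, strata,
        pca_project(features) if np.asarray(features).shape[1] >= 1 else None,
    )
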