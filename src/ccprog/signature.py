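"""Signature building: enrichment filtering, SAM selection, NSC classification.

The prognostic signature is derived from the tumor-attributed shortlist in
three stages. Samples are first filtered to those whose tumor-cell fraction
strictly exceeds a threshold (default 50%), so that the relapse/non-relapse
contrast is computed on tumor-enriched tissue. A SAM-style moderated
d-statistic with permutation p-values then ranks the shortlist, and the top
genes (default 7, gated at p < 0.002) form the signature. Finally a nearest
shrunken centroid (NSC) classifier is trained on the signature, optionally
augmented with the Gleason sum as one extra feature — NSC standardizes every
feature by its pooled within-class deviation, so the clinical covariate enters
with the same weighting as each gene. Exhaustive cross-validation enumerates
every train/test split with fixed per-class training counts.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .io import CompositionTable

logger = logging.getLogger("ccprog")


# ---------------------------------------------------------------------------
# sample filtering


def filter_enriched(comp: CompositionTable, cell_type: str = "tumor", threshold: float = 0.5):
    """Sample ids whose ``cell_type`` fraction is strictly greater than ``threshold``."""
    frac = comp.fraction_of(cell_type)
    ids = [s for s, f in zip(comp.sample_ids, frac) if f > threshold]
    if not ids:
        warnings.warn(f"no samples with {cell_type} fraction > {threshold}")
    return ids


# ---------------------------------------------------------------------------
# SAM-style permutation selection


def _d_statistics(Y: np.ndarray, labels: np.ndarray, s0: float):
    """Moderated two-sample statistics for every gene (rows of Y).

    d = (mean_1 - mean_0) / (s + s0) with s the usual two-sample pooled
    standard deviation scaled by sqrt(1/n1 + 1/n0).
    """
    g1 = labels == 1
    g0 = ~g1
    n1, n0 = int(g1.sum()), int(g0.sum())
    m1 = Y[:, g1].mean(axis=1)
    m0 = Y[:, g0].mean(axis=1)
    ss1 = ((Y[:, g1] - m1[:, None]) ** 2).sum(axis=1)
    ss0 = ((Y[:, g0] - m0[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n0) * (ss1 + ss0) / (n1 + n0 - 2))
    return (m1 - m0) / (s + s0), s, m1, m0


def _choose_s0(diff: np.ndarray, s: np.ndarray) -> float:
    """Exchangeability constant minimizing the coefficient of variation of d.

    Candidates are the percentiles of s in 5% steps; for each, genes are
    binned into windows by s and the median absolute deviation of d is
    computed per window; the candidate with the smallest CV of these MADs
    wins. Falls back to the median of s when there are too few genes to form
    windows.
    """
    G = len(s)
    n_windows = min(100, max(2, G // 10))
    if G < 20:
        return float(np.median(s))
    edges = np.quantile(s, np.linspace(0, 1, n_windows + 1))
    window = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_windows - 1)
    candidates = np.percentile(s, np.arange(0, 101, 5))
    best_s0, best_cv = candidates[0], np.inf
    for s0 in candidates:
        d = diff / (s + s0)
        mads = np.array(
            [np.median(np.abs(d[window == w] - np.median(d[window == w])))
             for w in range(n_windows) if np.any(window == w)]
        )
        mean = mads.mean()
        if mean <= 0:
            continue
        cv = mads.std() / mean
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _permutation_matrix(n: int, n1: int, n_perm: int, rng) -> tuple[np.ndarray, bool]:
    """Boolean (B, n) matrix of group-1 memberships; exhaustive if feasible."""
    total = math.comb(n, n1)
    if total <= n_perm:
        L = np.zeros((total, n), dtype=bool)
        for b, idx in enumerate(combinations(range(n), n1)):
            L[b, list(idx)] = True
        return L, True
    L = np.zeros((n_perm, n), dtype=bool)
    for b in range(n_perm):
        L[b, rng.choice(n, size=n1, replace=False)] = True
    return L, False


def sam_screen(
    Y,
    group_labels,
    gene_ids=None,
    n_perm: int = 10000,
    seed: int = 0,
    s0: float | None = None,
) -> pd.DataFrame:
    """SAM-style selection: moderated d-statistics with permutation p-values.

    Parameters
    ----------
    Y : (genes, samples) log2 expression values (or an ExpressionMatrix).
    group_labels : binary vector; 1 = relapse group, 0 = non-relapse group.
    s0 : exchangeability constant; estimated by the CV-minimization rule when
        None. Pass 0 to recover the plain two-sample statistic.

    Returns a DataFrame ranked by \\|d\\| descending with columns gene_id, d,
    s, s0, perm_p, fold_change (anti-logged group-mean ratio, relapse over
    non-relapse). When the label-permutation space has at most ``n_perm``
    distinct assignments it is enumerated exhaustively and perm_p is the exact
    fraction of assignments with \\|d\\| at least as extreme (the observed
    labeling counts, so perm_p is in (0, 1]); otherwise ``n_perm`` random
    assignments are drawn and perm_p = (1 + #extreme) / (1 + n_perm).
    """
    if hasattr(Y, "values") and hasattr(Y, "gene_ids"):
        gene_ids = Y.gene_ids if gene_ids is None else gene_ids
        Y = Y.values
    Y = np.asarray(Y, dtype=float)
    labels = np.asarray(group_labels, dtype=float)
    if set(np.unique(labels)) - {0.0, 1.0}:
        raise ValueError("group labels must be binary 0/1")
    n1, n0 = int((labels == 1).sum()), int((labels == 0).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("each group needs at least 2 samples")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; permutation p-values will be coarse")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(Y.shape[0])]

    diff = Y[:, labels == 1].mean(axis=1) - Y[:, labels == 0].mean(axis=1)
    _, s, _, _ = _d_statistics(Y, labels.astype(int), 0.0)
    if s0 is None:
        s0 = _choose_s0(diff, s)
    d_obs, s, m1, m0 = _d_statistics(Y, labels.astype(int), s0)

    rng = np.random.default_rng(seed)
    n = Y.shape[1]
    L, exhaustive = _permutation_matrix(n, n1, n_perm, rng)
    B = L.shape[0]
    # vectorized permutation statistics from sufficient sums
    tot = Y.sum(axis=1)
    tot2 = (Y**2).sum(axis=1)
    S1 = Y @ L.T  # (G, B) group-1 sums
    Q1 = (Y**2) @ L.T
    M1 = S1 / n1
    M0 = (tot[:, None] - S1) / n0
    SS1 = Q1 - S1**2 / n1
    SS0 = (tot2[:, None] - Q1) - (tot[:, None] - S1) ** 2 / n0
    sp = np.sqrt((1.0 / n1 + 1.0 / n0) * np.maximum(SS1 + SS0, 0.0) / (n1 + n0 - 2))
    d_perm = (M1 - M0) / (sp + s0)
    extreme = (np.abs(d_perm) >= np.abs(d_obs)[:, None] - 1e-12).sum(axis=1)
    if exhaustive:
        perm_p = extreme / B
    else:
        perm_p = (1.0 + extreme) / (1.0 + B)

    out = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "d": d_obs,
            "s": s,
            "s0": s0,
            "perm_p": perm_p,
            "fold_change": 2.0 ** (m1 - m0),
        }
    )
    return out.reindex(np.abs(out["d"]).sort_values(ascending=False).index).reset_index(
        drop=True
    )


def select_top_genes(sam_result: pd.DataFrame, n_top: int = 7, p_threshold: float = 0.002):
    """The ``n_top`` genes by |d| among those passing the permutation-p gate."""
    passing = sam_result[sam_result["perm_p"] < p_threshold]
    return list(passing["gene_id"].head(n_top))


# ---------------------------------------------------------------------------
# nearest shrunken centroid


@dataclass
class NscModel:
    """Nearest-shrunken-centroid classifier (the PAM classification rule).

    Class centroids are soft-thresholded toward the overall centroid: the
    standardized difference d_jk = (c_jk - c_j) / (m_k (s_j + s0)) with
    m_k = sqrt(1/n_k - 1/n) is shrunk by ``delta``, and the shrunken centroid
    is c'_jk = c_j + m_k (s_j + s0) d'_jk. Classification minimizes
    sum_j (x_j - c'_jk)^2 / (s_j + s0)^2 - 2 log pi_k.
    """

    feature_ids: list
    classes: np.ndarray
    overall_centroid: np.ndarray
    class_centroids: np.ndarray  # K x p, unshrunken
    shrunken_centroids: np.ndarray
    shrunken_differences: np.ndarray
    delta: float
    class_priors: np.ndarray
    pooled_sd: np.ndarray
    s0: float
    m_k: np.ndarray

    @property
    def n_active_features(self) -> int:
        return int(np.any(self.shrunken_differences != 0, axis=0).sum())

    def to_dict(self) -> dict:
        return {
            "feature_ids": list(self.feature_ids),
            "classes": self.classes.tolist(),
            "overall_centroid": self.overall_centroid.tolist(),
            "class_centroids": self.class_centroids.tolist(),
            "shrunken_centroids": self.shrunken_centroids.tolist(),
            "shrunken_differences": self.shrunken_differences.tolist(),
            "delta": self.delta,
            "class_priors": self.class_priors.tolist(),
            "pooled_sd": self.pooled_sd.tolist(),
            "s0": self.s0,
            "m_k": self.m_k.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NscModel":
        return cls(
            feature_ids=list(d["feature_ids"]),
            classes=np.asarray(d["classes"]),
            overall_centroid=np.asarray(d["overall_centroid"], dtype=float),
            class_centroids=np.asarray(d["class_centroids"], dtype=float),
            shrunken_centroids=np.asarray(d["shrunken_centroids"], dtype=float),
            shrunken_differences=np.asarray(d["shrunken_differences"], dtype=float),
            delta=float(d["delta"]),
            class_priors=np.asarray(d["class_priors"], dtype=float),
            pooled_sd=np.asarray(d["pooled_sd"], dtype=float),
            s0=float(d["s0"]),
            m_k=np.asarray(d["m_k"], dtype=float),
        )


def _nsc_fit_at_delta(X, y, classes, delta):
    n, p = X.shape
    K = len(classes)
    nk = np.array([(y == c).sum() for c in classes])
    overall = X.mean(axis=0)
    cent = np.vstack([X[y == c].mean(axis=0) for c in classes])
    within_ss = np.zeros(p)
    for k, c in enumerate(classes):
        within_ss += ((X[y == c] - cent[k]) ** 2).sum(axis=0)
    sd = np.sqrt(within_ss / (n - K))
    s0 = float(np.median(sd))
    mk = np.sqrt(1.0 / nk - 1.0 / n)
    djk = (cent - overall) / (mk[:, None] * (sd + s0))
    shrunk = np.sign(djk) * np.maximum(np.abs(djk) - delta, 0.0)
    cent_shrunk = overall + mk[:, None] * (sd + s0) * shrunk
    priors = nk / n
    return overall, cent, cent_shrunk, shrunk, priors, sd, s0, mk


def _stratified_folds(y, classes, n_folds):
    """Deterministic round-robin assignment of each class's samples to folds."""
    folds = np.zeros(len(y), dtype=int)
    for c in classes:
        idx = np.flatnonzero(y == c)
        folds[idx] = np.arange(len(idx)) % n_folds
    return folds


def nsc_train(
    X,
    labels,
    feature_ids=None,
    delta=None,
    delta_grid=None,
    n_grid: int = 30,
) -> NscModel:
    """Train a nearest-shrunken-centroid model.

    The shrinkage threshold is ``delta`` if given; otherwise it is chosen from
    ``delta_grid`` (default: 30 points from 0 to the largest standardized
    centroid difference) by stratified inner cross-validation minimizing the
    misclassification count, ties resolved toward the larger (sparser) delta.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    nk = np.array([(y == c).sum() for c in classes])
    if np.any(nk < 2):
        raise ValueError("each class needs at least 2 samples")
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(X.shape[1])]

    if delta is None:
        if delta_grid is None:
            d0 = _nsc_fit_at_delta(X, y, classes, 0.0)[3]
            delta_grid = np.linspace(0.0, float(np.abs(d0).max()), n_grid)
        n_folds = int(min(5, nk.min()))
        folds = _stratified_folds(y, classes, n_folds)
        errors = np.zeros(len(delta_grid))
        for f in range(n_folds):
            tr, te = folds != f, folds == f
            for i, dlt in enumerate(delta_grid):
                model = _build_model(X[tr], y[tr], classes, float(dlt), feature_ids)
                pred, _ = nsc_predict(model, X[te])
                errors[i] += int((pred != y[te]).sum())
        best = np.min(errors)
        delta = float(np.max(np.asarray(delta_grid)[errors == best]))
    return _build_model(X, y, classes, float(delta), feature_ids)


def _build_model(X, y, classes, delta, feature_ids):
    overall, cent, cent_shrunk, shrunk, priors, sd, s0, mk = _nsc_fit_at_delta(
        X, y, classes, delta
    )
    return NscModel(
        feature_ids=list(feature_ids),
        classes=classes,
        overall_centroid=overall,
        class_centroids=cent,
        shrunken_centroids=cent_shrunk,
        shrunken_differences=shrunk,
        delta=delta,
        class_priors=priors,
        pooled_sd=sd,
        s0=s0,
        m_k=mk,
    )


def nsc_predict(model: NscModel, X, feature_ids=None):
    """Classify samples; returns (labels, per-class discriminant scores).

    Lower score is better; exact ties break toward the first class.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if feature_ids is not None:
        if set(model.feature_ids) - set(feature_ids):
            missing = sorted(set(model.feature_ids) - set(feature_ids))
            raise KeyError(f"missing feature(s) for prediction: {missing}")
        order = [list(feature_ids).index(f) for f in model.feature_ids]
        X = X[:, order]
    if X.shape[1] != len(model.feature_ids):
        raise ValueError("feature count does not match the model")
    denom = (model.pooled_sd + model.s0) ** 2
    scores = np.stack(
        [
            ((X - model.shrunken_centroids[k]) ** 2 / denom).sum(axis=1)
            - 2.0 * np.log(model.class_priors[k])
            for k in range(len(model.classes))
        ],
        axis=1,
    )
    return model.classes[np.argmin(scores, axis=1)], scores


def augment_with_clinical(X, feature_ids, gleason, feature_name: str = "gleason"):
    """Append a clinical covariate (Gleason sum) as one extra NSC feature.

    Samples with a missing value are excluded (mask returned). NSC's
    per-feature standardization gives the appended covariate the same
    weighting as each gene.
    """
    X = np.asarray(X, dtype=float)
    g = np.asarray(gleason, dtype=float)
    keep = ~np.isnan(g)
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} sample(s) with missing {feature_name}")
    Xa = np.column_stack([X[keep], g[keep]])
    return Xa, list(feature_ids) + [feature_name], keep


# ---------------------------------------------------------------------------
# exhaustive cross-validation


@dataclass
class CvReport:
    n_rounds: int
    predictions: list  # (round, test_index, predicted, observed) tuples
    accuracy: float
    sensitivity: float
    specificity: float


@dataclass
class ClassificationMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    accuracy_counts: tuple
    sensitivity_counts: tuple
    specificity_counts: tuple

    def __str__(self):
        def fmt(v, c):
            if np.isnan(v):
                return f"undefined (0 of 0)"
            return f"{100 * v:.0f}% ({c[0]} of {c[1]})"

        return (
            f"accuracy {fmt(self.accuracy, self.accuracy_counts)}, "
            f"sensitivity {fmt(self.sensitivity, self.sensitivity_counts)}, "
            f"specificity {fmt(self.specificity, self.specificity_counts)}"
        )


def classification_metrics(predicted, observed, positive_label=1) -> ClassificationMetrics:
    """Accuracy / sensitivity / specificity with 'x of y' counts.

    Sensitivity is recall on the positive (relapse) class. A metric whose
    denominator is empty is reported as NaN (undefined), never 0.
    """
    pred = np.asarray(predicted)
    obs = np.asarray(observed)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed must be aligned")
    pos = obs == positive_label
    neg = ~pos
    correct = pred == obs
    def ratio(num, den):
        return (num / den if den else float("nan")), (int(num), int(den))
    acc, acc_c = ratio(int(correct.sum()), len(obs))
    sens, sens_c = ratio(int(correct[pos].sum()), int(pos.sum()))
    spec, spec_c = ratio(int(correct[neg].sum()), int(neg.sum()))
    return ClassificationMetrics(acc, sens, spec, acc_c, sens_c, spec_c)


def n_cv_rounds(samples_by_class: dict, train_counts: dict) -> int:
    """Closed-form number of distinct splits: product of binomial coefficients."""
    total = 1
    for cls, n in samples_by_class.items():
        k = train_counts[cls]
        if k > n:
            raise ValueError(f"train count {k} exceeds class size {n} for {cls!r}")
        total *= math.comb(n, k)
    return total


def enumerate_splits(class_indices: dict, train_counts: dict):
    """All train/test index splits, lexicographic within and across classes."""
    classes = list(class_indices)
    per_class = [
        list(combinations(sorted(class_indices[c]), train_counts[c])) for c in classes
    ]

    def rec(level, chosen):
        if level == len(classes):
            train = [i for sub in chosen for i in sub]
            all_idx = sorted(i for c in classes for i in class_indices[c])
            test = [i for i in all_idx if i not in set(train)]
            yield sorted(train), test
            return
        for sub in per_class[level]:
            yield from rec(level + 1, chosen + [sub])

    yield from rec(0, [])


def exhaustive_cv(
    X,
    labels,
    train_counts: dict,
    trainer,
    predictor,
    positive_label=1,
    cap: int = 10**6,
) -> CvReport:
    """Train/test on every split with the given per-class training counts.

    ``trainer(X_train, y_train)`` returns a model; ``predictor(model, X_test)``
    returns predicted labels. Metrics are pooled over all rounds (sensitivity =
    recall on ``positive_label``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    class_indices = {c: np.flatnonzero(y == c).tolist() for c in np.unique(y)}
    counts = {c: len(v) for c, v in class_indices.items()}
    missing = set(counts) - set(train_counts)
    if missing:
        raise ValueError(f"train_counts missing for class(es): {sorted(missing)}")
    total = n_cv_rounds(counts, train_counts)
    if total > cap:
        raise ValueError(
            f"{total} rounds exceed the cap of {cap}; use a sampled cross-validation instead"
        )
    if all(train_counts[c] == counts[c] for c in counts):
        raise ValueError("training counts equal class sizes: every test set would be empty")
    preds, obs, records = [], [], []
    for r, (train, test) in enumerate(enumerate_splits(class_indices, train_counts)):
        model = trainer(X[train], y[train])
        p = predictor(model, X[test])
        for i, t in enumerate(test):
            records.append((r, t, p[i], y[t]))
        preds.extend(p)
        obs.extend(y[test])
    m = classification_metrics(np.asarray(preds), np.asarray(obs), positive_label)
    return CvReport(
        n_rounds=total,
        predictions=records,
        accuracy=m.accuracy,
        sensitivity=m.sensitivity,
        specificity=m.specificity,
    )
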