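"""Anchor-set enrichment classifier with an FPR-targeted threshold.

The central statistic is the enrichment score

    S = mean_log2_ratio * (-log10 q)

combining effect size and significance from the bait-vs-control contrast.
A one-dimensional logistic regression is trained on curated anchor sets —
positives that must be enriched (e.g. complex members of the bait) and
negatives that must not be (e.g. mitochondrial-matrix proteins for a
cytosolic/nuclear bait) — and assessed by repeated stratified 10-fold
cross-validation with ROC analysis.  The deployed decision rule is a
score threshold chosen so that the false-positive rate on the anchor
negatives is closest to a target (default 0.05); because the logistic is
monotone in S, score thresholding and probability thresholding coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "AnchorSets",
    "ScoreTable",
    "ClassifierFit",
    "CVSummary",
    "compute_enrichment_scores",
    "fit_logistic_1d",
    "crossvalidate",
    "roc_auc",
    "select_fpr_threshold",
    "fit_enrichment_classifier",
    "call_enriched",
    "call_enriched_by_cutoff",
]


@dataclass(frozen=True)
class AnchorSets:
    """Curated positive and negative training protein sets."""

    positives: frozenset[str]
    negatives: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "positives", frozenset(self.positives))
        object.__setattr__(self, "negatives", frozenset(self.negatives))
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"anchor sets overlap: {sorted(overlap)[:5]} ...")

    def restrict(self, ids) -> "AnchorSets":
        ids = set(ids)
        return AnchorSets(self.positives & ids, self.negatives & ids)


@dataclass
class ScoreTable:
    """Per-protein enrichment scores S plus bookkeeping of drops."""

    scores: pd.Series
    n_dropped: int = 0
    meta: dict = field(default_factory=dict)


@dataclass
class CVSummary:
    mean_auc: float
    sd_auc: float
    fold_aucs: np.ndarray
    n_folds: int
    n_repeats: int
    seed: int


@dataclass
class ClassifierFit:
    """Fitted 1-D logistic model plus the deployed score threshold."""

    intercept: float
    slope: float
    threshold: float
    achieved_fpr: float
    target_fpr: float
    cv: CVSummary | None = None


def compute_enrichment_scores(contrast) -> ScoreTable:
    """S = mean_log2_ratio * (-log10 q) per protein.

    Proteins lacking either the ratio or the q-value are dropped and
    counted.  q-values of exactly zero are clamped to the smallest
    positive normal float (recorded in the metadata) so that S stays
    finite while q = 0 proteins remain the most significant.
    """
    tab = contrast.table
    ok = tab["mean_log2_ratio"].notna() & tab["q_value"].notna()
    mlr = tab.loc[ok, "mean_log2_ratio"].to_numpy(dtype=float)
    q = tab.loc[ok, "q_value"].to_numpy(dtype=float)
    clamp = None
    if (q == 0).any():
        clamp = float(np.finfo(float).tiny)
        q = np.maximum(q, clamp)
    s = mlr * (-np.log10(q))
    return ScoreTable(
        scores=pd.Series(s, index=tab.index[ok], name="enrichment_score"),
        n_dropped=int((~ok).sum()),
        meta={"q_zero_clamp": clamp, "log_base": 10},
    )


def _anchor_xy(scores: pd.Series, anchors: AnchorSets):
    anchors = anchors.restrict(scores.index)
    if not anchors.positives or not anchors.negatives:
        raise ValueError("an anchor class is empty after intersecting with "
                         "the scored proteins")
    ids = sorted(anchors.positives) + sorted(anchors.negatives)
    x = scores.loc[ids].to_numpy(dtype=float)
    y = np.array([1] * len(anchors.positives) + [0] * len(anchors.negatives))
    return x, y, anchors


def fit_logistic_1d(scores: pd.Series, anchors: AnchorSets,
                    C: float = 1e6) -> tuple[float, float]:
    """Maximum-likelihood 1-D logistic fit P(pos|S) = expit(a + b*S).

    A tiny ridge penalty (large ``C``) keeps separable anchor sets from
    diverging; the fit is deterministic given its inputs.
    """
    x, y, _ = _anchor_xy(scores, anchors)
    model = LogisticRegression(C=C, solver="lbfgs", tol=1e-12, max_iter=50_000)
    model.fit(x[:, None], y)
    return float(model.intercept_[0]), float(model.coef_[0, 0])


def roc_auc(pos_scores, neg_scores) -> tuple[pd.DataFrame, float]:
    """ROC curve and AUC by the rank (Mann-Whitney) formula, ties as 1/2.

    ROC points are computed at every distinct score threshold (plus the
    all-call and no-call endpoints).
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be nonempty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    auc = (ranks[:pos.size].sum() - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size)

    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    points = [(0.0, 0.0, np.inf)]
    for t in thresholds:
        points.append(((neg >= t).mean(), (pos >= t).mean(), t))
    roc = pd.DataFrame(points, columns=["fpr", "tpr", "threshold"])
    return roc, float(auc)


def crossvalidate(scores: pd.Series, anchors: AnchorSets, n_folds: int = 10,
                  n_repeats: int = 30, seed: int = 0) -> CVSummary:
    """Repeated stratified k-fold CV of the 1-D logistic classifier.

    Each repeat draws a fresh stratified fold assignment from a child seed
    of ``seed``; per held-out fold the ROC AUC is recorded and the mean
    and SD over all repeats x folds are reported.
    """
    x, y, anchors = _anchor_xy(scores, anchors)
    n_pos, n_neg = int(y.sum()), int((y == 0).sum())
    if min(n_pos, n_neg) < n_folds:
        raise ValueError(
            f"smallest anchor class has {min(n_pos, n_neg)} members, fewer "
            f"than n_folds={n_folds}; use fewer folds")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_repeats) % (2**31)
    aucs = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=int(child_seeds[rep]))
        for train, test in skf.split(x[:, None], y):
            model = LogisticRegression(C=1e6, solver="lbfgs", tol=1e-10,
                                       max_iter=50_000)
            model.fit(x[train, None], y[train])
            decision = model.decision_function(x[test, None])
            _, auc = roc_auc(decision[y[test] == 1], decision[y[test] == 0])
            aucs.append(auc)
    aucs = np.array(aucs)
    return CVSummary(mean_auc=float(aucs.mean()), sd_auc=float(aucs.std(ddof=1)),
                     fold_aucs=aucs, n_folds=n_folds, n_repeats=n_repeats,
                     seed=seed)


def select_fpr_threshold(scores: pd.Series, anchors: AnchorSets,
                         target_fpr: float = 0.05) -> tuple[float, float]:
    """Score cutoff whose anchor-negative FPR is closest to the target.

    Candidate thresholds are the distinct anchor scores plus +inf;
    FPR(t) = #{negatives with S >= t} / #negatives.  Ties in
    |FPR - target| break toward the higher threshold (fewer calls), except
    that +inf is only chosen when no finite candidate attains the minimum
    — the top finite score always matches +inf's FPR of the no-call rule,
    and a classifier that can never call its own top-scoring anchors would
    be useless.
    """
    x, y, _ = _anchor_xy(scores, anchors)
    neg = x[y == 0]
    candidates = np.append(np.unique(x), np.inf)
    fprs = (neg[None, :] >= candidates[:, None]).mean(axis=1)
    dist = np.abs(fprs - target_fpr)
    best = dist <= dist.min() + 1e-12  # tolerate float noise so true ties tie
    finite_best = best & np.isfinite(candidates)
    pool = finite_best if finite_best.any() else best
    idx = np.flatnonzero(pool)[-1]  # candidates ascend, so last = highest t
    return float(candidates[idx]), float(fprs[idx])


def fit_enrichment_classifier(scores: ScoreTable | pd.Series,
                              anchors: AnchorSets, target_fpr: float = 0.05,
                              n_folds: int = 10, n_repeats: int = 30,
                              seed: int = 0, run_cv: bool = True) -> ClassifierFit:
    """Fit, cross-validate, and select the FPR-targeted threshold.

    CV estimates performance; the deployed threshold is selected on the
    full anchor set afterwards.
    """
    s = scores.scores if isinstance(scores, ScoreTable) else scores
    a, b = fit_logistic_1d(s, anchors)
    cv = crossvalidate(s, anchors, n_folds, n_repeats, seed) if run_cv else None
    threshold, achieved = select_fpr_threshold(s, anchors, target_fpr)
    return ClassifierFit(intercept=a, slope=b, threshold=threshold,
                         achieved_fpr=achieved, target_fpr=target_fpr, cv=cv)


def call_enriched(scores: ScoreTable | pd.Series, fit: ClassifierFit,
                  truth_labels: pd.Series | None = None) -> pd.DataFrame:
    """Apply the deployed threshold to every scored protein.

    A protein is called enriched iff S >= threshold (boundary inclusive).
    Probabilities come from the fitted logistic.  If ``truth_labels`` is
    given, it is carried into the output for stratified summaries.
    """
    s = scores.scores if isinstance(scores, ScoreTable) else scores
    prob = 1.0 / (1.0 + np.exp(-(fit.intercept + fit.slope * s.to_numpy())))
    out = pd.DataFrame({
        "score": s,
        "probability": prob,
        "enriched": s.to_numpy() >= fit.threshold,
    }, index=s.index)
    if truth_labels is not None:
        out["truth_label"] = truth_labels.reindex(s.index)
    return out


def call_enriched_by_cutoff(contrast, fc_cutoff: float = 1.0,
                            q_cutoff: float = 0.05) -> pd.DataFrame:
    """Fixed-cutoff alternative: log2FC strictly above and q strictly below."""
    tab = contrast.table
    enriched = (tab["mean_log2_ratio"] > fc_cutoff) & (tab["q_value"] < q_cutoff)
    return pd.DataFrame({
        "mean_log2_ratio": tab["mean_log2_ratio"],
        "q_value": tab["q_value"],
        "enriched": enriched.fillna(False),
    }, index=tab.index)
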