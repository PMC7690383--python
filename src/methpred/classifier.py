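"""Marker selection, DLDA training, LOOCV and cross-platform recalibration.

The classifier is a diagonal linear discriminant: with per-marker class means
mu_pCR,j / mu_pIR,j and pooled within-class variances s2_j, the score of a
sample x is S(x) = sum_j w_j x_j with w_j = (mu_pCR,j - mu_pIR,j) / s2_j, and
the decision threshold tau = sum_j w_j (mu_pCR,j + mu_pIR,j) / 2 — the
Gaussian Bayes rule with shared diagonal covariance and equal class priors.
An explicit orientation flag records which side of tau is called pCR, because
a published model may be stated with either sign convention.

Candidate markers are ranked by per-probe AUC (Mann-Whitney identity, ties
counted one half, orientation-free as max(AUC, 1-AUC)); the top_k survivors
pass through forward-backward stepwise linear regression of the 0/1 response
to drop redundant probes. Performance is estimated by leave-one-out
cross-validation, either refitting only the DLDA weights per fold
(classifier_only, the workflow a fixed published panel implies) or rerunning
selection inside each fold (nested, the unbiased variant).

Moving the model to a new measurement scale (e.g. microarray beta values to
pyrosequencing percent) keeps the weights and rescans the threshold over
midpoints of adjacent observed scores for best overall accuracy.

Samples with any missing marker are not imputed: prediction returns an
explicit no-call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

from .formats_io import ARRAY_SCALE, PYRO_SCALE, BetaMatrix, get_logger

__all__ = [
    "ClassifierModel",
    "EvalResult",
    "POSITIVE_CLASS",
    "NEGATIVE_CLASS",
    "NO_CALL",
    "probe_auc",
    "select_features",
    "dlda_train",
    "score",
    "loocv",
    "recalibrate_threshold",
    "evaluate",
    "published_array_model",
]

_log = get_logger(__name__)

POSITIVE_CLASS = "pCR"
NEGATIVE_CLASS = "pIR"
NO_CALL = "no_call"

#: The published three-CpG array-scale model: Score = -19.3 * beta_A
#: - 11.2 * beta_B - 24.6 * beta_C, response threshold -35.9. The pCR side of
#: the cut is ambiguous as printed, so the orientation is a datum the caller
#: sets; the default follows the reported pIR hypomethylation at all three
#: CpGs (lower beta with negative weights -> higher score -> pIR side high).
_PUBLISHED_MODEL_FILE = Path(__file__).parent / "data" / "published_model.json"


@dataclass(frozen=True)
class ClassifierModel:
    """Linear marker panel: ordered probes, weights, threshold, scale, orientation."""

    probe_ids: tuple
    weights: tuple
    threshold: float
    scale: str = ARRAY_SCALE
    orientation: str = "pCR_high"

    def __post_init__(self) -> None:
        if len(self.probe_ids) != len(self.weights) or len(self.probe_ids) < 1:
            raise ValueError("need equally many probe ids and weights, at least one")
        if self.orientation not in ("pCR_high", "pCR_low"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.scale not in (ARRAY_SCALE, PYRO_SCALE):
            raise ValueError(f"unknown scale {self.scale!r}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "probe_ids": list(self.probe_ids),
                    "weights": list(self.weights),
                    "threshold": self.threshold,
                    "scale": self.scale,
                    "orientation": self.orientation,
                },
                fh,
                indent=2,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path, orientation: str | None = None) -> "ClassifierModel":
        with open(path) as fh:
            d = json.load(fh)
        if orientation is not None:
            d["orientation"] = orientation
        return cls(
            probe_ids=tuple(d["probe_ids"]),
            weights=tuple(float(w) for w in d["weights"]),
            threshold=float(d["threshold"]),
            scale=d["scale"],
            orientation=d["orientation"],
        )


def published_array_model(orientation: str = "pCR_high") -> ClassifierModel:
    """The published array-scale model, importable with either orientation."""
    return ClassifierModel.from_json(_PUBLISHED_MODEL_FILE, orientation=orientation)


@dataclass
class EvalResult:
    """Per-sample scores and labels with confusion counts and summary metrics."""

    scores: pd.Series
    predicted: pd.Series
    true: pd.Series
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    auc: float | None
    n_no_call: int = 0

    @property
    def accuracy(self) -> float | None:
        n = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / n if n else None


def probe_auc(values, labels, positive: str = POSITIVE_CLASS, directed: bool = False) -> float:
    """Mann-Whitney AUC of one marker: P(value_positive > value_negative), ties half.

    With ``directed=False`` (the ranking convention) the orientation-free
    max(AUC, 1 - AUC) is returned.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    pos = v[lab == positive]
    neg = v[lab != positive]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    auc = u / (len(pos) * len(neg))
    return float(auc if directed else max(auc, 1.0 - auc))


def _stepwise_ols(
    y: np.ndarray,
    x: pd.DataFrame,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> list[str]:
    """Forward-backward stepwise OLS of a 0/1 response; returns entry-ordered columns."""
    included: list[str] = []
    while True:
        changed = False
        candidates = [c for c in x.columns if c not in included]
        if candidates:
            pvals = {}
            for c in candidates:
                design = sm.add_constant(x[included + [c]])
                # a candidate collinear with the current model carries no
                # independent information; skip it
                if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
                    continue
                model = sm.OLS(y, design).fit()
                pvals[c] = model.pvalues[c]
            if pvals:
                best = min(pvals, key=pvals.get)
                if pvals[best] <= p_enter:
                    included.append(best)
                    changed = True
        if included:
            model = sm.OLS(y, sm.add_constant(x[included])).fit()
            worst = model.pvalues.drop("const").idxmax()
            if model.pvalues[worst] >= p_remove:
                included.remove(worst)
                changed = True
        if not changed:
            return included


def select_features(
    candidates,
    bm: BetaMatrix,
    labels: pd.Series,
    top_k: int = 10,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> list[str]:
    """Rank candidates by AUC, keep the top_k, drop redundant probes stepwise.

    ``labels`` maps sample id to class; the AUC is orientation-free. Returns
    the retained probes in stepwise entry order (empty list, with a warning,
    when nothing passes the entry criterion).
    """
    candidates = [c for c in candidates if c in bm.probe_ids]
    lab = labels.reindex(bm.sample_ids)
    aucs = {
        c: probe_auc(bm.values.loc[c], lab.to_numpy()) for c in candidates
    }
    ranked = sorted(candidates, key=lambda c: (-aucs[c], c))[:top_k]
    if not ranked:
        _log.warning("no candidate probes available for selection")
        return []
    y = (lab == POSITIVE_CLASS).astype(float).to_numpy()
    x = bm.values.loc[ranked].T
    kept = _stepwise_ols(y, x, p_enter=p_enter, p_remove=p_remove)
    if not kept:
        _log.warning("no probe passed the stepwise entry criterion (p <= %.3g)", p_enter)
    return kept


def dlda_train(bm: BetaMatrix, labels: pd.Series, markers=None) -> ClassifierModel:
    """Fit the diagonal LDA rule on the given markers (all probes by default).

    Weights w_j = (mu_pCR,j - mu_pIR,j) / s2_pool,j; threshold at the score of
    the per-marker class-mean midpoint; orientation fixed so the pCR class
    mean scores on the pCR side. Equal class priors.
    """
    markers = list(markers) if markers is not None else list(bm.probe_ids)
    lab = labels.reindex(bm.sample_ids)
    pos_samples = lab.index[lab == POSITIVE_CLASS]
    neg_samples = lab.index[lab == NEGATIVE_CLASS]
    if len(pos_samples) < 2 or len(neg_samples) < 2:
        raise ValueError("each class needs at least 2 samples")
    xp = bm.values.loc[markers, pos_samples].to_numpy(dtype=float)
    xn = bm.values.loc[markers, neg_samples].to_numpy(dtype=float)
    mu_p = xp.mean(axis=1)
    mu_n = xn.mean(axis=1)
    n_p, n_n = xp.shape[1], xn.shape[1]
    s2 = ((n_p - 1) * xp.var(axis=1, ddof=1) + (n_n - 1) * xn.var(axis=1, ddof=1)) / (
        n_p + n_n - 2
    )
    zero = s2 <= 0
    if zero.any():
        raise ValueError(f"zero pooled variance for marker {markers[int(np.argmax(zero))]!r}")
    w = (mu_p - mu_n) / s2
    if np.all(w == 0):
        _log.warning("degenerate model: equal class means, all weights zero")
    tau = float(np.sum(w * (mu_p + mu_n) / 2.0))
    pos_score = float(np.sum(w * mu_p))
    orientation = "pCR_high" if pos_score >= tau else "pCR_low"
    return ClassifierModel(
        probe_ids=tuple(markers),
        weights=tuple(float(x) for x in w),
        threshold=tau,
        scale=bm.scale,
        orientation=orientation,
    )


def score(model: ClassifierModel, x) -> tuple[float, str]:
    """Score one sample and classify it; any missing marker yields a no-call.

    ``x`` may be a mapping/Series keyed by probe id or a sequence ordered like
    ``model.probe_ids``, on the model's scale.
    """
    if isinstance(x, (pd.Series, dict)):
        vec = np.array([dict(x).get(p, np.nan) for p in model.probe_ids], dtype=float)
    else:
        vec = np.asarray(x, dtype=float)
        if vec.shape != (len(model.probe_ids),):
            raise ValueError("input length does not match model markers")
    if np.isnan(vec).any():
        return float("nan"), NO_CALL
    s = float(np.dot(model.weights, vec))
    if model.orientation == "pCR_high":
        label = POSITIVE_CLASS if s > model.threshold else NEGATIVE_CLASS
    else:
        label = POSITIVE_CLASS if s < model.threshold else NEGATIVE_CLASS
    return s, label


def _predict_matrix(model: ClassifierModel, bm: BetaMatrix) -> tuple[pd.Series, pd.Series]:
    if bm.scale != model.scale:
        raise ValueError(f"input scale {bm.scale!r} does not match model scale {model.scale!r}")
    scores, labels = {}, {}
    sub = bm.values.reindex(list(model.probe_ids))
    for sid in bm.sample_ids:
        s, lab = score(model, sub[sid].to_numpy())
        scores[sid] = s
        labels[sid] = lab
    return pd.Series(scores, name="score"), pd.Series(labels, name="predicted")


def predict(model: ClassifierModel, bm: BetaMatrix) -> pd.DataFrame:
    """Score every sample of a matrix on the model's scale."""
    s, lab = _predict_matrix(model, bm)
    return pd.DataFrame({"score": s, "predicted": lab})


def loocv(
    bm: BetaMatrix,
    labels: pd.Series,
    markers=None,
    mode: str = "classifier_only",
    candidates=None,
    top_k: int = 10,
    usage_hook=None,
) -> EvalResult:
    """Leave-one-out cross-validation of the DLDA panel.

    mode="classifier_only" refits the DLDA weights per fold on fixed markers;
    mode="nested" reruns AUC ranking + stepwise selection inside each fold
    (requires ``candidates``). Folds that would leave a class with fewer than
    two training samples are skipped with a warning. ``usage_hook``, if given,
    is called with the training sample ids of each fold (instrumentation for
    leakage checks).
    """
    if mode not in ("classifier_only", "nested"):
        raise ValueError(f"unknown LOOCV mode {mode!r}")
    if mode == "classifier_only" and markers is None:
        raise ValueError("classifier_only mode requires fixed markers")
    if mode == "nested" and candidates is None:
        raise ValueError("nested mode requires a candidate probe pool")
    lab = labels.reindex(bm.sample_ids)
    eval_samples = lab.index[lab.isin([POSITIVE_CLASS, NEGATIVE_CLASS])]
    if len(eval_samples) < 3:
        raise ValueError("LOOCV needs at least 3 labelled samples")

    scores, predicted = {}, {}
    for held in eval_samples:
        train_ids = [s for s in eval_samples if s != held]
        train_lab = lab.loc[train_ids]
        if (train_lab == POSITIVE_CLASS).sum() < 2 or (train_lab == NEGATIVE_CLASS).sum() < 2:
            _log.warning("fold for %s skipped: a class would have < 2 training samples", held)
            continue
        if usage_hook is not None:
            usage_hook(train_ids)
        train_bm = bm.subset_samples(train_ids)
        fold_markers = (
            select_features(candidates, train_bm, train_lab, top_k=top_k)
            if mode == "nested"
            else list(markers)
        )
        if not fold_markers:
            scores[held], predicted[held] = float("nan"), NO_CALL
            continue
        model = dlda_train(train_bm, train_lab, fold_markers)
        s, pred = score(model, bm.values.loc[fold_markers, held].to_numpy())
        # orient scores consistently (pCR high) so a pooled AUC is meaningful
        scores[held] = s if model.orientation == "pCR_high" else -s
        predicted[held] = pred
    return evaluate(
        pd.Series(predicted), lab.loc[list(predicted)], pd.Series(scores)
    )


def recalibrate_threshold(
    model: ClassifierModel, bm_newscale: BetaMatrix, labels: pd.Series
) -> ClassifierModel:
    """Port the model to a new measurement scale by rescanning the threshold.

    Weights are kept; candidate thresholds are the midpoints of adjacent
    distinct sorted scores on the new scale; the candidate with the best
    overall accuracy wins, ties broken toward higher sensitivity, then lower
    threshold. Samples with missing markers are excluded from the scan.
    """
    lab = labels.reindex(bm_newscale.sample_ids)
    sub = bm_newscale.values.reindex(list(model.probe_ids))
    raw = sub.to_numpy(dtype=float)
    ok = ~np.isnan(raw).any(axis=0)
    ok &= lab.isin([POSITIVE_CLASS, NEGATIVE_CLASS]).to_numpy()
    s = np.asarray(model.weights) @ raw[:, ok]
    y_pos = (lab.to_numpy()[ok] == POSITIVE_CLASS)
    uniq = np.unique(s)
    if len(uniq) < 2:
        raise ValueError("all scores identical; threshold cannot be recalibrated")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    sign = 1.0 if model.orientation == "pCR_high" else -1.0
    best = None
    for tau in mids:
        pred_pos = (sign * s) > (sign * tau)
        acc = np.mean(pred_pos == y_pos)
        sens = np.mean(pred_pos[y_pos]) if y_pos.any() else 0.0
        key = (acc, sens, -tau)
        if best is None or key > best[0]:
            best = (key, tau)
    return replace(model, threshold=float(best[1]), scale=bm_newscale.scale)


def evaluate(predicted: pd.Series, true: pd.Series, scores: pd.Series) -> EvalResult:
    """Confusion counts, sensitivity, specificity and rank AUC of the scores.

    No-calls are excluded from the confusion table and counted separately.
    Sensitivity (pCR recall) and specificity (pIR recall) are None when the
    corresponding class is absent. The AUC uses the convention that pCR
    scores high; callers orienting scores differently should flip them first.
    """
    true = true.reindex(predicted.index)
    scores = scores.reindex(predicted.index)
    called = predicted != NO_CALL
    n_no_call = int((~called).sum())
    p, t, s = predicted[called], true[called], scores[called]
    tp = int(((p == POSITIVE_CLASS) & (t == POSITIVE_CLASS)).sum())
    fn = int(((p != POSITIVE_CLASS) & (t == POSITIVE_CLASS)).sum())
    tn = int(((p != POSITIVE_CLASS) & (t != POSITIVE_CLASS)).sum())
    fp = int(((p == POSITIVE_CLASS) & (t != POSITIVE_CLASS)).sum())
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    auc = None
    pos_scores = s[t == POSITIVE_CLASS].dropna()
    neg_scores = s[t != POSITIVE_CLASS].dropna()
    if len(pos_scores) and len(neg_scores):
        auc = probe_auc(
            np.concatenate([pos_scores, neg_scores]),
            np.array([POSITIVE_CLASS] * len(pos_scores) + [NEGATIVE_CLASS] * len(neg_scores)),
            directed=True,
        )
    return EvalResult(
        scores=s,
        predicted=p,
        true=t,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        n_no_call=n_no_call,
    )
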