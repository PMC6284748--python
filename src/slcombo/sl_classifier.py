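"""Random-forest inference of synthetic-lethal gene pairs.

The orthologue-translated SL set is sparse; a tree-ensemble classifier trained
on pair feature vectors (annotation Dice coefficients, mean node measures,
shortest path) extends it to unobserved pairs.  Because screens report only
positives, the negative class is constructed by uniform random sampling of
non-positive gene pairs from the gene universe (default ratio 1:1), a standard
device for interaction inference that the evaluation report records.

Defaults: 500 trees, unlimited depth, sqrt(p) features per split, stratified
25% held-out test split, decision threshold 0.5.  Every stochastic step takes
an explicit seed; a fixed seed makes training and prediction bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

SL, NON_SL = "SL", "non-SL"

DEFAULT_HYPERPARAMS: dict = {
    "n_estimators": 500,
    "max_depth": None,
    "max_features": "sqrt",
}


class SizingError(ValueError):
    """Raised when the gene universe cannot supply the requested negatives."""


class FeatureMismatchError(ValueError):
    """Raised when candidate features do not match the model's manifest."""


@dataclass(frozen=True)
class LabeledPair:
    pair: tuple[str, str]
    label: str  # SL or NON_SL
    features: tuple[float, ...] | None = None


@dataclass
class TrainedModel:
    estimator: RandomForestClassifier
    manifest: tuple[str, ...]
    hyperparams: Mapping[str, object]
    seed: int
    n_train_pos: int
    n_train_neg: int
    threshold: float = 0.5

    def metadata(self) -> dict:
        """Everything needed to retrain reproducibly, JSON-serialisable."""
        return {
            "manifest": list(self.manifest),
            "hyperparams": dict(self.hyperparams),
            "seed": self.seed,
            "n_train_pos": self.n_train_pos,
            "n_train_neg": self.n_train_neg,
            "threshold": self.threshold,
        }


@dataclass
class EvaluationReport:
    auc: float
    accuracy: float
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float

    @property
    def n_test(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def assemble_training_set(
    positives: Sequence[tuple[str, str]],
    universe: Sequence[str],
    neg_ratio: float = 1.0,
    seed: int = 0,
) -> list[LabeledPair]:
    """Label positives SL and draw ``round(neg_ratio * n_pos)`` random negatives.

    Negatives are unordered gene pairs sampled uniformly without replacement
    from the universe, disjoint from the positive set.  Reproducible for a
    fixed seed.
    """
    if neg_ratio <= 0:
        raise SizingError("neg_ratio must be positive")
    genes = sorted(set(g.upper() for g in universe))
    pos_keys = {tuple(sorted((a.upper(), b.upper()))) for a, b in positives}
    n_neg = round(neg_ratio * len(pos_keys))
    n_possible = len(genes) * (len(genes) - 1) // 2 - len(pos_keys)
    if n_neg > n_possible:
        raise SizingError(
            f"requested {n_neg} negatives but only {n_possible} distinct "
            "non-positive pairs exist in the universe"
        )
    rng = np.random.default_rng(seed)
    negatives: set[tuple[str, str]] = set()
    while len(negatives) < n_neg:
        i, j = rng.integers(0, len(genes), size=2)
        if i == j:
            continue
        key = tuple(sorted((genes[i], genes[j])))
        if key not in pos_keys:
            negatives.add(key)
    labeled = [LabeledPair(p, SL) for p in sorted(pos_keys)]
    labeled += [LabeledPair(p, NON_SL) for p in sorted(negatives)]
    return labeled


def _feature_matrix(features: pd.DataFrame, manifest: Sequence[str]) -> np.ndarray:
    missing = [c for c in manifest if c not in features.columns]
    extra = [
        c
        for c in features.columns
        if c not in manifest and c not in ("gene_a", "gene_b")
    ]
    if missing or extra:
        raise FeatureMismatchError(
            f"feature manifest mismatch; missing={missing} unexpected={extra}"
        )
    return features[list(manifest)].to_numpy(dtype=float)


def train_and_validate(
    features: pd.DataFrame,
    labels: Sequence[str],
    manifest: Sequence[str],
    test_fraction: float = 0.25,
    seed: int = 0,
    hyperparams: Mapping[str, object] | None = None,
    threshold: float = 0.5,
) -> tuple[TrainedModel, EvaluationReport]:
    """Fit the forest on a stratified split and score the held-out fraction.

    The report's AUC, accuracy and confusion counts are computed only on the
    held-out pairs; the split is stratified by label so class proportions are
    preserved within rounding.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie in (0, 1)")
    y = np.asarray([1 if l == SL else 0 for l in labels])
    if len(set(y)) < 2:
        raise ValueError("training data must contain both classes")
    X = _feature_matrix(features, manifest)
    hp = dict(DEFAULT_HYPERPARAMS)
    hp.update(hyperparams or {})
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, random_state=seed, stratify=y
    )
    clf = RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    clf.fit(X_tr, y_tr)
    prob = clf.predict_proba(X_te)[:, 1]
    pred = (prob >= threshold).astype(int)
    report = EvaluationReport(
        auc=float(roc_auc_score(y_te, prob)),
        accuracy=float(np.mean(pred == y_te)),
        tp=int(np.sum((pred == 1) & (y_te == 1))),
        fp=int(np.sum((pred == 1) & (y_te == 0))),
        tn=int(np.sum((pred == 0) & (y_te == 0))),
        fn=int(np.sum((pred == 0) & (y_te == 1))),
        threshold=threshold,
    )
    model = TrainedModel(
        estimator=clf,
        manifest=tuple(manifest),
        hyperparams=hp,
        seed=seed,
        n_train_pos=int(y_tr.sum()),
        n_train_neg=int(len(y_tr) - y_tr.sum()),
        threshold=threshold,
    )
    return model, report


def predict_pairs(
    model: TrainedModel,
    candidates: pd.DataFrame,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Score candidate pairs; SL iff probability >= threshold.

    ``candidates`` must carry ``gene_a``/``gene_b`` plus exactly the model's
    feature manifest; a mismatch raises :class:`FeatureMismatchError` naming
    the offending columns.  Deterministic given the fitted model.
    """
    thr = model.threshold if threshold is None else threshold
    out = candidates[["gene_a", "gene_b"]].copy()
    if len(candidates) == 0:
        out["probability"] = pd.Series(dtype=float)
        out["label"] = pd.Series(dtype=str)
        return out
    X = _feature_matrix(candidates, model.manifest)
    prob = model.estimator.predict_proba(X)[:, 1]
    out["probability"] = prob
    out["label"] = np.where(prob >= thr, SL, NON_SL)
    return out


def rank_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """AUC as the Mann-Whitney rank statistic: P(score_pos > score_neg) + ½ ties.

    Quadratic-time pairwise comparison; kept as an independent check of the
    report's AUC on small test sets.
    """
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    if not pos or not neg:
        raise ValueError("both classes required")
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
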