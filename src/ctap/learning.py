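"""Training and evaluation of the gene-regulation classifiers.

The training set pairs every functional-group marker entry (and the two
transcription factors themselves) with each comparison pair: the 5-feature
vector is the input, the entry's expected regulation in the CP's context the
+/-1 label.  Four classifier families are supported — linear-kernel SVM,
l1-penalized logistic regression, Gaussian naive Bayes, and a small
multilayer perceptron (two hidden layers of 5 and 3 units, ReLU, Adam).

Evaluation conventions: samples are split 70/30 stratified by label, +1
(up-regulation) is the positive class for sensitivity/specificity, and
reported metrics are rounded half-away-from-zero at two decimals.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .cohort import Cohort
from .features import FEATURE_NAMES, feature_table
from .functional_groups import (
    DEFAULT_TF_DIRECTIONS,
    FunctionalGroup,
    TFGSResult,
    expected_label,
    fg_score,
    fg_state,
    tfgs,
)

__all__ = [
    "ModelSpec",
    "EvalMetrics",
    "TrainedModel",
    "DEFAULT_GRIDS",
    "build_training_set",
    "train_model",
    "evaluate",
    "random_gene_baseline",
    "loo_fg_tfgs",
    "round2",
]

FAMILIES = ("svm", "lr", "gnb", "nn")

# Small fixed hyperparameter grids searched by held-out AUC.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svm": {"C": [0.01, 0.1, 1.0, 10.0]},
    "lr": {"C": [0.01, 0.1, 1.0, 10.0]},
    "gnb": {},
    "nn": {},
}


def round2(x: float) -> float:
    """Round to 2 decimals, halves away from zero (reporting convention)."""
    return math.floor(abs(x) * 100 + 0.5) / 100 * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ModelSpec:
    """Classifier family, hyperparameters, split fraction, and seed."""

    family: str = "svm"
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    split_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class EvalMetrics:
    """Confusion counts and derived metrics, +1 as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    mcc: float
    sn: float
    sp: float
    auc: float | None = None

    def rounded(self) -> dict[str, float]:
        out = {k: round2(getattr(self, k)) for k in ("acc", "mcc", "sn", "sp")}
        if self.auc is not None:
            out["auc"] = round2(self.auc)
        return out


@dataclass(frozen=True)
class TrainedModel:
    """A fitted classifier together with its spec and held-out metrics."""

    spec: ModelSpec
    model: object
    metrics: EvalMetrics

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(self.model.predict(features), dtype=int)

    def scores(self, features: np.ndarray) -> np.ndarray:
        if hasattr(self.model, "decision_function"):
            return np.asarray(self.model.decision_function(features))
        return np.asarray(self.model.predict_proba(features)[:, 1])


def _make_classifier(spec: ModelSpec, params: Mapping[str, object]):
    if spec.family == "svm":
        return SVC(kernel="linear", random_state=spec.seed, **params)
    if spec.family == "lr":
        # lasso-penalized logistic regression
        return LogisticRegression(
            l1_ratio=1, solver="liblinear", random_state=spec.seed, **params
        )
    if spec.family == "gnb":
        return GaussianNB(**params)
    return MLPClassifier(
        hidden_layer_sizes=(5, 3),
        activation="relu",
        solver="adam",
        max_iter=800,
        random_state=spec.seed,
        **params,
    )


def build_training_set(
    cohort: Cohort,
    fg_registry: Sequence[FunctionalGroup],
    tf_directions: Mapping[str, Mapping[str, int]] = DEFAULT_TF_DIRECTIONS,
) -> pd.DataFrame:
    """One labeled sample per (marker entry, CP).

    Marker entries are every (group, gene) pair of the registry — a gene
    recurring in two groups contributes two entries — plus one "TF" entry per
    transcription factor in ``tf_directions``.  Entries unmeasured in a CP's
    study carry the zero-imputed features of the big matrix.  Columns:
    gene, group, cp_id, context, the five features, label.
    """
    if not fg_registry:
        raise ValueError("empty functional-group registry")
    entries: list[tuple[str, str]] = [
        (fg.name, gene) for fg in fg_registry for gene in fg.genes
    ]
    entries += [("TF", tf.upper()) for tf in tf_directions]
    unique_genes = sorted({g for _, g in entries})
    present = [g for g in unique_genes if g in cohort.m_prime.values.index]
    feats = feature_table(cohort.cps, cohort.m_prime, present)
    feats = feats.set_index(["cp_id", "gene"])
    by_group = {fg.name: fg for fg in fg_registry}
    rows = []
    zero = dict.fromkeys(FEATURE_NAMES, 0.0)
    for cp in cohort.cps:
        for group, gene in entries:
            if group == "TF":
                label = tf_directions[gene][cp.context]
            else:
                label = expected_label(by_group[group], cp.context)
            if (cp.cp_id, gene) in feats.index:
                f = feats.loc[(cp.cp_id, gene)][list(FEATURE_NAMES)].to_dict()
            else:
                f = dict(zero)
            rows.append({"gene": gene, "group": group, "cp_id": cp.cp_id,
                         "context": cp.context, **f, "label": label})
    return pd.DataFrame(rows)


def _split(samples: pd.DataFrame, spec: ModelSpec):
    X = samples[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = samples["label"].to_numpy(dtype=int)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=spec.split_fraction, random_state=spec.seed,
        stratify=y,
    )
    if len(set(y_tr)) < 2 or len(set(y_te)) < 2:
        raise ValueError("single-class split; reseed or rebalance the samples")
    return X_tr, X_te, y_tr, y_te


def train_model(
    samples: pd.DataFrame,
    spec: ModelSpec,
    *,
    grid: Mapping[str, Sequence] | None = None,
) -> TrainedModel:
    """Fit one classifier on a stratified 70/30 split of the samples.

    With ``grid`` given (e.g. ``DEFAULT_GRIDS[spec.family]``), each
    hyperparameter combination is fitted on the training split and the one
    with the highest held-out AUC is kept.
    """
    X_tr, X_te, y_tr, y_te = _split(samples, spec)
    combos: list[dict] = [dict(spec.hyperparameters)]
    if grid:
        keys = sorted(grid)
        combos = [
            {**dict(spec.hyperparameters), **dict(zip(keys, vals))}
            for vals in itertools.product(*(grid[k] for k in keys))
        ]
    best = None
    for params in combos:
        clf = _make_classifier(spec, params)
        clf.fit(X_tr, y_tr)
        if hasattr(clf, "decision_function"):
            scores = clf.decision_function(X_te)
        else:
            scores = clf.predict_proba(X_te)[:, 1]
        auc = roc_auc_score(y_te, scores)
        if best is None or auc > best[0]:
            best = (auc, clf, params)
    auc, clf, params = best
    metrics = evaluate(clf.predict(X_te), y_te, auc=float(auc))
    return TrainedModel(spec=replace(spec, hyperparameters=params),
                        model=clf, metrics=metrics)


def evaluate(
    predicted: Sequence[int],
    true: Sequence[int],
    *,
    auc: float | None = None,
) -> EvalMetrics:
    """Confusion counts and ACC/MCC/Sn/Sp with +1 as the positive class."""
    pred = np.asarray(list(predicted), dtype=int)
    y = np.asarray(list(true), dtype=int)
    if pred.size == 0 or pred.shape != y.shape:
        raise ValueError("predicted and true labels must be equal-length, non-empty")
    bad = set(np.unique(np.concatenate([pred, y]))) - {-1, 1}
    if bad:
        raise ValueError(f"labels must be +1/-1, found {sorted(bad)}")
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == -1) & (y == -1)).sum())
    fp = int(((pred == 1) & (y == -1)).sum())
    fn = int(((pred == -1) & (y == 1)).sum())
    n = tp + tn + fp + fn
    acc = (tp + tn) / n
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return EvalMetrics(tp=tp, tn=tn, fp=fp, fn=fn, acc=acc, mcc=mcc,
                       sn=sn, sp=sp, auc=auc)


def random_gene_baseline(
    cohort: Cohort,
    fg_registry: Sequence[FunctionalGroup],
    spec: ModelSpec,
    n_repeats: int = 10,
    seed: int = 0,
    tf_directions: Mapping[str, Mapping[str, int]] = DEFAULT_TF_DIRECTIONS,
) -> tuple[list[EvalMetrics], dict[str, float]]:
    """Baseline: marker genes replaced by random non-marker genes.

    Each repeat substitutes every marker slot with a distinct gene sampled
    (without replacement) from the cohort genes outside the registry and the
    TFs, keeping the slot's label, then trains and evaluates ``spec``'s model.
    Returns the per-repeat metrics and their means.
    """
    samples = build_training_set(cohort, fg_registry, tf_directions)
    slots = samples[["gene", "group"]].drop_duplicates()
    marker_genes = set(samples["gene"])
    pool = sorted(set(cohort.genes) - marker_genes)
    if len(pool) < len(slots):
        raise ValueError(
            f"need {len(slots)} non-marker genes, cohort offers {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    feats_all = feature_table(cohort.cps, cohort.m_prime, pool)
    feats_all = feats_all.set_index(["cp_id", "gene"])
    results: list[EvalMetrics] = []
    for rep in range(n_repeats):
        chosen = rng.choice(pool, size=len(slots), replace=False)
        rows = []
        for (slot_gene, group), rand_gene in zip(
            slots.itertuples(index=False), chosen
        ):
            slot = samples[(samples["gene"] == slot_gene)
                           & (samples["group"] == group)]
            for r in slot.itertuples(index=False):
                f = feats_all.loc[(r.cp_id, rand_gene)]
                rows.append({
                    "gene": rand_gene, "group": group, "cp_id": r.cp_id,
                    "context": r.context,
                    **{k: float(f[k]) for k in FEATURE_NAMES},
                    "label": r.label,
                })
        rep_samples = pd.DataFrame(rows)
        trained = train_model(
            rep_samples, replace(spec, seed=spec.seed + rep)
        )
        results.append(trained.metrics)
    if not results:
        return [], {}
    summary = {
        k: float(np.mean([getattr(m, k) for m in results]))
        for k in ("acc", "mcc", "sn", "sp", "auc")
    }
    return results, summary


def loo_fg_tfgs(
    cohort: Cohort,
    fg_registry: Sequence[FunctionalGroup],
    spec: ModelSpec,
    tf_directions: Mapping[str, Mapping[str, int]] = DEFAULT_TF_DIRECTIONS,
    *,
    classifier_factory=None,
) -> dict[str, TFGSResult]:
    """Leave-one-group-out TFGS evaluation of one classifier family.

    Each functional group is held out in turn; the model is trained on the
    remaining groups (plus the TFs), predicts +/-1 for every held-out member
    gene in every CP, and the group's score per CP is recomputed from those
    predictions in place of the log2 ratios.  A (CP, held-out group) cell
    counts when the score's sign follows the group's expected state.  The
    same folds scored directly from the log2 fold changes give the
    fold-change-only reference under identical conditions.

    ``classifier_factory(spec, params)`` overrides the default estimator
    construction (any object with ``fit``/``predict``).
    """
    if len(fg_registry) < 2:
        raise ValueError("leave-one-group-out needs at least two groups")
    samples = build_training_set(cohort, fg_registry, tf_directions)
    model_states: dict[int, dict[str, bool]] = {
        cp.cp_id: {} for cp in cohort.cps
    }
    fc_states: dict[int, dict[str, bool]] = {cp.cp_id: {} for cp in cohort.cps}
    for held_out in fg_registry:
        train = samples[samples["group"] != held_out.name]
        X = train[list(FEATURE_NAMES)].to_numpy(dtype=float)
        y = train["label"].to_numpy(dtype=int)
        factory = classifier_factory or _make_classifier
        clf = factory(spec, dict(spec.hyperparameters))
        clf.fit(X, y)
        test = samples[samples["group"] == held_out.name]
        preds = clf.predict(test[list(FEATURE_NAMES)].to_numpy(dtype=float))
        test = test.assign(pred=preds)
        for cp in cohort.cps:
            sub = test[test["cp_id"] == cp.cp_id]
            expected = held_out.expected_state[cp.context]
            model_score = fg_score(sub["pred"].tolist())
            fc_score_ = fg_score(sub["log2fc"].tolist())
            model_states[cp.cp_id][held_out.name] = fg_state(model_score, expected)
            fc_states[cp.cp_id][held_out.name] = fg_state(fc_score_, expected)
    return {"model": tfgs(model_states), "log2fc_only": tfgs(fc_states)}
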