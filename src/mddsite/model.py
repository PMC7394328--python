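"""Per-subgroup RBF-SVM classifiers and the integrated (stacked) model.

Each motif subgroup found by the decomposition gets its own RBF-kernel
support-vector classifier, k(S_i, S_j) = exp(-gamma ||S_i - S_j||^2),
trained on the subgroup's positive windows plus the negatives that route to
the same leaf (rebalanced to ~2:1 negatives:positives by default). C and
gamma are chosen by an exhaustive log2 grid search maximising k-fold
cross-validated accuracy. The integrated model stacks the M subgroup
classifiers: their positive-class probabilities form an M-vector that feeds
a meta RBF-SVM. Meta-training vectors are computed out-of-fold so that no
subgroup classifier scores a window it was trained on.

Features are min-max scaled to [0, 1] per dimension before fitting; scaling
parameters are stored with each classifier. All randomness (fold
assignment, Platt calibration, negative trimming) derives from explicit
seeds, so training is exactly reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .encoding import encode_matrix
from .mdd import MddConfig, MddTree, mdd_partition, route
from .seqio import Fragment

logger = logging.getLogger(__name__)

DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0**p for p in range(-5, 16, 2))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0**p for p in range(-15, 4, 2))

#: Reduced grid for quick experiments; the full grid is the default.
SMALL_C_GRID: tuple[float, ...] = tuple(2.0**p for p in (-1, 1, 3, 5))
SMALL_GAMMA_GRID: tuple[float, ...] = tuple(2.0**p for p in (-7, -5, -3, -1))


@dataclass(frozen=True)
class SvmConfig:
    """RBF-SVM hyper-parameters and grid-search settings."""

    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    cv_folds: int = 5
    objective: str = "accuracy"  # or "mcc"

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.c_grid) or any(g <= 0 for g in self.gamma_grid):
            raise ValueError("C and gamma must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def _fold_score(y_true: np.ndarray, y_pred: np.ndarray, objective: str) -> float:
    if objective == "accuracy":
        return float((y_true == y_pred).mean())
    if objective == "mcc":
        from .evaluate import ConfusionMatrix, metrics

        cm = ConfusionMatrix.from_labels(y_true, y_pred)
        return metrics(cm).mcc
    raise ValueError(f"unknown objective {objective!r}")


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    seed: int = 0,
    objective: str = "accuracy",
) -> tuple[float, float, float]:
    """Exhaustive (C, gamma) grid search by stratified k-fold CV.

    Returns (C, gamma, best mean score). Ties keep the smaller C, then the
    smaller gamma (the grids are scanned in ascending order and only a
    strictly better score replaces the incumbent).
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("grid search requires both classes present")
    k = min(k, int(min(np.bincount(y.astype(int)))))
    if k < 2:
        raise ValueError("each class needs at least 2 members for CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best: tuple[float, float, float] | None = None  # (score, C, gamma)
    for c in sorted(c_grid):
        for gamma in sorted(gamma_grid):
            preds = np.empty_like(y)
            for train_idx, test_idx in folds:
                clf = SVC(C=c, gamma=gamma, kernel="rbf")
                clf.fit(X[train_idx], y[train_idx])
                preds[test_idx] = clf.predict(X[test_idx])
            score = _fold_score(y, preds, objective)
            if best is None or score > best[0]:
                best = (score, c, gamma)
    assert best is not None
    return best[1], best[2], best[0]


@dataclass
class SubgroupModel:
    """A fitted RBF-SVM for one motif subgroup (or for the pooled data).

    Stores the scaler, the selected (C, gamma) and its training set so that
    out-of-fold probabilities can be recomputed for stacking.
    """

    label: str
    scheme: str
    k: Optional[int]
    C: float
    gamma: float
    scaler: MinMaxScaler
    classifier: SVC
    n_pos: int
    n_neg: int
    seed: int
    training_X: np.ndarray = field(repr=False)
    training_y: np.ndarray = field(repr=False)
    training_keys: list[tuple] = field(repr=False, default_factory=list)

    def _encode(self, fragments: Sequence[Fragment]) -> np.ndarray:
        return self.scaler.transform(encode_matrix(fragments, self.scheme, self.k))

    def predict_proba(self, fragments: Sequence[Fragment]) -> np.ndarray:
        """Positive-class probability per fragment."""
        proba = self.classifier.predict_proba(self._encode(fragments))
        return proba[:, list(self.classifier.classes_).index(1)]

    def oof_proba(self, k: Optional[int] = None) -> dict[tuple, float]:
        """Out-of-fold positive-class probabilities for the training set.

        Each training window is scored by a classifier refitted on the other
        folds, so the probability is honest (no self-scoring).
        """
        k = k if k is not None else 5
        k = min(k, int(np.bincount(self.training_y.astype(int)).min()))
        out = np.empty(len(self.training_y))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=self.seed)
        for train_idx, test_idx in skf.split(self.training_X, self.training_y):
            clf = SVC(
                C=self.C, gamma=self.gamma, kernel="rbf", probability=True,
                random_state=self.seed,
            )
            clf.fit(self.training_X[train_idx], self.training_y[train_idx])
            col = list(clf.classes_).index(1)
            out[test_idx] = clf.predict_proba(self.training_X[test_idx])[:, col]
        return {key: out[i] for i, key in enumerate(self.training_keys)}


def fit_svm(
    positives: Sequence[Fragment],
    negatives: Sequence[Fragment],
    label: str = "All",
    scheme: str = "aac",
    k_spacing: Optional[int] = None,
    svm_config: SvmConfig = SvmConfig(),
    seed: int = 0,
) -> SubgroupModel:
    """Grid-search and fit one RBF-SVM on labelled fragment sets."""
    if len(positives) < 2 or len(negatives) < 2:
        raise ValueError(
            f"subgroup {label!r}: need >= 2 fragments per class "
            f"(got {len(positives)} positives, {len(negatives)} negatives); "
            f"consider a larger min_leaf_size"
        )
    frags = list(positives) + list(negatives)
    y = np.array([1] * len(positives) + [0] * len(negatives))
    raw = encode_matrix(frags, scheme, k_spacing)
    scaler = MinMaxScaler().fit(raw)
    X = scaler.transform(raw)
    C, gamma, _ = grid_search(
        X, y, k=svm_config.cv_folds, c_grid=svm_config.c_grid,
        gamma_grid=svm_config.gamma_grid, seed=seed, objective=svm_config.objective,
    )
    clf = SVC(C=C, gamma=gamma, kernel="rbf", probability=True, random_state=seed)
    clf.fit(X, y)
    return SubgroupModel(
        label=label, scheme=scheme, k=k_spacing, C=C, gamma=gamma, scaler=scaler,
        classifier=clf, n_pos=len(positives), n_neg=len(negatives), seed=seed,
        training_X=X, training_y=y, training_keys=[f.key() for f in frags],
    )


def allocate_negatives(
    tree: MddTree,
    negatives: Sequence[Fragment],
    ratio: Optional[float] = 2.0,
    seed: int = 0,
    method: str = "proportional",
) -> dict[str, list[Fragment]]:
    """Assign negative windows to the tree's leaves for subgroup training.

    ``method='proportional'`` (default): a seeded random partition giving
    each leaf ``round(ratio * leaf positives)`` negatives drawn from the
    whole pool without replacement (scaled down if the pool is short). Each
    subgroup model then discriminates its motif subgroup against generic
    negatives. ``method='routed'``: negatives follow the tree's split
    predicates and each leaf keeps a seeded subsample of its own share;
    this matches prediction-time routing but pits every subgroup against
    negatives that carry the same split residues, which erases most of the
    compositional signal. ``ratio=None`` with 'routed' keeps every routed
    negative; with 'proportional' it splits the whole pool proportionally
    to leaf size.
    """
    rng = np.random.default_rng(seed)
    leaves = tree.leaves
    if method == "routed":
        routed: dict[str, list[Fragment]] = {leaf.label: [] for leaf in leaves}
        for frag in negatives:
            routed[route(tree, frag)].append(frag)
        if ratio is None:
            return routed
        out: dict[str, list[Fragment]] = {}
        for leaf in leaves:
            pool = routed[leaf.label]
            target = round(ratio * leaf.size)
            if target < len(pool):
                idx = np.sort(rng.choice(len(pool), size=target, replace=False))
                pool = [pool[i] for i in idx]
            out[leaf.label] = pool
        return out
    if method != "proportional":
        raise ValueError(f"unknown allocation method {method!r}")
    n_pos_total = sum(leaf.size for leaf in leaves)
    if ratio is None:
        targets = [round(len(negatives) * leaf.size / n_pos_total) for leaf in leaves]
    else:
        targets = [round(ratio * leaf.size) for leaf in leaves]
    need = sum(targets)
    if need > len(negatives):
        logger.warning(
            "negative pool (%d) short of requested %d; scaling shares down",
            len(negatives), need,
        )
        scale = len(negatives) / need
        targets = [int(t * scale) for t in targets]
    perm = rng.permutation(len(negatives))
    out = {}
    start = 0
    for leaf, target in zip(leaves, targets):
        take = perm[start : start + target]
        out[leaf.label] = [negatives[i] for i in np.sort(take)]
        start += target
    return out


def train_subgroup_models(
    tree: MddTree,
    positives: Sequence[Fragment],
    negatives: Sequence[Fragment],
    scheme: str = "aac",
    svm_config: SvmConfig = SvmConfig(),
    seed: int = 0,
    negative_ratio: Optional[float] = 2.0,
    allocation_method: str = "proportional",
) -> list[SubgroupModel]:
    """One grid-searched RBF-SVM per tree leaf, in leaf-label order."""
    allocation = allocate_negatives(tree, negatives, ratio=negative_ratio, seed=seed,
                                    method=allocation_method)
    models = []
    for leaf in tree.leaves:
        leaf_pos = [positives[i] for i in leaf.members]
        models.append(
            fit_svm(
                leaf_pos, allocation[leaf.label], label=leaf.label, scheme=scheme,
                svm_config=svm_config, seed=seed,
            )
        )
    return models


def build_meta_vectors(
    models: Sequence[SubgroupModel],
    fragments: Sequence[Fragment],
    out_of_fold: bool = False,
    k: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """(n_fragments, M) matrix of subgroup positive-class probabilities.

    With ``out_of_fold=True``, a fragment that belongs to a model's training
    set receives that model's out-of-fold probability instead of the
    (optimistic) in-sample one.
    """
    cols = []
    for model in models:
        probs = model.predict_proba(fragments)
        if out_of_fold:
            oof = model.oof_proba(k)
            probs = np.array(
                [oof.get(f.key(), p) for f, p in zip(fragments, probs)]
            )
        cols.append(probs)
    return np.column_stack(cols)


@dataclass
class Prediction:
    fragment: Fragment
    probability: float
    label: bool
    motif: str


@dataclass
class IntegratedModel:
    """Stacked classifier: an MDD tree, M subgroup SVMs and a meta RBF-SVM
    over their probability outputs."""

    tree: MddTree
    subgroup_models: list[SubgroupModel]
    meta_scaler: MinMaxScaler
    meta_classifier: SVC
    threshold: float = 0.5

    @property
    def n_subgroups(self) -> int:
        return len(self.subgroup_models)

    def meta_vectors(self, fragments: Sequence[Fragment]) -> np.ndarray:
        return build_meta_vectors(self.subgroup_models, fragments, out_of_fold=False)

    def predict_proba(self, fragments: Sequence[Fragment]) -> np.ndarray:
        if any(f.half_width != self.tree.half_width for f in fragments):
            raise ValueError("fragment window size does not match the trained model")
        X = self.meta_scaler.transform(self.meta_vectors(fragments))
        proba = self.meta_classifier.predict_proba(X)
        return proba[:, list(self.meta_classifier.classes_).index(1)]

    def predict(self, fragments: Sequence[Fragment]) -> list[Prediction]:
        probs = self.predict_proba(fragments)
        return [
            Prediction(
                fragment=f,
                probability=float(p),
                label=bool(p >= self.threshold),
                motif=route(self.tree, f),
            )
            for f, p in zip(fragments, probs)
        ]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.tree.save(directory / "tree.json")
        manifest = {
            "threshold": self.threshold,
            "subgroups": [m.label for m in self.subgroup_models],
            "scheme": self.subgroup_models[0].scheme,
        }
        (directory / "model.json").write_text(json.dumps(manifest, indent=2))
        for m in self.subgroup_models:
            joblib.dump(m, directory / f"subgroup_{m.label}.joblib")
        joblib.dump(
            {"scaler": self.meta_scaler, "classifier": self.meta_classifier},
            directory / "meta.joblib",
        )

    @classmethod
    def load(cls, directory: str | Path) -> "IntegratedModel":
        directory = Path(directory)
        tree = MddTree.load(directory / "tree.json")
        manifest = json.loads((directory / "model.json").read_text())
        models = [
            joblib.load(directory / f"subgroup_{label}.joblib")
            for label in manifest["subgroups"]
        ]
        meta = joblib.load(directory / "meta.joblib")
        return cls(
            tree=tree, subgroup_models=models, meta_scaler=meta["scaler"],
            meta_classifier=meta["classifier"], threshold=manifest["threshold"],
        )


def train_integrated(
    positives: Sequence[Fragment],
    negatives: Sequence[Fragment],
    scheme: str = "aac",
    mdd_config: MddConfig = MddConfig(),
    svm_config: SvmConfig = SvmConfig(),
    seed: int = 0,
    negative_ratio: Optional[float] = 2.0,
    allocation_method: str = "proportional",
    oof_k: int = 5,
    threshold: float = 0.5,
) -> IntegratedModel:
    """Full stacked-training pipeline.

    Decompose the positives into motif subgroups, route/rebalance the
    negatives, grid-search one RBF-SVM per subgroup, compute out-of-fold
    meta vectors for every training window, and grid-search the meta
    RBF-SVM on them.
    """
    if not negatives:
        raise ValueError("negative set is empty")
    tree = mdd_partition(positives, mdd_config)
    models = train_subgroup_models(
        tree, positives, negatives, scheme=scheme, svm_config=svm_config,
        seed=seed, negative_ratio=negative_ratio, allocation_method=allocation_method,
    )
    frags = list(positives) + list(negatives)
    y = np.array([1] * len(positives) + [0] * len(negatives))
    meta_raw = build_meta_vectors(models, frags, out_of_fold=True, k=oof_k, seed=seed)
    meta_scaler = MinMaxScaler().fit(meta_raw)
    meta_X = meta_scaler.transform(meta_raw)
    C, gamma, _ = grid_search(
        meta_X, y, k=svm_config.cv_folds, c_grid=svm_config.c_grid,
        gamma_grid=svm_config.gamma_grid, seed=seed, objective=svm_config.objective,
    )
    meta_clf = SVC(C=C, gamma=gamma, kernel="rbf", probability=True, random_state=seed)
    meta_clf.fit(meta_X, y)
    return IntegratedModel(
        tree=tree, subgroup_models=models, meta_scaler=meta_scaler,
        meta_classifier=meta_clf, threshold=threshold,
    )


# --------------------------------------------------------------------------
# Trainer factories for cross-validation (see evaluate.kfold_cv).

Trainer = Callable[[Sequence[Fragment], Sequence[Fragment], int],
                   Callable[[Sequence[Fragment]], np.ndarray]]


def single_svm_trainer(
    scheme: str = "aac",
    k_spacing: Optional[int] = None,
    svm_config: SvmConfig = SvmConfig(),
) -> Trainer:
    """Trainer producing one pooled RBF-SVM (no decomposition)."""

    def train(pos: Sequence[Fragment], neg: Sequence[Fragment], seed: int):
        model = fit_svm(pos, neg, scheme=scheme, k_spacing=k_spacing,
                        svm_config=svm_config, seed=seed)
        return model.predict_proba

    return train


def integrated_trainer(
    scheme: str = "aac",
    mdd_config: MddConfig = MddConfig(),
    svm_config: SvmConfig = SvmConfig(),
    negative_ratio: Optional[float] = 2.0,
    oof_k: int = 5,
) -> Trainer:
    """Trainer producing the stacked subgroup + meta model."""

    def train(pos: Sequence[Fragment], neg: Sequence[Fragment], seed: int):
        model = train_integrated(
            pos, neg, scheme=scheme, mdd_config=mdd_config, svm_config=svm_config,
            seed=seed, negative_ratio=negative_ratio, oof_k=oof_k,
        )
        return model.predict_proba

    return train
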