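"""Two-layered SVM classification over MDD motif subgroups.

First layer: one RBF-kernel SVM per motif subgroup (an MDD leaf), trained
on that subgroup's positive fragments against a size-matched representative
sample of the shared negative pool.  Second layer: every training fragment
is re-described as the k-vector of first-layer class probabilities, and a
meta SVM over those vectors makes the final call.  The layering lets each
subgroup model specialise on its own motif while the meta model arbitrates
between them.

Performance is summarised by sensitivity, specificity, accuracy, and the
Matthews correlation coefficient computed from pooled confusion counts:

    Sn  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    Acc = (TP + TN) / (TP + FP + TN + FN)
    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

with MCC defined as 0 when any denominator factor vanishes.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .dataset_prep import BalancedDataset, kmeans_balance
from .mdd import MDDTree
from .seq_data import ProteinRecord, SiteFragment, enumerate_cysteines, extract_fragment

logger = logging.getLogger(__name__)

ARCHIVE_VERSION = 1

Encoder = Callable[[SiteFragment], np.ndarray]


@dataclass(frozen=True)
class SVMConfig:
    """RBF-kernel SVM hyperparameters (cost C and kernel width gamma)."""

    C: float = 1.0
    gamma: float | str = "scale"

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if isinstance(self.gamma, float) and self.gamma <= 0:
            raise ValueError("gamma must be positive")


def default_grid() -> list[SVMConfig]:
    """Exhaustive (C, gamma) grid: C in 2^-5..2^15, gamma in 2^-15..2^3, steps of 4x."""
    return [
        SVMConfig(C=2.0 ** ce, gamma=2.0 ** ge)
        for ce in range(-5, 16, 2)
        for ge in range(-15, 4, 2)
    ]


@dataclass(frozen=True)
class PerformanceMetrics:
    """Confusion counts with the four derived measures."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else 0.0

    @property
    def specificity(self) -> float:
        return self.TN / (self.TN + self.FP) if self.TN + self.FP else 0.0

    @property
    def accuracy(self) -> float:
        total = self.TP + self.TN + self.FP + self.FN
        return (self.TP + self.TN) / total if total else 0.0

    @property
    def mcc(self) -> float:
        denom = (
            (self.TP + self.FN) * (self.TN + self.FP)
            * (self.TP + self.FP) * (self.TN + self.FN)
        )
        if denom == 0:
            return 0.0
        return ((self.TP * self.TN) - (self.FN * self.FP)) / math.sqrt(denom)

    def as_dict(self) -> dict:
        return {
            "TP": int(self.TP), "TN": int(self.TN),
            "FP": int(self.FP), "FN": int(self.FN),
            "Sn": self.sensitivity, "Sp": self.specificity,
            "Acc": self.accuracy, "MCC": self.mcc,
        }


def compute_metrics(TP: int, TN: int, FP: int, FN: int) -> PerformanceMetrics:
    """Wrap raw confusion counts; derived measures follow the formulas above."""
    if TP + TN + FP + FN <= 0:
        raise ValueError("at least one prediction is required")
    if min(TP, TN, FP, FN) < 0:
        raise ValueError("confusion counts must be non-negative")
    return PerformanceMetrics(TP=TP, TN=TN, FP=FP, FN=FN)


def train_svm(
    X: np.ndarray, y: np.ndarray, config: SVMConfig, seed: int
) -> SVC:
    """Fit a probabilistic RBF SVM; raises if only one class is present."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    clf = SVC(
        C=config.C, gamma=config.gamma, kernel="rbf",
        probability=True, random_state=seed,
    )
    with warnings.catch_warnings():
        # sklearn 1.9 deprecates probability=True in favour of
        # CalibratedClassifierCV; the built-in Platt scaling matches the
        # reference LIBSVM behaviour, so keep it while it exists.
        warnings.simplefilter("ignore", FutureWarning)
        clf.fit(np.asarray(X, dtype=float), y)
    return clf


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    grid: Sequence[SVMConfig] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> SVMConfig:
    """Pick the grid point with the best cross-validated accuracy.

    Ties resolve to the smaller C, then the smaller gamma, so the result is
    deterministic for a fixed seed.
    """
    grid = list(grid) if grid is not None else default_grid()
    if not grid:
        raise ValueError("empty hyperparameter grid")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(splitter.split(X, y))
    best: tuple[float, float, float] | None = None
    best_config = grid[0]
    for config in grid:
        correct = total = 0
        for train_idx, test_idx in splits:
            clf = SVC(C=config.C, gamma=config.gamma, kernel="rbf")
            clf.fit(X[train_idx], y[train_idx])
            correct += int((clf.predict(X[test_idx]) == y[test_idx]).sum())
            total += len(test_idx)
        gamma_key = config.gamma if isinstance(config.gamma, float) else -1.0
        key = (-correct / total, config.C, gamma_key)
        if best is None or key < best:
            best, best_config = key, config
    return best_config


@dataclass(frozen=True)
class Prediction:
    """One scored cysteine: probability of glutathionylation and the matched motif."""

    accession: str
    position: int
    fragment: str
    probability: float
    call: str
    matched_motif: str
    motif_path: str

    @staticmethod
    def columns() -> list[str]:
        return ["accession", "position", "fragment", "probability",
                "call", "matched_motif", "motif_path"]


@dataclass
class LayeredModel:
    """Per-subgroup SVMs plus the meta SVM over their probability outputs.

    ``groups`` lists, per first-layer model, the names of the MDD leaves it
    covers (leaves with too few positives are merged into the sibling group
    whose split path shares the longest common prefix).  ``leaf_to_group``
    routes any tree leaf to its first-layer model.
    """

    tree: MDDTree
    scheme: str
    encoder: Encoder
    groups: list[list[str]]
    group_models: list[SVC]
    meta_model: SVC
    config: SVMConfig
    seed: int
    threshold: float = 0.5
    leaf_to_group: dict[str, int] = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return len(self.group_models)

    def group_name(self, index: int) -> str:
        return self.groups[index][0]

    def leaf_probabilities(self, fragments: Sequence[SiteFragment]) -> np.ndarray:
        """(n_fragments, k) matrix of first-layer positive-class probabilities."""
        X = np.vstack([self.encoder(f) for f in fragments])
        cols = []
        for clf in self.group_models:
            pos_col = list(clf.classes_).index(1)
            cols.append(clf.predict_proba(X)[:, pos_col])
        return np.column_stack(cols)

    def predict_proba(self, fragments: Sequence[SiteFragment]) -> np.ndarray:
        """Final positive-class probability per fragment."""
        meta_X = self.leaf_probabilities(fragments)
        pos_col = list(self.meta_model.classes_).index(1)
        return self.meta_model.predict_proba(meta_X)[:, pos_col]

    def predict_fragments(self, fragments: Sequence[SiteFragment]) -> list[Prediction]:
        if not fragments:
            return []
        probs = self.predict_proba(fragments)
        out = []
        for frag, p in zip(fragments, probs):
            leaf = self.tree.route(frag)
            group = self.group_name(self.leaf_to_group[leaf.name])
            out.append(Prediction(
                accession=frag.accession, position=frag.position,
                fragment=frag.residues, probability=float(p),
                call="positive" if p > self.threshold else "negative",
                matched_motif=group, motif_path=leaf.describe_path(),
            ))
        return out


def _merge_small_leaves(
    tree: MDDTree, min_positives: int
) -> tuple[list[list[str]], dict[str, int]]:
    """Group tree leaves so every first-layer model has enough positives.

    Leaves below ``min_positives`` merge into the group whose path shares
    the longest common prefix (their nearest sibling in the tree);
    deterministic tie-break by group order.
    """
    leaves = tree.leaves
    groups: list[dict] = [
        {"names": [leaf.name], "size": leaf.size, "path": leaf.path}
        for leaf in leaves
    ]
    def common_prefix(p1, p2) -> int:
        k = 0
        for a, b in zip(p1, p2):
            if a != b:
                break
            k += 1
        return k

    while len(groups) > 1:
        sizes = [g["size"] for g in groups]
        smallest = min(range(len(groups)), key=lambda i: (sizes[i], i))
        if sizes[smallest] >= min_positives:
            break
        small = groups.pop(smallest)
        target = max(
            range(len(groups)),
            key=lambda i: (common_prefix(groups[i]["path"], small["path"]), -i),
        )
        logger.warning(
            "subgroup %s has %d positives (< %d); merging into %s",
            small["names"][0], small["size"], min_positives,
            groups[target]["names"][0],
        )
        groups[target]["names"].extend(small["names"])
        groups[target]["size"] += small["size"]
        groups[target]["path"] = groups[target]["path"][
            : common_prefix(groups[target]["path"], small["path"])
        ]
    name_lists = [g["names"] for g in groups]
    leaf_to_group = {
        name: gi for gi, names in enumerate(name_lists) for name in names
    }
    return name_lists, leaf_to_group


def train_layered(
    tree: MDDTree,
    positives: Sequence[SiteFragment],
    negatives: Sequence[SiteFragment],
    encoder: Encoder,
    seed: int,
    scheme: str = "custom",
    config: SVMConfig | None = None,
    min_leaf_positives: int = 10,
    threshold: float = 0.5,
) -> LayeredModel:
    """Train the two-layered model on a balanced fragment set.

    Each first-layer model sees its subgroup's positives against a
    size-matched negative sample drawn from the shared pool by seeded
    K-means balancing; the meta model is then trained on every fragment's
    vector of first-layer probabilities.
    """
    config = config or SVMConfig()
    groups, leaf_to_group = _merge_small_leaves(tree, min_leaf_positives)
    leaf_frags = {leaf.name: leaf.fragments for leaf in tree.leaves}
    all_frags = list(positives) + list(negatives)
    frag_index = {id(f): i for i, f in enumerate(all_frags)}
    meta_X = np.zeros((len(all_frags), len(groups)))
    group_models: list[SVC] = []
    for gi, names in enumerate(groups):
        group_pos = [f for name in names for f in leaf_frags[name]]
        k = min(len(group_pos), len(negatives))
        group_neg = kmeans_balance(list(negatives), k=k, seed=seed + gi)
        train_frags = group_pos + group_neg
        X = np.vstack([encoder(f) for f in train_frags])
        y = np.array([1] * len(group_pos) + [0] * len(group_neg))
        clf = train_svm(X, y, config, seed=seed + gi)
        group_models.append(clf)
        # meta features must be out-of-sample for the fragments this
        # first-layer model was trained on, or the meta SVM learns from
        # optimistically separated probabilities it will never see at
        # prediction time; cross-fit them fold-wise.
        oof = _out_of_fold_probabilities(X, y, config, seed=seed + gi)
        pos_col = list(clf.classes_).index(1)
        in_train = set()
        for frag, p in zip(train_frags, oof):
            meta_X[frag_index[id(frag)], gi] = p
            in_train.add(id(frag))
        rest = [f for f in all_frags if id(f) not in in_train]
        if rest:
            rest_X = np.vstack([encoder(f) for f in rest])
            rest_p = clf.predict_proba(rest_X)[:, pos_col]
            for frag, p in zip(rest, rest_p):
                meta_X[frag_index[id(frag)], gi] = p
    meta_y = np.array([1] * len(positives) + [0] * len(negatives))
    meta_model = train_svm(meta_X, meta_y, config, seed=seed)
    return LayeredModel(
        tree=tree, scheme=scheme, encoder=encoder, groups=groups,
        group_models=group_models, meta_model=meta_model,
        config=config, seed=seed, threshold=threshold,
        leaf_to_group=leaf_to_group,
    )


def _out_of_fold_probabilities(
    X: np.ndarray, y: np.ndarray, config: SVMConfig, seed: int, folds: int = 5
) -> np.ndarray:
    """Cross-fitted positive-class probabilities for a training matrix."""
    folds = min(folds, int(np.bincount(y).min()))
    if folds < 2:
        clf = train_svm(X, y, config, seed)
        return clf.predict_proba(X)[:, list(clf.classes_).index(1)]
    out = np.zeros(len(y))
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in splitter.split(X, y):
        clf = train_svm(X[train_idx], y[train_idx], config, seed)
        pos_col = list(clf.classes_).index(1)
        out[test_idx] = clf.predict_proba(X[test_idx])[:, pos_col]
    return out


def predict_protein(
    model: LayeredModel,
    protein: ProteinRecord,
    n: int | None = None,
) -> list[Prediction]:
    """Score every cysteine of a protein; empty list when it has none."""
    n = n if n is not None else model.tree.root.fragments[0].n
    fragments = [
        extract_fragment(protein, pos, n=n)
        for pos in enumerate_cysteines(protein)
    ]
    return model.predict_fragments(fragments)


def predictions_frame(predictions: Sequence[Prediction]) -> pd.DataFrame:
    rows = [
        {"accession": p.accession, "position": p.position, "fragment": p.fragment,
         "probability": round(p.probability, 6), "call": p.call,
         "matched_motif": p.matched_motif, "motif_path": p.motif_path}
        for p in predictions
    ]
    return pd.DataFrame(rows, columns=Prediction.columns())


# --- cross-validation --------------------------------------------------------

Trainer = Callable[[Sequence[SiteFragment], Sequence[SiteFragment], int], object]


def single_svm_trainer(
    encoder: Encoder, config: SVMConfig | None = None
) -> Trainer:
    """A trainer producing one global SVM (the no-clustering baseline)."""
    config = config or SVMConfig()

    class _Single:
        def __init__(self, clf: SVC):
            self.clf = clf

        def predict_proba(self, fragments: Sequence[SiteFragment]) -> np.ndarray:
            X = np.vstack([encoder(f) for f in fragments])
            pos_col = list(self.clf.classes_).index(1)
            return self.clf.predict_proba(X)[:, pos_col]

    def train(pos: Sequence[SiteFragment], neg: Sequence[SiteFragment], seed: int):
        X = np.vstack([encoder(f) for f in list(pos) + list(neg)])
        y = np.array([1] * len(pos) + [0] * len(neg))
        return _Single(train_svm(X, y, config, seed))

    return train


def layered_trainer(
    encoder: Encoder,
    grouping=None,
    mdd_threshold: float | None = None,
    max_cluster_size: int | None = None,
    config: SVMConfig | None = None,
    min_leaf_positives: int = 10,
    scheme: str = "custom",
) -> Trainer:
    """A trainer that re-runs MDD clustering on each fold's positives, then
    trains the two-layered model."""
    from .mdd import DEFAULT_MAX_CLUSTER_SIZE, DEFAULT_THRESHOLD, mdd_cluster

    mdd_threshold = DEFAULT_THRESHOLD if mdd_threshold is None else mdd_threshold
    max_size = DEFAULT_MAX_CLUSTER_SIZE if max_cluster_size is None else max_cluster_size

    def train(pos: Sequence[SiteFragment], neg: Sequence[SiteFragment], seed: int):
        tree = mdd_cluster(pos, grouping=grouping, threshold=mdd_threshold,
                           max_cluster_size=max_size)
        return train_layered(
            tree, pos, neg, encoder, seed=seed, scheme=scheme, config=config,
            min_leaf_positives=min_leaf_positives,
        )

    return train


def five_fold_cv(
    dataset: BalancedDataset,
    trainer: Trainer,
    seed: int,
    threshold: float = 0.5,
    folds: int = 5,
) -> tuple[PerformanceMetrics, list[PerformanceMetrics]]:
    """Stratified k-fold cross-validation with pooled confusion counts.

    Every fragment is tested exactly once; the per-fold confusion counts are
    summed into a single pooled estimate (micro-averaging), and the
    per-fold metrics are returned alongside.
    """
    frags = dataset.fragments
    y = np.array([1 if f.label == "positive" else 0 for f in frags])
    if min((y == 1).sum(), (y == 0).sum()) < folds:
        raise ValueError(f"need at least {folds} samples per class")
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold: list[PerformanceMetrics] = []
    pooled = np.zeros(4, dtype=int)  # TP TN FP FN
    for fold, (train_idx, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
        train_pos = [frags[i] for i in train_idx if y[i] == 1]
        train_neg = [frags[i] for i in train_idx if y[i] == 0]
        model = trainer(train_pos, train_neg, seed + fold)
        probs = model.predict_proba([frags[i] for i in test_idx])
        calls = (probs > threshold).astype(int)
        truth = y[test_idx]
        tp = int(((calls == 1) & (truth == 1)).sum())
        tn = int(((calls == 0) & (truth == 0)).sum())
        fp = int(((calls == 1) & (truth == 0)).sum())
        fn = int(((calls == 0) & (truth == 1)).sum())
        per_fold.append(compute_metrics(tp, tn, fp, fn))
        pooled += np.array([tp, tn, fp, fn])
    return compute_metrics(*(int(v) for v in pooled)), per_fold


# --- persistence -------------------------------------------------------------

def save_model(model: LayeredModel, path: str | Path) -> None:
    """Persist a trained model (versioned joblib archive).

    The encoder callable is stored by scheme name when it is one of the
    registry schemes; models trained with a custom encoder must be re-bound
    on load.
    """
    payload = {
        "version": ARCHIVE_VERSION,
        "tree": model.tree,
        "scheme": model.scheme,
        "groups": model.groups,
        "group_models": model.group_models,
        "meta_model": model.meta_model,
        "config": model.config,
        "seed": model.seed,
        "threshold": model.threshold,
        "leaf_to_group": model.leaf_to_group,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path, encoder: Encoder | None = None) -> LayeredModel:
    from .features import SCHEMES, get_encoder

    payload = joblib.load(path)
    if payload.get("version") != ARCHIVE_VERSION:
        raise ValueError(f"unsupported model archive version {payload.get('version')}")
    if encoder is None:
        if payload["scheme"] not in SCHEMES:
            raise ValueError(
                f"archive used scheme {payload['scheme']!r}; pass encoder= to load"
            )
        encoder = get_encoder(payload["scheme"])
    return LayeredModel(
        tree=payload["tree"], scheme=payload["scheme"], encoder=encoder,
        groups=payload["groups"], group_models=payload["group_models"],
        meta_model=payload["meta_model"], config=payload["config"],
        seed=payload["seed"], threshold=payload["threshold"],
        leaf_to_group=payload["leaf_to_group"],
    )
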