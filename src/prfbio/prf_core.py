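"""Probabilistic random forest: trees that train on probabilistic labels.

A classical random-forest classifier consumes hard labels y ∈ {0, 1}.  The
probabilistic variant consumes, for every training sample, a probability
pair (p_A, p_B) = (Δy, 1 − Δy) describing how likely the sample is to belong
to each class, and a propagation probability π giving how much of the sample
reaches a node.  Node class probabilities become π-weighted expectations

    P̄_A = Σ πᵢ p_{i,A} / Σ πᵢ        (and symmetrically for B),

the Gini impurity becomes Ḡ = 1 − (P̄_A² + P̄_B²), and a split's cost is the
π-mass-weighted average of the child impurities.  With all Δy ∈ {0, 1} and
π ∈ {0, 1} every quantity reduces exactly to its classical counterpart, so
the same learner in "hard" mode *is* a classical random forest — the
degeneracy the benchmarking in :mod:`prfbio.benchmark` relies on.

Feature uncertainty is supported at prediction time as an optional
per-feature Gaussian sd: a sample's π mass then splits across both branches
of a node, and branches whose mass falls below ``keep_proba`` are pruned
(surviving mass renormalised).  Training assumes exact features (π ∈ {0, 1}),
matching the intended use on binary fingerprints.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import ndtr
from sklearn.base import BaseEstimator, ClassifierMixin

from .activity_data import FeatureMatrix
from .label_uncertainty import LabelConfig, SoftLabelDataset

logger = logging.getLogger(__name__)

SERIALIZATION_VERSION = 1

# Cost must beat the node impurity by more than float noise to accept a split.
_SPLIT_TOL = 1e-12


def weighted_class_probs(
    p_a: Sequence[float], pi: Sequence[float] | None = None
) -> tuple[float, float]:
    """π-weighted class-probability pair (P̄_A, P̄_B) of a node.

    ``p_a`` holds each sample's probability of class A (the soft label);
    ``pi`` the propagation probabilities (default: all 1).  Raises if the
    total π mass is zero — callers must never create an empty node side.
    """
    p_a = np.asarray(p_a, dtype=float)
    w = np.ones_like(p_a) if pi is None else np.asarray(pi, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate node: total propagation mass is zero")
    pa = float((w * p_a).sum() / total)
    return pa, 1.0 - pa


def modified_gini(p_bar_a: float, p_bar_b: float) -> float:
    """Gini impurity of a probability-weighted node: 1 − (P̄_A² + P̄_B²)."""
    return 1.0 - (p_bar_a**2 + p_bar_b**2)


def split_cost(
    p_a_left: Sequence[float],
    pi_left: Sequence[float] | None,
    p_a_right: Sequence[float],
    pi_right: Sequence[float] | None,
) -> float:
    """Mass-weighted impurity of a candidate split.

    Ḡ_left · (Σπ_left / Σπ_parent) + Ḡ_right · (Σπ_right / Σπ_parent).
    If one side carries zero π mass the split is degenerate and the parent's
    own impurity is returned, so the split can never look like a gain.
    """
    p_a_left = np.asarray(p_a_left, dtype=float)
    p_a_right = np.asarray(p_a_right, dtype=float)
    w_l = np.ones_like(p_a_left) if pi_left is None else np.asarray(pi_left, float)
    w_r = np.ones_like(p_a_right) if pi_right is None else np.asarray(pi_right, float)
    sum_l, sum_r = w_l.sum(), w_r.sum()
    total = sum_l + sum_r
    if total <= 0:
        raise ValueError("degenerate split: no propagation mass on either side")
    if sum_l <= 0 or sum_r <= 0:
        pa = float((np.concatenate([w_l, w_r]) * np.concatenate(
            [p_a_left, p_a_right])).sum() / total)
        return modified_gini(pa, 1.0 - pa)
    pa_l = float((w_l * p_a_left).sum() / sum_l)
    pa_r = float((w_r * p_a_right).sum() / sum_r)
    g_l = modified_gini(pa_l, 1.0 - pa_l)
    g_r = modified_gini(pa_r, 1.0 - pa_r)
    return g_l * (sum_l / total) + g_r * (sum_r / total)


@dataclass
class Tree:
    """One decision tree in flat-array form.

    ``feature[k] == -1`` marks node ``k`` as terminal; otherwise the node
    routes samples with ``x[feature] > threshold`` right and the rest left.
    ``prob_active[k]`` stores the node's P̄_A (kept for internal nodes too —
    it is the fallback prediction when propagation prunes every branch).
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    prob_active: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "prob_active": self.prob_active.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Tree":
        return cls(
            feature=np.asarray(d["feature"], dtype=np.int32),
            threshold=np.asarray(d["threshold"], dtype=float),
            left=np.asarray(d["left"], dtype=np.int32),
            right=np.asarray(d["right"], dtype=np.int32),
            prob_active=np.asarray(d["prob_active"], dtype=float),
        )


class _TreeBuilder:
    """Grows one tree; node ids are assigned in preorder."""

    def __init__(self, X, y, max_depth, min_samples_split, k_features, rng):
        self.X = X
        self.y = y
        self.max_depth = math.inf if max_depth is None else max_depth
        self.min_samples_split = min_samples_split
        self.k = k_features
        self.rng = rng
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.prob: list[float] = []

    def build(self, idx: np.ndarray) -> Tree:
        self._grow(idx, depth=0)
        return Tree(
            feature=np.asarray(self.feature, dtype=np.int32),
            threshold=np.asarray(self.threshold, dtype=float),
            left=np.asarray(self.left, dtype=np.int32),
            right=np.asarray(self.right, dtype=np.int32),
            prob_active=np.asarray(self.prob, dtype=float),
        )

    def _add_node(self, pa: float) -> int:
        node = len(self.feature)
        self.feature.append(-1)
        self.threshold.append(0.5)
        self.left.append(-1)
        self.right.append(-1)
        self.prob.append(pa)
        return node

    def _grow(self, idx: np.ndarray, depth: int) -> int:
        y = self.y[idx]
        pa = float(y.mean())
        node = self._add_node(pa)
        g_node = modified_gini(pa, 1.0 - pa)
        if (
            depth >= self.max_depth
            or len(idx) < self.min_samples_split
            or g_node <= _SPLIT_TOL
        ):
            return node

        n_feat = self.X.shape[1]
        feats = np.sort(self.rng.choice(n_feat, size=self.k, replace=False))
        Xs = self.X[np.ix_(idx, feats)].astype(float)
        n = len(idx)
        # Binary features at threshold 0.5: "right" side is the set of ones.
        n_right = Xs.sum(axis=0)
        s_right = y @ Xs
        n_left = n - n_right
        s_left = y.sum() - s_right
        with np.errstate(invalid="ignore", divide="ignore"):
            pa_r = np.where(n_right > 0, s_right / np.maximum(n_right, 1), 0.0)
            pa_l = np.where(n_left > 0, s_left / np.maximum(n_left, 1), 0.0)
        g_r = 1.0 - (pa_r**2 + (1.0 - pa_r) ** 2)
        g_l = 1.0 - (pa_l**2 + (1.0 - pa_l) ** 2)
        cost = (g_l * n_left + g_r * n_right) / n
        degenerate = (n_left == 0) | (n_right == 0)
        cost = np.where(degenerate, g_node, cost)

        # feats sorted ⇒ ties go to lowest feature id; ties are detected with
        # a tolerance so float noise cannot flip a mathematically equal pair
        best = int(np.flatnonzero(cost <= cost.min() + _SPLIT_TOL)[0])
        if cost[best] >= g_node - _SPLIT_TOL:
            return node

        f = int(feats[best])
        mask_right = self.X[idx, f] > 0.5
        self.feature[node] = f
        self.left[node] = self._grow(idx[~mask_right], depth + 1)
        self.right[node] = self._grow(idx[mask_right], depth + 1)
        return node


class ProbabilisticRandomForestClassifier(ClassifierMixin, BaseEstimator):
    """Random-forest classifier accepting probabilistic binary labels.

    Parameters
    ----------
    n_estimators : int, default 100
        Number of trees.
    max_depth : int or None, default None
        Depth limit; ``None`` grows until no split reduces the impurity
        (bounded anyway on binary features, which cannot be reused along a
        path).
    min_samples_split : int, default 2
        Minimum samples a node needs to be considered for splitting.
    max_features : "sqrt", int or None, default "sqrt"
        Candidate features per node: ⌈√n_features⌉, a fixed count, or all.
    keep_proba : float, default 0.05
        Prediction-time lower bound on the propagation probability π; a
        branch whose mass falls below it is pruned and the surviving mass is
        renormalised.  Inert when features carry no uncertainty (π ∈ {0, 1}).
    bootstrap : bool, default True
        Grow each tree on a bootstrap resample of the data.
    random_state : int or None, default None
        Seed; a fixed value makes fitting and prediction bit-reproducible.

    The target passed to :meth:`fit` may be hard labels in {0, 1} or soft
    labels in [0, 1] (the probability of the active class); with hard labels
    the learner reduces exactly to a classical random forest.

    Attributes
    ----------
    trees_ : list of :class:`Tree`
        The fitted forest.
    n_features_in_ : int
    classes_ : ndarray of shape (2,), always ``[0, 1]``.
    mode_ : str
        ``"soft"`` or ``"hard"`` depending on the labels seen by ``fit``.
    """

    def __init__(
        self,
        n_estimators: int = 100,
        max_depth: int | None = None,
        min_samples_split: int = 2,
        max_features="sqrt",
        keep_proba: float = 0.05,
        bootstrap: bool = True,
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.min_samples_split = min_samples_split
        self.max_features = max_features
        self.keep_proba = keep_proba
        self.bootstrap = bootstrap
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def _resolve_k(self, n_features: int) -> int:
        if self.max_features is None:
            return n_features
        if self.max_features == "sqrt":
            return int(math.ceil(math.sqrt(n_features)))
        k = int(self.max_features)
        if not 1 <= k <= n_features:
            raise ValueError(
                f"max_features={k} outside 1..{n_features}"
            )
        return k

    def fit(self, X, y):
        """Grow the forest on binary features ``X`` and labels ``y`` ∈ [0, 1]."""
        X = self._validate_features(X, reset=True)
        y = np.asarray(y, dtype=float)
        if y.shape != (X.shape[0],):
            raise ValueError(f"y must have shape ({X.shape[0]},), got {y.shape}")
        if ((y < 0) | (y > 1)).any() or not np.isfinite(y).all():
            raise ValueError("labels must lie in [0, 1]")
        if not 0 <= self.keep_proba < 1:
            raise ValueError("keep_proba must lie in [0, 1)")
        if X.shape[0] < self.min_samples_split:
            raise ValueError(
                f"need at least min_samples_split={self.min_samples_split} samples"
            )
        if (X == X[0]).all():
            logger.warning(
                "all feature rows identical; forest degenerates to the prior"
            )
        self.mode_ = "hard" if np.isin(y, (0.0, 1.0)).all() else "soft"
        self.classes_ = np.array([0, 1])
        k = self._resolve_k(X.shape[1])
        rng = np.random.default_rng(self.random_state)
        n = X.shape[0]
        trees = []
        for _ in range(self.n_estimators):
            if self.bootstrap:
                idx = rng.integers(0, n, size=n)
            else:
                idx = np.arange(n)
            builder = _TreeBuilder(
                X, y, self.max_depth, self.min_samples_split, k, rng
            )
            trees.append(builder.build(idx))
        self.trees_ = trees
        return self

    def _validate_features(self, X, reset: bool) -> np.ndarray:
        if isinstance(X, FeatureMatrix):
            X = X.values
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if not np.isin(X, (0, 1)).all():
            raise ValueError("features must be binary (0/1)")
        if reset:
            self.n_features_in_ = X.shape[1]
        elif X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; the model was fitted with "
                f"{self.n_features_in_}"
            )
        return X.astype(np.int8)

    # -- prediction --------------------------------------------------------

    def predict_proba(self, X, X_sd=None) -> np.ndarray:
        """Class-probability matrix, columns ordered as ``classes_`` = [0, 1].

        ``X_sd`` optionally gives a per-feature Gaussian measurement sd; the
        propagation mass of each sample then splits across branches, with
        branches below ``keep_proba`` pruned and the survivors renormalised.
        Without it every sample deterministically reaches one leaf per tree.
        """
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "trees_")
        X = self._validate_features(X, reset=False)
        if X_sd is None:
            per_tree = np.stack(
                [_route_deterministic(t, X) for t in self.trees_], axis=1
            )
        else:
            X_sd = np.asarray(X_sd, dtype=float)
            if X_sd.shape != (self.n_features_in_,):
                raise ValueError(
                    f"X_sd must have shape ({self.n_features_in_},)"
                )
            per_tree = np.empty((X.shape[0], len(self.trees_)))
            for j, t in enumerate(self.trees_):
                for i in range(X.shape[0]):
                    per_tree[i, j] = _propagate(
                        t, X[i], X_sd, self.keep_proba
                    )
        pr_a = per_tree.mean(axis=1)
        return np.column_stack([1.0 - pr_a, pr_a])

    def predict(self, X, X_sd=None) -> np.ndarray:
        proba = self.predict_proba(X, X_sd=X_sd)
        return (proba[:, 1] >= 0.5).astype(int)

    def predict_detail(self, X, X_sd=None) -> "PredictionResult":
        """Forest probabilities plus per-tree votes and their dispersion."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "trees_")
        Xv = self._validate_features(X, reset=False)
        if X_sd is None:
            per_tree = np.stack(
                [_route_deterministic(t, Xv) for t in self.trees_], axis=1
            )
        else:
            X_sd = np.asarray(X_sd, dtype=float)
            per_tree = np.empty((Xv.shape[0], len(self.trees_)))
            for j, t in enumerate(self.trees_):
                for i in range(Xv.shape[0]):
                    per_tree[i, j] = _propagate(t, Xv[i], X_sd, self.keep_proba)
        pr_a = per_tree.mean(axis=1)
        vote_fraction = (per_tree >= 0.5).mean(axis=1)
        dispersion = per_tree.std(axis=1, ddof=0)
        return PredictionResult(
            prob_active=pr_a,
            prob_inactive=1.0 - pr_a,
            per_tree=per_tree,
            vote_fraction_active=vote_fraction,
            vote_dispersion=dispersion,
        )

    # -- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "trees_")
        d = {
            "format_version": SERIALIZATION_VERSION,
            "hyperparameters": self.get_params(),
            "n_features_in": int(self.n_features_in_),
            "mode": self.mode_,
            "trees": [t.to_dict() for t in self.trees_],
        }
        if getattr(self, "label_config_", None) is not None:
            d["label_config"] = {
                "p_threshold": self.label_config_.p_threshold,
                "sigma": self.label_config_.sigma,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProbabilisticRandomForestClassifier":
        if d.get("format_version") != SERIALIZATION_VERSION:
            raise ValueError(
                f"unsupported model format version {d.get('format_version')!r}"
            )
        model = cls(**d["hyperparameters"])
        model.n_features_in_ = d["n_features_in"]
        model.mode_ = d["mode"]
        model.classes_ = np.array([0, 1])
        model.trees_ = [Tree.from_dict(t) for t in d["trees"]]
        if "label_config" in d:
            model.label_config_ = LabelConfig(**d["label_config"])
        return model


@dataclass
class PredictionResult:
    """Forest output with per-tree detail.

    ``prob_active``/``prob_inactive`` are the probability-averaged forest
    outputs (the primary prediction); ``vote_fraction_active`` is the share
    of trees whose own output favours the active class, an alternative
    certainty readout; ``vote_dispersion`` the per-sample sd across trees.
    """

    prob_active: np.ndarray
    prob_inactive: np.ndarray
    per_tree: np.ndarray
    vote_fraction_active: np.ndarray
    vote_dispersion: np.ndarray


def _route_deterministic(tree: Tree, X: np.ndarray) -> np.ndarray:
    """Leaf P̄_A for every row of X when features are exact (π ∈ {0,1})."""
    node = np.zeros(X.shape[0], dtype=np.int64)
    while True:
        feat = tree.feature[node]
        live = np.where(feat >= 0)[0]
        if live.size == 0:
            return tree.prob_active[node]
        go_right = X[live, feat[live]] > tree.threshold[node[live]]
        node[live] = np.where(
            go_right, tree.right[node[live]], tree.left[node[live]]
        )


def _propagate(
    tree: Tree, x: np.ndarray, x_sd: np.ndarray, keep_proba: float
) -> float:
    """Probabilistic propagation of one sample with Gaussian feature noise.

    At each internal node the mass splits by P(x_f + ε > threshold) with
    ε ~ N(0, sd_f²).  Branches whose mass drops below ``keep_proba`` are
    pruned; the prediction is Σ π(leaf)·P̄_A over surviving leaves with the
    mass renormalised.  If pruning removes every branch the single highest-π
    path is followed instead, so a prediction always exists.
    """
    survivors: list[tuple[float, float]] = []  # (pi, leaf P̄_A)

    def descend(node: int, pi: float) -> None:
        f = tree.feature[node]
        if f < 0:
            survivors.append((pi, tree.prob_active[node]))
            return
        sd = x_sd[f]
        if sd > 0:
            p_right = float(ndtr((x[f] - tree.threshold[node]) / sd))
        else:
            p_right = 1.0 if x[f] > tree.threshold[node] else 0.0
        for child, mass in (
            (tree.right[node], pi * p_right),
            (tree.left[node], pi * (1.0 - p_right)),
        ):
            if mass > 0 and mass >= keep_proba:
                descend(child, mass)

    descend(0, 1.0)
    if survivors:
        total = sum(pi for pi, _ in survivors)
        return sum(pi * p for pi, p in survivors) / total

    # Every branch fell below keep_proba: greedily follow the heaviest one.
    node, pi = 0, 1.0
    while tree.feature[node] >= 0:
        f = tree.feature[node]
        sd = x_sd[f]
        if sd > 0:
            p_right = float(ndtr((x[f] - tree.threshold[node]) / sd))
        else:
            p_right = 1.0 if x[f] > tree.threshold[node] else 0.0
        if p_right >= 0.5:
            node = tree.right[node]
        else:
            node = tree.left[node]
    return float(tree.prob_active[node])


# -- module-level convenience wrappers ------------------------------------


def fit(
    dataset: SoftLabelDataset, **hyperparameters
) -> ProbabilisticRandomForestClassifier:
    """Fit a probabilistic forest on a labelled dataset's soft labels."""
    model = ProbabilisticRandomForestClassifier(**hyperparameters)
    model.fit(dataset.features.values, dataset.delta_y)
    model.label_config_ = dataset.config
    return model


def fit_hard_rf(
    dataset: SoftLabelDataset, **hyperparameters
) -> ProbabilisticRandomForestClassifier:
    """Fit the same learner on the hard labels — the classical-RF baseline."""
    model = ProbabilisticRandomForestClassifier(**hyperparameters)
    model.fit(dataset.features.values, dataset.hard_label.astype(float))
    model.label_config_ = dataset.config
    return model


def predict_proba(
    model: ProbabilisticRandomForestClassifier,
    features: FeatureMatrix | np.ndarray,
    X_sd: np.ndarray | None = None,
) -> np.ndarray:
    """Active-class probability for each row of ``features``."""
    return model.predict_proba(features, X_sd=X_sd)[:, 1]


def save_model(
    model: ProbabilisticRandomForestClassifier, path: str | Path
) -> None:
    """Write the versioned JSON model container."""
    Path(path).write_text(
        json.dumps(model.to_dict(), sort_keys=True, separators=(",", ":"))
    )


def load_model(path: str | Path) -> ProbabilisticRandomForestClassifier:
    """Load a model saved by :func:`save_model`; predictions round-trip exactly."""
    return ProbabilisticRandomForestClassifier.from_dict(
        json.loads(Path(path).read_text())
    )
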