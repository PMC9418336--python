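"""Probabilistic classification with margin-driven active learning.

A random forest (250 trees by default) is trained on labeled points, class
probabilities are predicted wall-to-wall, and the per-pixel probability
margin

    M_prob = p(most likely class) - p(second most likely class)

flags low-confidence regions. The class-wise 25th percentile of M_prob
over the pixels predicted as each class serves as a threshold; additional
training locations are sampled below it, labeled (by the scene truth in
tests, by an interpreter in production via the pluggable labeler
callback), and the model is retrained. The same machinery with a class
filter supports targeted augmentation of a single hard-to-train class,
such as short-term fallow.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .core import ClassMap, FeatureStack

logger = logging.getLogger(__name__)


@dataclass
class TrainingSet:
    """Feature matrix + labels with per-sample provenance tags."""

    X: np.ndarray
    y: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    tags: np.ndarray  # e.g. initial / fallow-augmented / margin-augmented

    def __post_init__(self) -> None:
        n = len(self.y)
        for name in ("X", "rows", "cols", "tags"):
            if len(getattr(self, name)) != n:
                raise ValueError("training arrays must align")

    def __len__(self) -> int:
        return len(self.y)

    def counts_by_tag(self):
        import pandas as pd

        df = pd.DataFrame({"class_code": self.y, "tag": self.tags})
        return df.groupby(["class_code", "tag"]).size().unstack(fill_value=0)

    def extend(self, X, y, rows, cols, tag: str) -> "TrainingSet":
        return TrainingSet(
            np.vstack([self.X, X]), np.concatenate([self.y, y]),
            np.concatenate([self.rows, rows]),
            np.concatenate([self.cols, cols]),
            np.concatenate([self.tags, np.full(len(y), tag, dtype=object)]),
        )


@dataclass
class ProbabilityStack:
    """Per-pixel class probabilities, classes in ascending code order."""

    classes: np.ndarray  # (k,) class codes, ascending
    probs: np.ndarray    # (k, H, W), each pixel sums to 1

    def __post_init__(self) -> None:
        if self.probs.shape[0] != len(self.classes):
            raise ValueError("one probability layer per class required")
        if np.any(np.diff(self.classes) <= 0):
            raise ValueError("classes must be in ascending code order")


@dataclass
class LearnerConfig:
    n_trees: int = 250
    margin_quantile: float = 0.25
    augment_per_class: int = 50
    min_dist_px: float = 0.0
    quantile_subsample: int = 1_000_000
    seed: int = 0


def train_classifier(X: np.ndarray, y: np.ndarray, n_trees: int = 250,
                     seed: int = 0) -> RandomForestClassifier:
    """Fit a seeded random forest; rows with undefined features are
    dropped (with a logged count) and single-class input is rejected."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    keep = np.all(np.isfinite(X), axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d training rows with undefined features",
                    dropped)
        X, y = X[keep], y[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least two classes")
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                   n_jobs=1)
    model.fit(X, y)
    return model


def predict_probabilities(model, stack: FeatureStack,
                          batch: int = 262_144) -> ProbabilityStack:
    """Wall-to-wall class probabilities; rows with undefined features get
    a uniform distribution (and are normalized like every other pixel)."""
    h, w = stack.shape
    flat = stack.data.reshape(stack.data.shape[0], -1).T
    k = len(model.classes_)
    out = np.empty((flat.shape[0], k), dtype=np.float64)
    finite = np.all(np.isfinite(flat), axis=1)
    out[~finite] = 1.0 / k
    idx = np.nonzero(finite)[0]
    for start in range(0, len(idx), batch):
        sel = idx[start:start + batch]
        out[sel] = model.predict_proba(flat[sel])
    out /= out.sum(axis=1, keepdims=True)
    return ProbabilityStack(np.asarray(model.classes_),
                            out.T.reshape(k, h, w))


def classify(prob: ProbabilityStack, pixel_size: float = 1.0) -> ClassMap:
    """Argmax classification; ties break to the lowest class code."""
    idx = np.argmax(prob.probs, axis=0)  # first maximum = lowest code
    return ClassMap(prob.classes[idx].astype(np.uint8),
                    pixel_size=pixel_size)


def margin(prob: ProbabilityStack) -> np.ndarray:
    """M_prob: top probability minus runner-up probability per pixel."""
    if prob.probs.shape[0] < 2:
        return np.ones(prob.probs.shape[1:])
    part = np.partition(prob.probs, -2, axis=0)
    return part[-1] - part[-2]


def classwise_margin_threshold(margin_map: np.ndarray, predicted: ClassMap,
                               q: float = 0.25,
                               subsample: int = 1_000_000,
                               seed: int = 0) -> dict[int, float]:
    """Per-class q-quantile of M_prob over the pixels predicted as each
    class. Rasters above ``subsample`` pixels are subsampled reproducibly;
    classes absent from the prediction are skipped with a warning."""
    rng = np.random.default_rng(seed)
    codes = predicted.codes.ravel()
    marg = np.asarray(margin_map).ravel()
    if len(codes) > subsample:
        sel = rng.choice(len(codes), subsample, replace=False)
        codes, marg = codes[sel], marg[sel]
    thresholds: dict[int, float] = {}
    for c in np.unique(predicted.codes):
        vals = marg[codes == c]
        if vals.size == 0:
            warnings.warn(f"class {int(c)} absent from prediction; "
                          "no margin threshold", stacklevel=2)
            continue
        thresholds[int(c)] = float(np.quantile(vals, q))
    return thresholds


def sample_low_confidence(margin_map: np.ndarray, predicted: ClassMap,
                          thresholds: dict[int, float],
                          n_per_class: int = 50, min_dist_px: float = 0.0,
                          seed: int = 0,
                          classes: list[int] | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Seeded sample of pixel locations with below-threshold margins.

    Returns (rows, cols) of up to ``n_per_class`` locations per class
    (optionally restricted to ``classes``, e.g. for targeted augmentation
    of one rare class); shortfalls are logged, not fatal.
    """
    rng = np.random.default_rng(seed)
    rows_out: list[int] = []
    cols_out: list[int] = []
    for c in sorted(thresholds):
        if classes is not None and c not in classes:
            continue
        mask = (predicted.codes == c) & (margin_map < thresholds[c])
        rs, cs = np.nonzero(mask)
        if rs.size == 0:
            logger.info("class %d: no low-margin pixels to sample", c)
            continue
        order = rng.permutation(rs.size)
        taken = 0
        for i in order:
            if taken >= n_per_class:
                break
            r, c_ = int(rs[i]), int(cs[i])
            if min_dist_px > 0 and rows_out:
                arr_r = np.asarray(rows_out, dtype=float)
                arr_c = np.asarray(cols_out, dtype=float)
                if np.min(np.hypot(arr_r - r, arr_c - c_)) < min_dist_px:
                    continue
            rows_out.append(r)
            cols_out.append(c_)
            taken += 1
        if taken < n_per_class:
            logger.info("class %d: sampled %d of %d low-margin locations",
                        c, taken, n_per_class)
    return np.asarray(rows_out, dtype=int), np.asarray(cols_out, dtype=int)


def compare_augmentation_strategies(stack: FeatureStack, truth_codes: np.ndarray,
                                    n_initial_per_class: int = 8,
                                    n_augment_per_class: int = 15,
                                    n_trees: int = 100,
                                    min_dist_px: float = 4.0,
                                    seed: int = 0) -> dict:
    """Margin-targeted versus same-budget random augmentation, one replicate.

    From a shared initial random sample, one branch augments the training
    set at low-margin locations of the initial prediction and the other
    adds the same number of randomly placed points; both are labeled from
    the truth map and refitted. Both final models are scored on full-map
    accuracy over every pixel not used for training by either branch, so
    the comparison is paired and free of hold-out sampling noise. Returns
    the two accuracies and the initial-model accuracy.
    """
    rng = np.random.default_rng(seed)

    def random_points(n_per_class, rng_):
        rows, cols = [], []
        for c in np.unique(truth_codes):
            rs, cs = np.nonzero(truth_codes == c)
            sel = rng_.choice(rs.size, size=min(n_per_class, rs.size),
                              replace=False)
            rows.append(rs[sel])
            cols.append(cs[sel])
        return np.concatenate(rows), np.concatenate(cols)

    ir, ic = random_points(n_initial_per_class, rng)
    iy = truth_codes[ir, ic]
    model0 = train_classifier(stack.values_at(ir, ic), iy, n_trees, seed)

    prob = predict_probabilities(model0, stack)
    pred = classify(prob)
    marg = margin(prob)
    thresholds = classwise_margin_threshold(marg, pred, seed=seed)
    mr, mc = sample_low_confidence(marg, pred, thresholds,
                                   n_augment_per_class,
                                   min_dist_px=min_dist_px, seed=seed)
    n_budget = mr.size
    Xm = np.vstack([stack.values_at(ir, ic), stack.values_at(mr, mc)])
    ym = np.concatenate([iy, truth_codes[mr, mc]])
    model_margin = train_classifier(Xm, ym, n_trees, seed)

    rr, rc = random_points(n_augment_per_class, np.random.default_rng(seed + 1))
    if rr.size > n_budget:  # match budgets exactly
        keep = np.random.default_rng(seed + 2).choice(rr.size, n_budget,
                                                      replace=False)
        rr, rc = rr[keep], rc[keep]
    Xr = np.vstack([stack.values_at(ir, ic), stack.values_at(rr, rc)])
    yr = np.concatenate([iy, truth_codes[rr, rc]])
    model_random = train_classifier(Xr, yr, n_trees, seed)

    eval_mask = np.ones(truth_codes.shape, dtype=bool)
    eval_mask[ir, ic] = False
    eval_mask[mr, mc] = False
    eval_mask[rr, rc] = False

    def map_accuracy(model):
        p = predict_probabilities(model, stack)
        cm = classify(p)
        return float(np.mean(cm.codes[eval_mask] == truth_codes[eval_mask]))

    return {
        "initial_accuracy": float(np.mean(
            pred.codes[eval_mask] == truth_codes[eval_mask])),
        "margin_accuracy": map_accuracy(model_margin),
        "random_accuracy": map_accuracy(model_random),
        "n_augmented": int(n_budget),
    }


@dataclass
class ActiveLearningResult:
    model: RandomForestClassifier
    training: TrainingSet
    history: list[dict] = field(default_factory=list)


def run_active_learning(stack: FeatureStack, initial: TrainingSet,
                        labeler, cfg: LearnerConfig | None = None,
                        extra_random: tuple[np.ndarray, np.ndarray] | None = None,
                        eval_points: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
                        ) -> ActiveLearningResult:
    """Two-stage margin-driven training.

    Iteration 0 fits the initial model; iteration 1 adds optional extra
    random locations plus margin-targeted locations (labeled through the
    ``labeler(rows, cols) -> class codes`` callback) and refits. When
    ``eval_points = (rows, cols, labels)`` is given, hold-out accuracy is
    recorded per iteration.
    """
    cfg = cfg or LearnerConfig()
    history: list[dict] = []

    def _evaluate(model):
        if eval_points is None:
            return None
        er, ec, ey = eval_points
        pred = model.predict(stack.values_at(er, ec))
        return float(np.mean(pred == ey))

    model = train_classifier(initial.X, initial.y, cfg.n_trees, cfg.seed)
    history.append({"iteration": 0, "n_samples": len(initial),
                    "accuracy": _evaluate(model)})

    training = initial
    if extra_random is not None:
        rr, cc = extra_random
        training = training.extend(stack.values_at(rr, cc), labeler(rr, cc),
                                   rr, cc, tag="extra-random")
    prob = predict_probabilities(model, stack)
    pred = classify(prob, pixel_size=stack.pixel_size)
    marg = margin(prob)
    thresholds = classwise_margin_threshold(
        marg, pred, cfg.margin_quantile, cfg.quantile_subsample, cfg.seed)
    rr, cc = sample_low_confidence(marg, pred, thresholds,
                                   cfg.augment_per_class, cfg.min_dist_px,
                                   cfg.seed)
    if rr.size:
        training = training.extend(stack.values_at(rr, cc), labeler(rr, cc),
                                   rr, cc, tag="margin-augmented")
    model = train_classifier(training.X, training.y, cfg.n_trees, cfg.seed)
    history.append({"iteration": 1, "n_samples": len(training),
                    "accuracy": _evaluate(model)})
    return ActiveLearningResult(model, training, history)
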