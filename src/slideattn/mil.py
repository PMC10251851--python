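"""Attention-based multiple-instance bag classifier (the slide-level
lymph-node predictor).

A slide is a bag of patch feature vectors with a single binary label.
Gated attention pooling assigns each instance a weight

    a_k = softmax_k( w^T ( tanh(V h_k) * sigmoid(U h_k) ) )

and the bag embedding  z = sum_k a_k h_k  feeds a linear two-class head.
Training minimizes the binary smooth top-1 SVM loss (a temperature-
smoothed multiclass hinge, more robust to label noise than cross-entropy)
with Adam, early stopping on the monitored loss, and patient-level
stratified five-fold cross-validation. The attention weights double as
per-patch importance scores for heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax

from ._optim import Adam
from .bags import FeatureBag
from .features import Standardizer


@dataclass
class AttentionParams:
    """Gated-attention parameters: V, U (hidden x dim) and vector w."""

    v: np.ndarray
    u: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        if self.v.shape != self.u.shape or self.w.shape != (self.v.shape[0],):
            raise ValueError("inconsistent attention parameter shapes")


@dataclass
class TrainConfig:
    """Optimization settings for the bag classifier."""

    lr: float = 1e-4
    weight_decay: float = 1e-5
    beta1: float = 0.9
    beta2: float = 0.999
    max_epochs: int = 200
    patience: int = 20
    rel_tol: float = 1e-4  # "loss did not change" = rel. improvement below this
    tau: float = 1.0  # smooth top-1 SVM temperature
    alpha: float = 1.0  # margin
    hidden: int | None = None  # attention hidden size L; None = min(128, 4*dim)
    standardize: bool = True
    monitor: str = "train"  # or "val" when validation bags are supplied
    restarts: int = 3  # independent initializations; best final loss wins

    def __post_init__(self) -> None:
        for name in ("lr", "beta1", "beta2", "max_epochs", "tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hidden is not None and self.hidden < 1:
            raise ValueError("hidden must be >= 1")
        if self.weight_decay < 0 or self.alpha < 0 or self.patience < 0:
            raise ValueError("weight_decay, alpha and patience must be >= 0")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass
class MILModel:
    """Trained attention-MIL model: attention parameters + linear bag head."""

    attention: AttentionParams
    head_w: np.ndarray  # (2, dim)
    head_b: np.ndarray  # (2,)
    config: TrainConfig
    scaler: Standardizer | None = None
    fold_id: int | None = None
    seed: int = 0
    training_log: list = field(default_factory=list)
    stopped_epoch: int | None = None

    @property
    def dim(self) -> int:
        return self.head_w.shape[1]


@dataclass
class BagPrediction:
    """Bag scores, positive-class probability, per-instance attention."""

    scores: np.ndarray  # (2,)
    probability: float
    attention: np.ndarray  # (N,), >= 0, sums to 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("probability outside [0, 1]")
        if (self.attention < 0).any() or abs(self.attention.sum() - 1.0) > 1e-6:
            raise ValueError("attention must be a probability vector")


def attention_pool(features: np.ndarray, params: AttentionParams):
    """Gated attention pooling.

    Returns ``(embedding, attention)`` with attention the softmax over
    instances of the gated scores; the embedding is the attention-weighted
    sum of instance features (permutation invariant).
    """
    h = np.asarray(features, dtype=np.float64)
    if h.ndim != 2 or h.shape[0] < 1:
        raise ValueError("need at least one instance")
    t = np.tanh(h @ params.v.T)  # (N, L)
    g = 1.0 / (1.0 + np.exp(-(h @ params.u.T)))  # (N, L)
    e = (t * g) @ params.w  # (N,)
    a = softmax(e)
    return a @ h, a


def smooth_top1_svm_loss(scores, label: int, tau: float = 1.0,
                         alpha: float = 1.0) -> float:
    """Binary smooth top-1 SVM loss.

    L = tau * log( sum_j exp( (alpha*[j != y] + s_j - s_y) / tau ) ),
    a temperature-smoothed margin loss that tends to the multiclass hinge
    max_j(alpha*[j != y] + s_j - s_y) as tau -> 0 (gap at most tau*log 2,
    the smoothed maximum over the two classes).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    s = np.asarray(scores, dtype=np.float64)
    if s.shape != (2,):
        raise ValueError("scores must be a 2-vector")
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    margins = alpha * (np.arange(2) != label) + s - s[label]
    return float(tau * logsumexp(margins / tau))


def _loss_grad_scores(s: np.ndarray, label: int, tau: float, alpha: float):
    """Loss and its gradient in the two class scores."""
    margins = alpha * (np.arange(2) != label) + s - s[label]
    u = margins / tau
    loss = float(tau * logsumexp(u))
    q = softmax(u)
    grad = q.copy()
    grad[label] -= 1.0
    return loss, grad


def _forward_backward(h: np.ndarray, label: int, params: AttentionParams,
                      head_w: np.ndarray, head_b: np.ndarray,
                      tau: float, alpha: float):
    """One bag's loss and gradients for all trainable arrays."""
    t = np.tanh(h @ params.v.T)
    g = 1.0 / (1.0 + np.exp(-(h @ params.u.T)))
    tg = t * g
    e = tg @ params.w
    a = softmax(e)
    z = a @ h
    s = head_w @ z + head_b
    loss, d_s = _loss_grad_scores(s, label, tau, alpha)

    g_head_w = np.outer(d_s, z)
    g_head_b = d_s
    d_z = head_w.T @ d_s
    d_a = h @ d_z
    d_e = a * (d_a - float(a @ d_a))  # softmax jacobian
    g_w = tg.T @ d_e
    d_tg = np.outer(d_e, params.w)
    d_t = d_tg * g
    d_g = d_tg * t
    d_zv = d_t * (1.0 - t ** 2)
    d_zu = d_g * g * (1.0 - g)
    g_v = d_zv.T @ h
    g_u = d_zu.T @ h
    return loss, [g_v, g_u, g_w, g_head_w, g_head_b]


def _init_model(dim: int, config: TrainConfig, rng) -> MILModel:
    # capped-proportional hidden size: wide attention layers are badly
    # conditioned when the feature dimension is small
    L = config.hidden if config.hidden is not None else min(128, 4 * dim)
    sd = 1.0 / np.sqrt(dim)
    # w starts at zero so attention begins exactly uniform; random V/U break
    # the symmetry. A randomly initialized w can lock attention onto an
    # arbitrary direction early and never recover at small learning rates.
    params = AttentionParams(
        v=rng.standard_normal((L, dim)) * sd,
        u=rng.standard_normal((L, dim)) * sd,
        w=np.zeros(L),
    )
    return MILModel(attention=params,
                    head_w=rng.standard_normal((2, dim)) * sd,
                    head_b=np.zeros(2), config=config)


def _mean_loss(model: MILModel, bags, mats) -> float:
    total = 0.0
    for bag, h in zip(bags, mats):
        z, _ = attention_pool(h, model.attention)
        s = model.head_w @ z + model.head_b
        total += smooth_top1_svm_loss(s, bag.label, model.config.tau,
                                      model.config.alpha)
    return total / len(bags)


def train(bags: list[FeatureBag], config: TrainConfig | None = None,
          seed: int = 0, val_bags: list[FeatureBag] | None = None) -> MILModel:
    """Train the attention-MIL classifier on a list of bags.

    One bag per optimization step (bags have variable size), Adam with l2
    weight decay, loss averaged per epoch. Early stopping: when the
    monitored loss fails to improve on its best value by a relative
    ``rel_tol`` for ``patience`` consecutive epochs (at least one), the
    epoch loop stops and the best-epoch weights are restored.

    The non-convex attention objective occasionally locks onto a spurious
    instance direction, so ``config.restarts`` independent initializations
    are trained and the one with the best final monitored (training-side)
    loss is returned; no held-out data enters the selection. Deterministic
    given ``seed``.
    """
    config = config or TrainConfig()
    best_model, best_loss = None, np.inf
    for r in range(config.restarts):
        run_seed = seed if r == 0 else np.random.SeedSequence([seed, r])
        model = _train_once(bags, config, run_seed, val_bags)
        final = min((e["monitored"] for e in model.training_log),
                    default=np.inf)
        if best_model is None or final < best_loss:
            best_model, best_loss = model, final
    best_model.seed = seed
    return best_model


def _train_once(bags: list[FeatureBag], config: TrainConfig, seed,
                val_bags: list[FeatureBag] | None = None) -> MILModel:
    labels = {bag.label for bag in bags}
    if labels != {0, 1}:
        raise ValueError("training set must contain both classes")
    if config.monitor == "val" and not val_bags:
        raise ValueError("monitor='val' requires val_bags")
    rng = np.random.default_rng(seed)

    scaler = None
    mats = [bag.features for bag in bags]
    if config.standardize:
        scaler = Standardizer().fit(np.vstack(mats))
        mats = [scaler.transform(m) for m in mats]
    val_mats = None
    if val_bags:
        val_mats = [scaler.transform(b.features) if scaler else b.features
                    for b in val_bags]

    model = _init_model(mats[0].shape[1], config, rng)
    model.scaler = scaler
    params = [model.attention.v, model.attention.u, model.attention.w,
              model.head_w, model.head_b]
    opt = Adam(params, lr=config.lr, beta1=config.beta1, beta2=config.beta2,
               weight_decay=config.weight_decay)

    best = np.inf
    best_weights = [p.copy() for p in params]
    stall = 0
    n = len(bags)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        train_loss = 0.0
        for i in order:
            loss, grads = _forward_backward(
                mats[i], bags[i].label, model.attention, model.head_w,
                model.head_b, config.tau, config.alpha)
            opt.step(grads)
            train_loss += loss
        train_loss /= n
        monitored = train_loss
        if config.monitor == "val":
            monitored = _mean_loss(model, val_bags, val_mats)
        model.training_log.append({"epoch": epoch, "train_loss": train_loss,
                                   "monitored": monitored})
        if monitored < best * (1.0 - config.rel_tol):
            best = monitored
            best_weights = [p.copy() for p in params]
            stall = 0
        else:
            stall += 1
            if stall >= max(1, config.patience):
                break
    for p, w in zip(params, best_weights):
        p[...] = w
    model.stopped_epoch = len(model.training_log) - 1
    return model


def predict(model: MILModel, bag: FeatureBag) -> BagPrediction:
    """Score one bag; returns class scores, P(positive), and attention."""
    h = bag.features
    if h.shape[1] != model.dim:
        raise ValueError(f"bag has {h.shape[1]}-d features, model expects {model.dim}")
    if model.scaler is not None:
        h = model.scaler.transform(h)
    z, a = attention_pool(h, model.attention)
    s = model.head_w @ z + model.head_b
    p = float(softmax(s)[1])
    return BagPrediction(scores=s, probability=p, attention=a)


def _patient_table(bags: list[FeatureBag]) -> pd.DataFrame:
    rows = {}
    for bag in bags:
        if bag.patient_id in rows and rows[bag.patient_id] != bag.label:
            raise ValueError(
                f"patient {bag.patient_id} has inconsistent slide labels")
        rows[bag.patient_id] = bag.label
    return pd.DataFrame({"patient_id": list(rows), "label": list(rows.values())})


def assign_folds(bags: list[FeatureBag], k: int = 5, seed: int = 0) -> dict:
    """Patient-level stratified fold assignment (patient_id -> fold)."""
    patients = _patient_table(bags)
    for lab in (0, 1):
        if (patients["label"] == lab).sum() < k:
            raise ValueError(f"need at least {k} patients of class {lab}")
    rng = np.random.default_rng(seed)
    assignment = {}
    for lab in (0, 1):
        ids = patients.loc[patients["label"] == lab, "patient_id"].to_numpy()
        rng.shuffle(ids)
        for i, pid in enumerate(ids):
            assignment[pid] = i % k
    return assignment


@dataclass
class CVResult:
    """Per-fold models plus pooled out-of-fold slide scores."""

    models: list
    folds: dict  # patient_id -> fold
    scores: pd.DataFrame  # slide_id, patient_id, fold, score, label

    def patient_scores(self) -> pd.DataFrame:
        """Patient-level score = mean of the patient's slide probabilities."""
        return (self.scores.groupby("patient_id")
                .agg(score=("score", "mean"), label=("label", "first"),
                     fold=("fold", "first")).reset_index())


def crossvalidate(bags: list[FeatureBag], k: int = 5, seed: int = 0,
                  config: TrainConfig | None = None,
                  folds: dict | None = None) -> CVResult:
    """Stratified patient-level k-fold cross-validation.

    All slides of a patient share a fold (leakage guard); each slide
    receives exactly one out-of-fold score. A precomputed ``folds``
    mapping can be passed so other classifiers reuse identical splits.
    """
    config = config or TrainConfig()
    folds = folds if folds is not None else assign_folds(bags, k=k, seed=seed)
    models, rows = [], []
    for fold in range(k):
        train_bags = [b for b in bags if folds[b.patient_id] != fold]
        test_bags = [b for b in bags if folds[b.patient_id] == fold]
        model = train(train_bags, config=config, seed=seed + fold)
        model.fold_id = fold
        models.append(model)
        for bag in test_bags:
            pred = predict(model, bag)
            rows.append({"slide_id": bag.slide_id, "patient_id": bag.patient_id,
                         "fold": fold, "score": pred.probability,
                         "label": bag.label})
    return CVResult(models=models, folds=folds,
                    scores=pd.DataFrame(rows))
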