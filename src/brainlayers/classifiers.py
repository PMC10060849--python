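"""Classifiers: linear SVM and a domain-adversarial neural network (DANN).

The DANN has three parts: a feature extractor shared by a *label predictor*
(patient vs control, trained on labeled source-site subjects) and a *domain
classifier* (source vs target site, trained on all subjects).  A
gradient-reversal layer (GRL) sits between the extractor and the domain
classifier: identity on the forward pass, it multiplies backward
sensitivities by −λ, so the extractor is pushed to *remove* the site
information the domain classifier finds while the domain classifier keeps
trying to recover it.  Both losses are class-weighted binary cross-entropies
with weights

    W_c = e^{1/N_c} / Σ_{c'} e^{1/N_{c'}}

so the rarer class receives the larger weight.  Each classification head
ends in two sigmoid units (one per class, uncoupled), which keeps the
per-class weighting effective; the predicted class is the unit with the
larger activation.

Architecture (widths halve from layer to layer): the extractor is one fully
connected layer (input_dim → hidden) with BatchNorm → ReLU → Dropout(0.5);
each head is two fully connected layers (hidden → hidden/2 → 2) with
BatchNorm → ReLU → Dropout between them and a sigmoid output.  Training uses
adam at learning rate 0.001.  All randomness — initialization, shuffling,
dropout — flows from one integer seed through named child streams, so runs
are bit-reproducible and the label path's stream is untouched by the
presence or absence of the domain head (with λ = 0 the label-path trajectory
is identical to a plain MLP's).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from ._nn import Adam, BatchNorm1d, Dropout, GradientReversal, Linear, ReLU, Sigmoid, Stack
from .features import SelectionResult, Standardizer

__all__ = [
    "ClassWeights",
    "DannConfig",
    "TrainedModel",
    "class_weights",
    "weighted_bce",
    "GradientReversal",
    "train_dann",
    "train_svm",
    "predict",
]

_EPS = 1e-7  # probability clamp for the cross-entropy


@dataclass(frozen=True)
class ClassWeights:
    """Exponential-inverse-count class weights; sum to 1, rarer class larger."""

    weights: np.ndarray
    class_counts: np.ndarray

    @property
    def n_total(self) -> int:
        return int(self.class_counts.sum())

    @property
    def n_classes(self) -> int:
        return len(self.class_counts)


def class_weights(labels: Sequence[int] | np.ndarray, n_classes: int = 2) -> ClassWeights:
    """W_c = e^{1/N_c} / Σ e^{1/N_c} from integer class labels 0..C−1."""
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=n_classes)
    if np.any(counts == 0):
        missing = np.flatnonzero(counts == 0).tolist()
        raise ValueError(f"class(es) {missing} absent from the labels")
    raw = np.exp(1.0 / counts)
    return ClassWeights(weights=raw / raw.sum(), class_counts=counts)


def weighted_bce(
    yhat: np.ndarray, y: np.ndarray, weights: ClassWeights | np.ndarray
) -> float:
    """Class-weighted binary cross-entropy, averaged over samples.

    ``yhat`` and ``y`` are N×C arrays of per-class probabilities and 0/1
    truths; the loss is (1/N) Σ_n Σ_c W_c · E(y_{nc}, ŷ_{nc}) with
    E(y, ŷ) = −[y log ŷ + (1−y) log(1−ŷ)].  Probabilities are clamped to
    [ε, 1−ε], ε = 1e−7, so exact 0/1 predictions stay finite.
    """
    w = weights.weights if isinstance(weights, ClassWeights) else np.asarray(weights)
    yhat = np.clip(np.atleast_2d(yhat), _EPS, 1.0 - _EPS)
    y = np.atleast_2d(y)
    if yhat.shape != y.shape or yhat.shape[1] != len(w):
        raise ValueError("yhat, y and weights have inconsistent shapes")
    e = -(y * np.log(yhat) + (1.0 - y) * np.log(1.0 - yhat))
    return float((e * w).sum(axis=1).mean())


def _bce_grad(yhat: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """∂(weighted BCE)/∂ŷ for the clamped loss above."""
    n = yhat.shape[0]
    yc = np.clip(yhat, _EPS, 1.0 - _EPS)
    return w * (yc - y) / (yc * (1.0 - yc)) / n


@dataclass
class DannConfig:
    """Hyperparameters of the domain-adversarial classifier.

    ``extractor_width`` defaults to half the input dimension (the extractor
    halves the width like the heads do); ``lambda_grl`` is the constant GRL
    multiplier (0 disables adversarial pressure on the extractor);
    ``expose_target`` controls whether held-out-site subjects are shown,
    unlabeled, to the domain classifier during training.
    """

    input_dim: int
    extractor_width: Optional[int] = None
    lambda_grl: float = 1.0
    dropout: float = 0.5
    learning_rate: float = 0.001
    epochs: int = 200
    batch_size: int = 64
    seed: int = 0
    domain_adversarial: bool = True
    expose_target: bool = True
    lambda_ramp: bool = False  # optional 0→λ linear ramp over epochs

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError(
                "zero input features: the edge selection is empty — relax the "
                "p-value threshold"
            )
        if self.extractor_width is not None and self.extractor_width < 2:
            raise ValueError("extractor_width must be >= 2")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.lambda_grl < 0.0:
            raise ValueError("lambda_grl must be nonnegative")
        if self.epochs < 1 or self.batch_size < 2:
            raise ValueError("epochs must be >= 1 and batch_size >= 2")

    @property
    def hidden_width(self) -> int:
        """Extractor output width; defaults to half the input dimension."""
        return self.extractor_width or max(self.input_dim // 2, 2)


def _make_head(width: int, dropout: float, rng: np.random.Generator) -> Stack:
    mid = max(width // 2, 2)
    return Stack(
        [
            Linear(width, mid, rng),
            BatchNorm1d(mid),
            ReLU(),
            Dropout(dropout),
            Linear(mid, 2, rng),
            Sigmoid(),
        ]
    )


def _make_extractor(cfg: DannConfig, rng: np.random.Generator) -> Stack:
    return Stack(
        [
            Linear(cfg.input_dim, cfg.hidden_width, rng),
            BatchNorm1d(cfg.hidden_width),
            ReLU(),
            Dropout(cfg.dropout),
        ]
    )


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to apply it to new subjects."""

    kind: str  # "svm" | "dann"
    model: object
    standardizer: Optional[Standardizer] = None
    selections: Optional[dict[str, SelectionResult]] = None
    training_log: Optional[pd.DataFrame] = None
    config: Optional[DannConfig] = None
    class_weights: Optional[ClassWeights] = None


class _DannNet:
    """The three sub-networks and the GRL, bundled for prediction."""

    def __init__(self, cfg: DannConfig) -> None:
        ss = np.random.SeedSequence(cfg.seed)
        (
            s_ext,
            s_lab,
            s_dom,
            s_shuffle,
            s_drop_lab,
            s_drop_dom,
            s_target,
        ) = ss.spawn(7)
        self.extractor = _make_extractor(cfg, np.random.default_rng(s_ext))
        self.label_head = _make_head(cfg.hidden_width, cfg.dropout, np.random.default_rng(s_lab))
        self.domain_head = (
            _make_head(cfg.hidden_width, cfg.dropout, np.random.default_rng(s_dom))
            if cfg.domain_adversarial
            else None
        )
        self.grl = GradientReversal(cfg.lambda_grl)
        self.rng_shuffle = np.random.default_rng(s_shuffle)
        self.rng_drop_lab = np.random.default_rng(s_drop_lab)
        self.rng_drop_dom = np.random.default_rng(s_drop_dom)
        self.rng_target = np.random.default_rng(s_target)
        self.cfg = cfg

    def label_probs(self, x: np.ndarray, *, train: bool = False, rng=None) -> np.ndarray:
        f = self.extractor.forward(x, train=train, rng=rng, update_stats=train)
        return self.label_head.forward(f, train=train, rng=rng, update_stats=train)

    def domain_probs(self, x: np.ndarray) -> np.ndarray:
        f = self.extractor.forward(x, train=False)
        return self.domain_head.forward(self.grl.forward(f), train=False)

    def params(self):
        p = self.extractor.params() + self.label_head.params()
        if self.domain_head is not None:
            p += self.domain_head.params()
        return p


def _one_hot(y: np.ndarray) -> np.ndarray:
    out = np.zeros((len(y), 2))
    out[np.arange(len(y)), y] = 1.0
    return out


def _accuracy(probs: np.ndarray, y: np.ndarray) -> float:
    return float((probs.argmax(axis=1) == y).mean())


def train_dann(
    x: np.ndarray,
    y: np.ndarray,
    config: DannConfig,
    *,
    x_target: Optional[np.ndarray] = None,
    eval_x: Optional[np.ndarray] = None,
    eval_y: Optional[np.ndarray] = None,
) -> TrainedModel:
    """Train the domain-adversarial classifier on standardized features.

    ``x``/``y`` are the labeled source-site subjects (y ∈ {0 control,
    1 patient}); ``x_target`` are unlabeled held-out-site subjects shown only
    to the domain classifier.  ``eval_x``/``eval_y`` are scored (never
    trained on) once per epoch so the log supports both reporting senses:
    *test* — held-out accuracy at the epoch of highest training accuracy —
    and *best_test* — the maximum held-out accuracy over all epochs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if x.ndim != 2 or x.shape[1] != config.input_dim:
        raise ValueError("feature width does not match config.input_dim")
    if x.shape[1] == 0:
        raise ValueError(
            "zero input features: the edge selection is empty — relax the p-value threshold"
        )
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")

    cw = class_weights(y)
    net = _DannNet(config)
    use_domain = (
        config.domain_adversarial
        and config.expose_target
        and x_target is not None
        and len(x_target) >= 2
    )
    dw = None
    if use_domain:
        x_target = np.asarray(x_target, dtype=float)
        domain_labels = np.concatenate([np.zeros(len(x), int), np.ones(len(x_target), int)])
        dw = class_weights(domain_labels)

    opt = Adam(net.params(), lr=config.learning_rate)
    y_hot = _one_hot(y)
    log_rows = []
    n = len(x)
    for epoch in range(config.epochs):
        lam = (
            config.lambda_grl * (epoch + 1) / config.epochs
            if config.lambda_ramp
            else config.lambda_grl
        )
        net.grl.lambda_grl = lam
        order = net.rng_shuffle.permutation(n)
        ep_label_loss = 0.0
        ep_domain_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if len(idx) < 2:
                continue  # batch statistics undefined for a single subject
            xb, yb = x[idx], y_hot[idx]
            opt.zero_grad()

            # labeled source pass: extractor + label predictor
            feats = net.extractor.forward(
                xb, train=True, rng=net.rng_drop_lab, update_stats=True
            )
            probs = net.label_head.forward(
                feats, train=True, rng=net.rng_drop_lab, update_stats=True
            )
            ep_label_loss += weighted_bce(probs, yb, cw)
            grad = net.label_head.backward(_bce_grad(probs, yb, cw.weights))
            net.extractor.backward(grad)

            # adversarial pass: source batch + sampled target batch through GRL
            if use_domain:
                t_idx = net.rng_target.integers(0, len(x_target), size=len(idx))
                xd = np.vstack([xb, x_target[t_idx]])
                yd = _one_hot(
                    np.concatenate([np.zeros(len(idx), int), np.ones(len(t_idx), int)])
                )
                fd = net.extractor.forward(
                    xd, train=True, rng=net.rng_drop_dom, update_stats=False
                )
                pd_ = net.domain_head.forward(
                    net.grl.forward(fd),
                    train=True,
                    rng=net.rng_drop_dom,
                    update_stats=True,
                )
                ep_domain_loss += weighted_bce(pd_, yd, dw)
                gd = net.domain_head.backward(_bce_grad(pd_, yd, dw.weights))
                net.extractor.backward(net.grl.backward(gd))

            opt.step()
            n_batches += 1

        train_acc = _accuracy(net.label_probs(x), y)
        row = {
            "epoch": epoch,
            "train_acc": train_acc,
            "label_loss": ep_label_loss / max(n_batches, 1),
            "domain_loss": ep_domain_loss / max(n_batches, 1),
        }
        if eval_x is not None and eval_y is not None:
            row["test_acc"] = _accuracy(net.label_probs(eval_x), np.asarray(eval_y, int))
        if use_domain:
            all_x = np.vstack([x, x_target])
            row["domain_acc"] = _accuracy(
                net.domain_probs(all_x),
                np.concatenate([np.zeros(len(x), int), np.ones(len(x_target), int)]),
            )
        log_rows.append(row)

    return TrainedModel(
        kind="dann",
        model=net,
        training_log=pd.DataFrame(log_rows),
        config=config,
        class_weights=cw,
    )


def train_svm(x: np.ndarray, y: np.ndarray, c: float = 1.0) -> TrainedModel:
    """Linear soft-margin SVM (C = 1 by default); deterministic fit."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if x.shape[1] == 0:
        raise ValueError(
            "zero input features: the edge selection is empty — relax the p-value threshold"
        )
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    svm = SVC(kernel="linear", C=c)
    svm.fit(x, y)
    return TrainedModel(kind="svm", model=svm)


def predict(model: TrainedModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels (0/1) and scores for new subjects.

    If the model carries a standardizer, ``x`` is z-scored with the stored
    training-fold statistics first.  DANN scores are the patient unit's
    sigmoid activation (in (0, 1)); SVM scores are the signed margin.
    """
    x = np.asarray(x, dtype=float)
    if model.standardizer is not None:
        x = model.standardizer.transform(x)
    if model.kind == "svm":
        svm = model.model
        if x.shape[1] != svm.n_features_in_:
            raise ValueError("feature width does not match the fitted SVM")
        return svm.predict(x), svm.decision_function(x)
    net: _DannNet = model.model
    if x.shape[1] != net.cfg.input_dim:
        raise ValueError("feature width does not match the fitted network")
    probs = net.label_probs(x)
    return probs.argmax(axis=1), probs[:, 1]
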