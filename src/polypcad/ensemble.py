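"""Deep ensembles: train many member CNNs on resampled train-validation
splits and predict with the arithmetic mean of their output scores.

Each member sees a different randomly drawn 80-20 split of the training
cohort. Training uses stochastic gradient descent on binary cross-entropy
(defaults: learning rate 0.01, batch size 8) with early stopping monitored
on the validation AUC: if the validation AUC does not strictly exceed its
running maximum for ``patience_epochs`` consecutive epochs, training stops
and the weights of the best-validation-AUC epoch are restored. Ensembling
counteracts the run-to-run variance of individual small-cohort CNNs.

The module offers both a functional surface (``train_member``,
``train_ensemble``, ``predict``) and a scikit-learn style estimator
(:class:`EnsembleClassifier`) with ``fit`` / ``predict_proba`` /
``get_params`` that composes with sklearn model selection.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .data_io import ModelInput, TrainValSplit, make_split, augment, centre_crop
from .evaluate import roc_auc
from .network import MemberNetwork, NetworkConfig, build_member

__all__ = ["TrainingParams", "EnsembleModel", "train_member", "train_ensemble",
           "predict", "EnsembleClassifier"]


@dataclass
class TrainingParams:
    """SGD training hyperparameters (defaults are the standard profile)."""

    learning_rate: float = 0.01
    batch_size: int = 8
    patience_epochs: int = 64
    max_epochs: int = 1000
    momentum: float = 0.0

    def __post_init__(self):
        if self.batch_size < 1 or self.max_epochs < 1 or self.patience_epochs < 1:
            raise ValueError("batch_size, max_epochs and patience_epochs must be >= 1")
        if self.momentum != 0.0:
            raise NotImplementedError("plain SGD only; momentum is reserved")


@dataclass
class EnsembleModel:
    """An ordered collection of member networks sharing one configuration."""

    members: list[MemberNetwork]
    model_variant: str
    member_seeds: list[int] = field(default_factory=list)

    def __post_init__(self):
        if len(self.members) < 1:
            raise ValueError("ensemble needs at least one member")
        cfg0 = self.members[0].config
        if any(m.config != cfg0 for m in self.members):
            raise ValueError("all members must share one NetworkConfig")
        if self.model_variant not in ("SEG", "noSEG"):
            raise ValueError("model_variant must be 'SEG' or 'noSEG'")

    def predict_scores(self, X: np.ndarray, batch_size: int = 8) -> np.ndarray:
        return predict(self, X, batch_size=batch_size)

    def member_scores(self, X: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """(n_members, n_samples) matrix of per-member scores."""
        X = _as_model_batch(X)
        return np.stack([m.predict_scores(X, batch_size) for m in self.members])

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, m in enumerate(self.members):
            m.save(out_dir / f"member_{i:03d}.npz")
        meta = {"model_variant": self.model_variant,
                "member_seeds": [int(s) for s in self.member_seeds],
                "n_members": len(self.members)}
        (out_dir / "ensemble.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, out_dir: str | Path) -> "EnsembleModel":
        out_dir = Path(out_dir)
        meta = json.loads((out_dir / "ensemble.json").read_text())
        members = [MemberNetwork.load(out_dir / f"member_{i:03d}.npz")
                   for i in range(meta["n_members"])]
        return cls(members=members, model_variant=meta["model_variant"],
                   member_seeds=meta["member_seeds"])


def _as_model_batch(X) -> np.ndarray:
    X = np.asarray(X, np.float32)
    if X.ndim == 4:
        X = X[None]
    if X.ndim != 5:
        raise ValueError(f"expected (n, d, h, w, c) inputs, got shape {X.shape}")
    if X.shape[1] != 50:
        X = np.stack([centre_crop(x) for x in X])
    return X


def _random_crop(x: np.ndarray, rng: np.random.Generator, size: int = 50) -> np.ndarray:
    o = [int(rng.integers(0, n - size + 1)) for n in x.shape[:3]]
    return x[o[0]:o[0] + size, o[1]:o[1] + size, o[2]:o[2] + size, :]


def _prep_train_sample(x: np.ndarray, augment_mode: str,
                       rng: np.random.Generator) -> np.ndarray:
    """Training-time view of one context sample.

    ``augment_mode``: "crop" — random 50^3 crop only (the study protocol's
    stated augmentation); "full" — crop + axis flips + right-angle rotation;
    "none" — deterministic centre crop.
    """
    if augment_mode == "full":
        return augment(ModelInput(data=x), rng).data
    if augment_mode == "crop" and x.shape[0] > 50:
        return _random_crop(x, rng)
    if x.shape[0] != 50:
        return centre_crop(x)
    return x


def train_member(net: MemberNetwork, X: np.ndarray, y: np.ndarray,
                 split: TrainValSplit, params: TrainingParams, seed: int,
                 augment_train: bool | str = True) -> MemberNetwork:
    """Train one member on its split with early stopping on validation AUC.

    ``X`` is (n, s, s, s, c) with s >= 50; training samples are re-drawn
    each epoch under the augmentation policy (``augment_train``: True or
    "crop" for random cropping, "full" for cropping + flips + right-angle
    rotations, False/"none" to disable), while validation samples are only
    centre-cropped, never augmented.
    """
    mode = {True: "crop", False: "none"}.get(augment_train, augment_train)
    if mode not in ("crop", "full", "none"):
        raise ValueError(f"unknown augmentation mode {augment_train!r}")
    y = np.asarray(y).astype(int)
    tr = np.asarray(split.train_ids, int)
    va = np.asarray(split.val_ids, int)
    if len(np.unique(y[va])) < 2:
        raise ValueError("validation set contains a single class: AUC undefined")
    if len(np.unique(y[tr])) < 2:
        raise ValueError("training set contains a single class")
    ss = np.random.SeedSequence(seed)
    shuffle_rng, aug_rng, drop_rng = (np.random.default_rng(c) for c in ss.spawn(3))

    Xval = np.stack([x if x.shape[0] == 50 else centre_crop(x) for x in X[va]])
    yval = y[va]
    net.history = {"loss": [], "val_auc": []}
    best_auc = -np.inf
    best_weights = net.get_weights()
    epochs_since_best = 0
    for _epoch in range(params.max_epochs):
        order = shuffle_rng.permutation(tr)
        losses = []
        diverged = False
        for i0 in range(0, len(order), params.batch_size):
            chunk = order[i0:i0 + params.batch_size]
            xb = np.stack([_prep_train_sample(X[i], mode, aug_rng)
                           for i in chunk])
            try:
                losses.append(net.train_step(xb, y[chunk],
                                             params.learning_rate, drop_rng))
            except FloatingPointError:
                # numeric divergence: keep the best weights seen so far
                import warnings
                warnings.warn("training diverged (non-finite activations); "
                              "stopping and restoring the best epoch",
                              stacklevel=2)
                diverged = True
                break
        if diverged:
            break
        val_auc = roc_auc(net.predict_scores(Xval, params.batch_size), yval)
        net.history["loss"].append(float(np.mean(losses)))
        net.history["val_auc"].append(float(val_auc))
        if val_auc > best_auc:
            best_auc = val_auc
            best_weights = net.get_weights()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
        if epochs_since_best >= params.patience_epochs:
            break
    net.set_weights(best_weights)
    net.release_buffers()
    net.trained = True
    return net


def train_ensemble(X: np.ndarray, y: np.ndarray, variant: str = "noSEG",
                   n_members: int = 50, base_seed: int = 0,
                   params: TrainingParams | None = None,
                   split_fraction: float = 0.8, augment_train: bool | str = True,
                   dropout_rate: float = 0.5, groups=None) -> EnsembleModel:
    """Train ``n_members`` networks on distinct splits; members are mutually
    independent given their seeds, so training order cannot matter.

    Member ``i`` draws its 80-20 split with seed ``base_seed + i`` and its
    weight initialization / shuffling / dropout streams from an independent
    seed sequence derived from the same pair.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    if variant not in ("SEG", "noSEG"):
        raise ValueError("variant must be 'SEG' or 'noSEG'")
    params = params or TrainingParams()
    X = np.asarray(X, np.float32)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("dataset must contain both classes")
    expected_c = 2 if variant == "SEG" else 1
    if X.shape[-1] != expected_c:
        raise ValueError(f"variant {variant} expects {expected_c}-channel inputs, "
                         f"got {X.shape[-1]}")
    cfg = NetworkConfig(in_channels=expected_c, dropout_rate=dropout_rate)
    members, seeds = [], []
    for i in range(n_members):
        split_seed = base_seed + i
        member_ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(1000 + i,))
        init_seed, run_seed = (int(c.generate_state(1)[0] % (2 ** 31))
                               for c in member_ss.spawn(2))
        split = make_split(range(len(y)), fraction=split_fraction, seed=split_seed,
                           groups=groups)
        net = build_member(cfg, seed=init_seed)
        train_member(net, X, y, split, params, seed=run_seed,
                     augment_train=augment_train)
        members.append(net)
        seeds.append(split_seed)
    return EnsembleModel(members=members, model_variant=variant, member_seeds=seeds)


def predict(ensemble: EnsembleModel, X: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Ensemble score(s): unweighted arithmetic mean of the member scores."""
    if len(ensemble.members) < 1:
        raise ValueError("ensemble has no members")
    X = _as_model_batch(X)
    acc = np.zeros(X.shape[0], np.float64)
    for m in ensemble.members:
        acc += m.predict_scores(X, batch_size)
        m.release_buffers()
    return acc / len(ensemble.members)


class EnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn style deep-ensemble polyp classifier.

    Parameters mirror the training protocol: ``variant`` selects image-only
    ("noSEG", 1 input channel) or image+mask ("SEG", 2 channels) inputs;
    ``n_members`` networks are trained on distinct random 80-20 splits and
    prediction averages their output scores.

    Attributes (after ``fit``): ``classes_``, ``model_``, ``members_``,
    ``member_seeds_``, ``histories_``, ``n_features_in_``.
    """

    def __init__(self, variant: str = "noSEG", n_members: int = 50,
                 learning_rate: float = 0.01, batch_size: int = 8,
                 patience_epochs: int = 64, max_epochs: int = 1000,
                 split_fraction: float = 0.8, augment: bool = True,
                 dropout_rate: float = 0.5, random_state: int = 0):
        self.variant = variant
        self.n_members = n_members
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.patience_epochs = patience_epochs
        self.max_epochs = max_epochs
        self.split_fraction = split_fraction
        self.augment = augment
        self.dropout_rate = dropout_rate
        self.random_state = random_state

    def fit(self, X, y, groups=None):
        X = np.asarray(X, np.float32)
        y = np.asarray(y)
        if X.ndim != 5:
            raise ValueError("X must be (n_samples, d, h, w, channels)")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary classification requires exactly two classes")
        y01 = (y == self.classes_[1]).astype(int)
        params = TrainingParams(learning_rate=self.learning_rate,
                                batch_size=self.batch_size,
                                patience_epochs=self.patience_epochs,
                                max_epochs=self.max_epochs)
        self.model_ = train_ensemble(
            X, y01, variant=self.variant, n_members=self.n_members,
            base_seed=self.random_state, params=params,
            split_fraction=self.split_fraction, augment_train=self.augment,
            dropout_rate=self.dropout_rate, groups=groups)
        self.members_ = self.model_.members
        self.member_seeds_ = self.model_.member_seeds
        self.histories_ = [m.history for m in self.members_]
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def decision_scores(self, X) -> np.ndarray:
        """Ensemble output scores in [0, 1] (mean of member scores)."""
        self._check_fitted()
        return predict(self.model_, X, batch_size=self.batch_size)

    def predict_proba(self, X) -> np.ndarray:
        p = self.decision_scores(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        p = self.decision_scores(X)
        return self.classes_[(p >= 0.5).astype(int)]

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("EnsembleClassifier is not fitted yet")
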