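"""Three-layer feed-forward classifier trained by backpropagation.

The network is the shallow architecture of the era the method comes from:
one sigmoid hidden layer, a single sigmoid output unit read as the
probability of disease, mean-squared-error loss, and full-batch gradient
descent with a momentum term.  Weights start uniform in [-0.5, 0.5].  The
number of training epochs is selected by an internal early-stopping slice:
a stratified fraction of the training pool is held aside, and the weights
from the epoch with the smallest slice MSE are kept.

Also here: the hidden-size sweep under stratified k-fold cross-validation
(the model-selection loop used to pick the architecture) and the stratified
train/validation holdout split.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "MLPBackpropClassifier",
    "SweepResult",
    "sweep_hidden",
    "holdout_split",
    "save_model",
    "load_model",
]

Params = tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]  # W1, b1, W2, b2


def _forward(params: Params, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    W1, b1, W2, b2 = params
    H = expit(X @ W1 + b1)
    out = expit(H @ W2 + b2)
    return H, out.ravel()


def _loss(params: Params, X: np.ndarray, y: np.ndarray) -> float:
    _, out = _forward(params, X)
    return float(np.mean((out - y) ** 2))


def _loss_and_gradients(params: Params, X: np.ndarray, y: np.ndarray) -> tuple[float, Params]:
    """MSE and its analytic gradients (the backpropagation pass)."""
    W1, b1, W2, b2 = params
    H, out = _forward(params, X)
    n = X.shape[0]
    err = out - y
    loss = float(np.mean(err**2))
    delta_out = (2.0 / n) * err * out * (1.0 - out)  # (n,)
    gW2 = H.T @ delta_out[:, None]
    gb2 = np.array([delta_out.sum()])
    delta_hid = (delta_out[:, None] * W2.T) * H * (1.0 - H)  # (n, h)
    gW1 = X.T @ delta_hid
    gb1 = delta_hid.sum(axis=0)
    return loss, (gW1, gb1, gW2, gb2)


class MLPBackpropClassifier(ClassifierMixin, BaseEstimator):
    """Single-hidden-layer sigmoid network, backprop with momentum on MSE.

    Parameters
    ----------
    hidden_neurons : int
        Hidden-layer width.
    learning_rate : float
        Gradient step size (0.5, the study's setting).
    momentum : float
        Momentum coefficient in [0, 1) (0.9, the study's setting).
    max_epochs : int
        Number of full passes over the training portion.
    batch_size : int or None
        None trains full-batch; otherwise shuffled minibatches.
    early_stopping_fraction : float
        Stratified fraction of the training pool held aside to pick the
        epoch (weights with minimal slice MSE are restored); 0 disables
        epoch selection and keeps the final weights.
    decision_threshold : float
        Probability cut for ``predict``.
    random_state : int or None
        Seed for weight initialisation, shuffling and the internal slice.

    Attributes
    ----------
    W1_, b1_, W2_, b2_ : ndarray
        Fitted weights and biases.
    mse_trace_ : ndarray
        Training MSE after each epoch.
    val_mse_trace_ : ndarray
        Early-stopping-slice MSE after each epoch (empty if disabled).
    best_epoch_ : int
        1-based epoch whose weights were kept.
    """

    def __init__(
        self,
        hidden_neurons: int = 8,
        learning_rate: float = 0.5,
        momentum: float = 0.9,
        max_epochs: int = 200,
        batch_size: int | None = None,
        early_stopping_fraction: float = 0.1,
        decision_threshold: float = 0.5,
        random_state: int | None = None,
    ):
        self.hidden_neurons = hidden_neurons
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.early_stopping_fraction = early_stopping_fraction
        self.decision_threshold = decision_threshold
        self.random_state = random_state

    def _validate_hyperparameters(self) -> None:
        if not isinstance(self.hidden_neurons, (int, np.integer)) or self.hidden_neurons < 1:
            raise ValueError(f"hidden_neurons must be a positive integer, got {self.hidden_neurons!r}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be positive, got {self.learning_rate!r}")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError(f"momentum must lie in [0, 1), got {self.momentum!r}")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError(f"decision_threshold must lie in (0, 1), got {self.decision_threshold!r}")
        if not 0.0 <= self.early_stopping_fraction < 1.0:
            raise ValueError(
                f"early_stopping_fraction must lie in [0, 1), got {self.early_stopping_fraction!r}"
            )

    def fit(self, X, y) -> "MLPBackpropClassifier":
        self._validate_hyperparameters()
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"need exactly two classes in y, got {len(self.classes_)}: {self.classes_}"
            )
        y01 = (y == self.classes_[1]).astype(float)
        rng = np.random.default_rng(self.random_state)

        if self.early_stopping_fraction > 0 and len(y) >= 10:
            idx_train, idx_stop = train_test_split(
                np.arange(len(y)),
                test_size=self.early_stopping_fraction,
                stratify=y01,
                random_state=int(rng.integers(2**31 - 1)),
            )
            X_tr, y_tr = X[idx_train], y01[idx_train]
            X_stop, y_stop = X[idx_stop], y01[idx_stop]
        else:
            X_tr, y_tr = X, y01
            X_stop = None

        n_in, h = X.shape[1], self.hidden_neurons
        params: list[np.ndarray] = [
            rng.uniform(-0.5, 0.5, size=(n_in, h)),
            rng.uniform(-0.5, 0.5, size=h),
            rng.uniform(-0.5, 0.5, size=(h, 1)),
            rng.uniform(-0.5, 0.5, size=1),
        ]
        velocity = [np.zeros_like(p) for p in params]

        mse_trace: list[float] = []
        stop_trace: list[float] = []
        best_mse = np.inf
        best_params = [p.copy() for p in params]
        best_epoch = 0
        n_tr = X_tr.shape[0]
        batch = self.batch_size or n_tr

        for epoch in range(1, self.max_epochs + 1):
            if batch >= n_tr:
                slices = [(X_tr, y_tr)]
            else:
                order = rng.permutation(n_tr)
                slices = [
                    (X_tr[order[s : s + batch]], y_tr[order[s : s + batch]])
                    for s in range(0, n_tr, batch)
                ]
            for Xb, yb in slices:
                _, grads = _loss_and_gradients(tuple(params), Xb, yb)
                for p, v, g in zip(params, velocity, grads):
                    v *= self.momentum
                    v -= self.learning_rate * g
                    p += v
            mse_trace.append(_loss(tuple(params), X_tr, y_tr))
            if X_stop is not None:
                stop_mse = _loss(tuple(params), X_stop, y_stop)
                stop_trace.append(stop_mse)
                if stop_mse < best_mse:
                    best_mse = stop_mse
                    best_params = [p.copy() for p in params]
                    best_epoch = epoch

        if X_stop is not None and best_epoch > 0:
            params = best_params
            self.best_epoch_ = best_epoch
        else:
            self.best_epoch_ = self.max_epochs

        self.W1_, self.b1_, self.W2_, self.b2_ = (p.copy() for p in params)
        self.mse_trace_ = np.asarray(mse_trace)
        self.val_mse_trace_ = np.asarray(stop_trace)
        self.n_features_in_ = n_in
        return self

    def _params(self) -> Params:
        return self.W1_, self.b1_, self.W2_, self.b2_

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "W1_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was fitted with {self.n_features_in_}"
            )
        _, out = _forward(self._params(), X)
        return np.column_stack([1.0 - out, out])

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        pos = self.predict_proba(X)[:, 1] >= self.decision_threshold
        return self.classes_[pos.astype(int)]


@dataclass
class SweepResult:
    """Outcome of the hidden-width model-selection sweep."""

    table: pd.DataFrame  # columns: hidden_size, mean_auc, sd_auc
    best_hidden: int
    folds: list[tuple[np.ndarray, np.ndarray]]
    seed: int

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def sweep_hidden(
    X,
    y,
    sizes: list[int] | None = None,
    k: int = 10,
    seed: int = 0,
    **ann_params,
) -> SweepResult:
    """Mean cross-validated AUC for each candidate hidden-layer width.

    The same stratified k-fold assignment is reused for every width; the
    best width attains the maximal mean AUC, ties going to the smallest
    network.  Extra keyword arguments are passed to the classifier.
    """
    from .evaluate import roc_auc

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if sizes is None:
        sizes = list(range(1, 78))
    if k > len(y):
        raise ValueError(f"k={k} exceeds the number of samples ({len(y)})")
    if k < 2:
        raise ValueError(f"k must be at least 2, got {k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [(tr, te) for tr, te in skf.split(X, y)]

    rows = []
    for size in sizes:
        aucs = []
        for f, (tr, te) in enumerate(folds):
            clf = MLPBackpropClassifier(
                hidden_neurons=size, random_state=seed + 104_729 * f, **ann_params
            )
            clf.fit(X[tr], y[tr])
            scores = clf.predict_proba(X[te])[:, 1]
            _, auc = roc_auc(scores, y[te])
            aucs.append(auc)
        rows.append(
            {"hidden_size": size, "mean_auc": float(np.mean(aucs)), "sd_auc": float(np.std(aucs, ddof=1))}
        )
    table = pd.DataFrame(rows)
    best_idx = int(table["mean_auc"].idxmax())  # idxmax takes the first (smallest size) on ties
    return SweepResult(
        table=table, best_hidden=int(table.loc[best_idx, "hidden_size"]), folds=folds, seed=seed
    )


def holdout_split(
    X, y, train_fraction: float = 0.85, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/validation index split (85/15 by default).

    The validation side is never touched by the sweep or by training.  If
    stratification is impossible (a class with a single member), the split
    is re-drawn without it until both classes appear on both sides.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction!r}")
    y = np.asarray(y)
    idx = np.arange(len(y))
    try:
        tr, va = train_test_split(idx, train_size=train_fraction, stratify=y, random_state=seed)
        return np.sort(tr), np.sort(va)
    except ValueError:
        pass
    import warnings

    for attempt in range(100):
        tr, va = train_test_split(idx, train_size=train_fraction, random_state=seed + attempt)
        if len(np.unique(y[tr])) == 2 and len(np.unique(y[va])) == 2:
            warnings.warn("stratified split impossible; re-drew an unstratified split")
            return np.sort(tr), np.sort(va)
    raise ValueError("could not produce a split with both classes on both sides")


def save_model(model: MLPBackpropClassifier, path: str | Path) -> None:
    """Portable text serialization: config, shapes, then decimal weights."""
    check_is_fitted(model, "W1_")
    lines = ["neuralhypernet-ann v1"]
    for key, value in sorted(model.get_params().items()):
        lines.append(f"param {key} {value!r}")
    lines.append(f"classes {model.classes_[0].item()!r} {model.classes_[1].item()!r}")
    lines.append(f"best_epoch {model.best_epoch_}")
    for name in ("W1_", "b1_", "W2_", "b2_"):
        arr = np.atleast_2d(getattr(model, name))
        lines.append(f"array {name} {arr.shape[0]} {arr.shape[1]}")
        for row in arr:
            lines.append(" ".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path: str | Path) -> MLPBackpropClassifier:
    import ast

    lines = Path(path).read_text().splitlines()
    if lines[0] != "neuralhypernet-ann v1":
        raise ValueError(f"unrecognized model file header: {lines[0]!r}")
    params: dict = {}
    arrays: dict[str, np.ndarray] = {}
    classes: list = []
    best_epoch = 0
    i = 1
    while i < len(lines):
        parts = lines[i].split(maxsplit=1)
        if parts[0] == "param":
            key, value = parts[1].split(maxsplit=1)
            params[key] = ast.literal_eval(value)
        elif parts[0] == "classes":
            classes = [ast.literal_eval(tok) for tok in parts[1].split()]
        elif parts[0] == "best_epoch":
            best_epoch = int(parts[1])
        elif parts[0] == "array":
            name, r, c = parts[1].split()
            r, c = int(r), int(c)
            block = [[float(tok) for tok in lines[i + 1 + j].split()] for j in range(r)]
            arrays[name] = np.asarray(block)
            i += r
        i += 1
    model = MLPBackpropClassifier(**params)
    model.W1_ = arrays["W1_"]
    model.b1_ = arrays["b1_"].ravel()
    model.W2_ = arrays["W2_"].reshape(-1, 1)
    model.b2_ = arrays["b2_"].ravel()
    model.classes_ = np.asarray(classes)
    model.best_epoch_ = best_epoch
    model.mse_trace_ = np.asarray([])
    model.val_mse_trace_ = np.asarray([])
    model.n_features_in_ = model.W1_.shape[0]
    return model
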