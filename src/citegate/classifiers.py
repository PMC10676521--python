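"""The five marker classifiers behind a single fit/predict surface.

* ``lr`` — L2-regularised logistic regression (C_LR), probability cut 0.5;
* ``svm_linear`` / ``svm_rbf`` — soft-margin SVMs (C_SVM, and gamma for the
  RBF kernel), hard decision at the sign of the decision function;
* ``stack`` — meta logistic regression on the hard 0/1 predictions of an LR
  and an RBF SVM base pair trained on the same data; the meta model's own
  regularisation is left at its default (it only sees two binary features);
* ``mlp`` — a small dense ReLU network with a sigmoid output, inverted
  dropout, Adam, binary cross-entropy, 15 epochs, batch 32.

Features are standardised inside the classifier so SVM/LR cost ranges mean
the same thing regardless of feature scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

MODEL_KINDS = ("lr", "svm_linear", "svm_rbf", "stack", "mlp")

#: hyperparameter search boxes, shared with the Bayesian optimizer
SEARCH_BOUNDS = {
    "t_de_upper": (1.0, 4.0),
    "t_de_lower": (-4.0, -1.0),
    "p_hn": (1e-6, 0.1),
    "c_svm": (1e-6, 100.0),
    "gamma": (1e-6, 2.0),
    "c_lr": (1e-6, 2.0),
    "n_layers": (1, 3),
    "n_nodes": (16, 128),
    "eta": (1e-4, 0.01),
    "rho": (0.1, 0.5),
}

#: which hyperparameters each model kind optimises (besides the two
#: feature-selection thresholds, which every kind shares)
MODEL_HP_NAMES = {
    "lr": ["c_lr"],
    "svm_linear": ["c_svm"],
    "svm_rbf": ["c_svm", "gamma"],
    "stack": ["c_svm", "gamma", "c_lr"],
    "mlp": ["n_layers", "n_nodes", "eta", "rho"],
}
INTEGER_HPS = {"n_layers", "n_nodes"}
FEATURE_HP_NAMES = ["t_de_upper", "t_de_lower", "p_hn"]


@dataclass
class HyperParams:
    """A point in the joint feature-selection + model search box."""

    model_kind: str
    t_de_upper: float = 2.0
    t_de_lower: float = -2.0
    p_hn: float = 0.05
    c_svm: float = 1.0
    gamma: float = 0.1
    c_lr: float = 1.0
    n_layers: int = 2
    n_nodes: int = 64
    eta: float = 1e-3
    rho: float = 0.2

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        self.n_layers = int(round(self.n_layers))
        self.n_nodes = int(round(self.n_nodes))

    def names(self) -> list[str]:
        return FEATURE_HP_NAMES + MODEL_HP_NAMES[self.model_kind]

    def to_dict(self) -> dict:
        d = {"model_kind": self.model_kind}
        for name in self.names():
            d[name] = getattr(self, name)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HyperParams":
        return cls(**d)


class NumpyMLP:
    """Dense ReLU binary classifier with dropout, trained by Adam.

    Architecture: ``n_layers`` hidden layers of ``n_nodes`` units (He-uniform
    init), inverted dropout with rate ``rho`` during training, sigmoid
    output, binary cross-entropy loss, Adam with learning rate ``eta``,
    15 epochs of shuffled minibatches of 32.
    """

    def __init__(self, n_layers=2, n_nodes=64, eta=1e-3, rho=0.2,
                 epochs=15, batch_size=32, seed=0):
        self.n_layers = int(n_layers)
        self.n_nodes = int(n_nodes)
        self.eta = float(eta)
        self.rho = float(rho)
        self.epochs = int(epochs)
        self.batch_size = int(batch_size)
        self.seed = int(seed)
        self.weights_: list[np.ndarray] | None = None
        self.biases_: list[np.ndarray] | None = None

    def _init_params(self, n_features: int, rng: np.random.Generator):
        sizes = [n_features] + [self.n_nodes] * self.n_layers + [1]
        W, b = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / fan_in)  # He-uniform for ReLU layers
            W.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            b.append(np.zeros(fan_out))
        return W, b

    @staticmethod
    def _sigmoid(z):
        return 0.5 * (1.0 + np.tanh(0.5 * z))

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NumpyMLP":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1, 1)
        rng = np.random.default_rng(self.seed)
        W, b = self._init_params(X.shape[1], rng)
        mW = [np.zeros_like(w) for w in W]
        vW = [np.zeros_like(w) for w in W]
        mb = [np.zeros_like(x) for x in b]
        vb = [np.zeros_like(x) for x in b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        n = X.shape[0]
        keep = 1.0 - self.rho
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = X[idx], y[idx]
                # forward with inverted dropout on hidden activations
                acts = [xb]
                masks = []
                h = xb
                for li in range(self.n_layers):
                    h = np.maximum(h @ W[li] + b[li], 0.0)
                    mask = (rng.random(h.shape) >= self.rho) / keep
                    h = h * mask
                    masks.append(mask)
                    acts.append(h)
                logits = h @ W[-1] + b[-1]
                prob = self._sigmoid(logits)
                # backward: d(BCE)/d(logits) = prob - y
                delta = (prob - yb) / len(idx)
                grads_W = [None] * len(W)
                grads_b = [None] * len(b)
                grads_W[-1] = acts[-1].T @ delta
                grads_b[-1] = delta.sum(axis=0)
                for li in range(self.n_layers - 1, -1, -1):
                    delta = delta @ W[li + 1].T
                    delta = delta * masks[li] * (acts[li + 1] > 0)
                    grads_W[li] = acts[li].T @ delta
                    grads_b[li] = delta.sum(axis=0)
                t += 1
                for li in range(len(W)):
                    mW[li] = beta1 * mW[li] + (1 - beta1) * grads_W[li]
                    vW[li] = beta2 * vW[li] + (1 - beta2) * grads_W[li] ** 2
                    mb[li] = beta1 * mb[li] + (1 - beta1) * grads_b[li]
                    vb[li] = beta2 * vb[li] + (1 - beta2) * grads_b[li] ** 2
                    mW_hat = mW[li] / (1 - beta1**t)
                    vW_hat = vW[li] / (1 - beta2**t)
                    mb_hat = mb[li] / (1 - beta1**t)
                    vb_hat = vb[li] / (1 - beta2**t)
                    W[li] -= self.eta * mW_hat / (np.sqrt(vW_hat) + eps)
                    b[li] -= self.eta * mb_hat / (np.sqrt(vb_hat) + eps)
        self.weights_, self.biases_ = W, b
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.weights_ is None:
            raise RuntimeError("model not fitted")
        h = np.asarray(X, dtype=float)
        for li in range(self.n_layers):
            h = np.maximum(h @ self.weights_[li] + self.biases_[li], 0.0)
        return self._sigmoid(h @ self.weights_[-1] + self.biases_[-1]).ravel()

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


@dataclass
class MarkerClassifier:
    """A fitted classifier of one of the five kinds, with its scaler."""

    model_kind: str
    hp: HyperParams
    seed: int = 0
    scaler_: StandardScaler | None = None
    estimator_: object = None
    base_lr_: object = None
    base_svm_: object = None
    classes_: np.ndarray = field(default_factory=lambda: np.array([0, 1]))

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MarkerClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if np.unique(y).size < 2:
            raise ValueError("training labels contain a single class")
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        hp = self.hp
        if self.model_kind == "lr":
            self.estimator_ = LogisticRegression(
                C=hp.c_lr, penalty="l2", solver="lbfgs", max_iter=2000
            ).fit(Xs, y)
        elif self.model_kind == "svm_linear":
            self.estimator_ = SVC(kernel="linear", C=hp.c_svm).fit(Xs, y)
        elif self.model_kind == "svm_rbf":
            self.estimator_ = SVC(kernel="rbf", C=hp.c_svm, gamma=hp.gamma).fit(Xs, y)
        elif self.model_kind == "stack":
            self.base_lr_ = LogisticRegression(
                C=hp.c_lr, penalty="l2", solver="lbfgs", max_iter=2000
            ).fit(Xs, y)
            self.base_svm_ = SVC(kernel="rbf", C=hp.c_svm, gamma=hp.gamma).fit(Xs, y)
            meta_X = self._meta_features(Xs)
            self.estimator_ = LogisticRegression(max_iter=2000).fit(meta_X, y)
        elif self.model_kind == "mlp":
            self.estimator_ = NumpyMLP(
                n_layers=hp.n_layers, n_nodes=hp.n_nodes, eta=hp.eta, rho=hp.rho,
                seed=self.seed,
            ).fit(Xs, y)
        else:
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        return self

    def _meta_features(self, Xs: np.ndarray) -> np.ndarray:
        # the stack consumes hard 0/1 base predictions
        return np.column_stack(
            [self.base_lr_.predict(Xs), self.base_svm_.predict(Xs)]
        ).astype(float)

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return self.scaler_.transform(np.asarray(X, dtype=float))

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = self._transform(X)
        if self.model_kind == "stack":
            return self.estimator_.predict(self._meta_features(Xs))
        return np.asarray(self.estimator_.predict(Xs)).astype(int)

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        """Probability for probabilistic models, decision value for SVMs."""
        Xs = self._transform(X)
        if self.model_kind == "lr":
            return self.estimator_.predict_proba(Xs)[:, 1]
        if self.model_kind in ("svm_linear", "svm_rbf"):
            return self.estimator_.decision_function(Xs)
        if self.model_kind == "stack":
            return self.estimator_.predict_proba(self._meta_features(Xs))[:, 1]
        return self.estimator_.predict_proba(Xs)

    @property
    def decision_threshold(self) -> float:
        return 0.0 if self.model_kind in ("svm_linear", "svm_rbf") else 0.5
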