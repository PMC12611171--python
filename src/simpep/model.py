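"""Siamese pair-similarity network and its iterative training strategy.

Architecture: two channels share one encoder ``f`` — a dense ReLU stack
(default 512, 128, 64, 32 units) mapping each peptide embedding to a latent
vector. The channels' latents are combined by elementwise absolute difference,
``lh = |f(v) - f(v')|``, passed through one 16-unit ReLU layer and a single
sigmoid unit that scores the probability the two peptides share a class.
Dropout (default 0.2) follows every hidden layer during training only, so
inference is deterministic and exactly symmetric under operand swap.

Training minimizes binary cross-entropy with Adam (default learning rate
1e-3) in rounds of a fixed number of epochs (default 5) over a balanced pair
dataset. If the per-epoch training accuracy has not stabilized at the end of
a round, a fresh balanced pair dataset is drawn and training resumes from the
current weights, up to a bounded number of rounds. The re-pairing injects
diversity (each round sees a different subsample of same-class and
cross-class pairs) without discarding learned weights.

The network is implemented directly in NumPy (forward, backprop, Adam); the
:class:`SiameseSimilarityClassifier` wraps it as a scikit-learn estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from simpep.pairing import PairingError, cons_train

BCE_EPS = 1e-7


class ModelError(Exception):
    """Training or inference failure (shape mismatch, divergence)."""


def bce_loss(y, y_hat) -> float:
    """Binary cross-entropy, mean over the batch.

    ``-[y log(ŷ) + (1-y) log(1-ŷ)]`` with predictions clamped to
    ``(eps, 1-eps)`` so endpoint predictions stay finite.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.clip(np.asarray(y_hat, dtype=float), BCE_EPS, 1.0 - BCE_EPS)
    return float(np.mean(-(y * np.log(y_hat) + (1.0 - y) * np.log(1.0 - y_hat))))


@dataclass
class NetConfig:
    """Hyperparameters of the similarity network and its training loop."""

    input_dim: int = 1024
    encoder_widths: tuple = (512, 128, 64, 32)
    head_width: int = 16
    dropout: float = 0.2
    learning_rate: float = 0.001
    epochs_per_round: int = 5
    max_rounds: int = 20
    stability_tol: float = 0.005
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        widths = tuple(self.encoder_widths)
        if any(w <= 0 for w in widths) or any(
            a < b for a, b in zip(widths, widths[1:])
        ):
            raise ModelError(f"encoder widths must be positive and descending: {widths}")
        if not 0.0 <= self.dropout < 1.0:
            raise ModelError(f"dropout must be in [0, 1): {self.dropout}")
        if self.learning_rate <= 0:
            raise ModelError(f"learning rate must be positive: {self.learning_rate}")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SimilarityNet:
    """The bare network: shared encoder, |difference| head, Adam state."""

    def __init__(
        self,
        input_dim: int,
        encoder_widths: Sequence[int] = (512, 128, 64, 32),
        head_width: int = 16,
        dropout: float = 0.2,
        rng: Optional[np.random.Generator] = None,
    ):
        rng = rng or np.random.default_rng()
        self.input_dim = int(input_dim)
        self.encoder_widths = tuple(int(w) for w in encoder_widths)
        self.head_width = int(head_width)
        self.dropout = float(dropout)

        def he(fan_in: int, fan_out: int) -> np.ndarray:
            return rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)

        dims = (self.input_dim,) + self.encoder_widths
        self.enc_W = [he(a, b) for a, b in zip(dims[:-1], dims[1:])]
        self.enc_b = [np.zeros(b) for b in dims[1:]]
        self.head_W = he(self.encoder_widths[-1], self.head_width)
        self.head_b = np.zeros(self.head_width)
        self.out_w = he(self.head_width, 1)
        self.out_b = np.zeros(1)

        self._adam_m = [np.zeros_like(p) for p in self._params()]
        self._adam_v = [np.zeros_like(p) for p in self._params()]
        self._adam_t = 0

    # -- parameter bookkeeping -------------------------------------------------

    def _params(self) -> list:
        return self.enc_W + self.enc_b + [self.head_W, self.head_b, self.out_w, self.out_b]

    def get_weights(self) -> list:
        return [p.copy() for p in self._params()]

    def set_weights(self, weights: list) -> None:
        for p, w in zip(self._params(), weights):
            p[...] = w

    # -- forward ---------------------------------------------------------------

    def encode(self, X: np.ndarray, rng: Optional[np.random.Generator] = None):
        """Encoder forward pass. With ``rng``, applies inverted dropout and
        returns the per-layer cache needed for backprop."""
        A = np.asarray(X, dtype=float)
        if A.ndim == 1:
            A = A[None, :]
        if A.shape[1] != self.input_dim:
            raise ModelError(f"expected {self.input_dim} features, got {A.shape[1]}")
        cache = {"A": [A], "Z": [], "mask": []}
        for W, b in zip(self.enc_W, self.enc_b):
            Z = A @ W + b
            A = np.maximum(Z, 0.0)
            mask = None
            if rng is not None and self.dropout > 0.0:
                mask = (rng.random(A.shape) >= self.dropout) / (1.0 - self.dropout)
                A = A * mask
            cache["Z"].append(Z)
            cache["mask"].append(mask)
            cache["A"].append(A)
        return A, cache

    def head(self, D: np.ndarray, rng: Optional[np.random.Generator] = None):
        """Score latent |difference| rows; returns probabilities and cache."""
        Zh = D @ self.head_W + self.head_b
        H = np.maximum(Zh, 0.0)
        mask = None
        if rng is not None and self.dropout > 0.0:
            mask = (rng.random(H.shape) >= self.dropout) / (1.0 - self.dropout)
            H = H * mask
        z_out = H @ self.out_w + self.out_b
        y_hat = _sigmoid(z_out)[:, 0]
        return y_hat, {"D": D, "Zh": Zh, "H": H, "mask": mask, "y_hat": y_hat}

    def forward(self, Xa: np.ndarray, Xb: np.ndarray, rng=None):
        """Pair similarity scores for row-aligned batches ``Xa``/``Xb``."""
        La, ca = self.encode(Xa, rng=rng)
        Lb, cb = self.encode(Xb, rng=rng)
        D = np.abs(La - Lb)
        y_hat, ch = self.head(D, rng=rng)
        return y_hat, {"a": ca, "b": cb, "La": La, "Lb": Lb, "head": ch}

    def pair_scores(self, Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
        """Deterministic (dropout-free) pair scores."""
        return self.forward(np.atleast_2d(Xa), np.atleast_2d(Xb))[0]

    def cross_scores(self, X_test: np.ndarray, X_train: np.ndarray) -> np.ndarray:
        """(m x n) score matrix between every test and training embedding."""
        Lt, _ = self.encode(X_test)
        Lr, _ = self.encode(X_train)
        out = np.empty((Lt.shape[0], Lr.shape[0]))
        for i in range(Lt.shape[0]):
            D = np.abs(Lt[i][None, :] - Lr)
            out[i], _ = self.head(D)
        return out

    # -- backward / optimizer --------------------------------------------------

    def _encoder_backward(self, dL: np.ndarray, cache: dict) -> list:
        grads = []
        grad = dL
        for layer in range(len(self.enc_W) - 1, -1, -1):
            mask = cache["mask"][layer]
            if mask is not None:
                grad = grad * mask
            grad = grad * (cache["Z"][layer] > 0.0)
            gW = cache["A"][layer].T @ grad
            gb = grad.sum(axis=0)
            grads.append((gW, gb))
            if layer > 0:
                grad = grad @ self.enc_W[layer].T
        grads.reverse()
        return grads

    def backward(self, cache: dict, y: np.ndarray) -> list:
        """Gradients of mean BCE w.r.t. every parameter, in _params() order."""
        ch = cache["head"]
        B = len(y)
        delta = (ch["y_hat"] - np.asarray(y, dtype=float))[:, None] / B
        g_out_w = ch["H"].T @ delta
        g_out_b = delta.sum(axis=0)
        dH = delta @ self.out_w.T
        if ch["mask"] is not None:
            dH = dH * ch["mask"]
        dZh = dH * (ch["Zh"] > 0.0)
        g_head_W = ch["D"].T @ dZh
        g_head_b = dZh.sum(axis=0)
        dD = dZh @ self.head_W.T

        sign = np.sign(cache["La"] - cache["Lb"])
        ga = self._encoder_backward(dD * sign, cache["a"])
        gb = self._encoder_backward(-dD * sign, cache["b"])
        # weight sharing: both channels contribute to the same encoder params
        enc_gW = [a[0] + b[0] for a, b in zip(ga, gb)]
        enc_gb = [a[1] + b[1] for a, b in zip(ga, gb)]
        return enc_gW + enc_gb + [g_head_W, g_head_b, g_out_w, g_out_b]

    def adam_step(self, grads: list, lr: float, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for p, g, m, v in zip(self._params(), grads, self._adam_m, self._adam_v):
            m[...] = beta1 * m + (1 - beta1) * g
            v[...] = beta2 * v + (1 - beta2) * g * g
            m_hat = m / (1 - beta1**t)
            v_hat = v / (1 - beta2**t)
            p -= lr * m_hat / (np.sqrt(v_hat) + eps)


class SiameseSimilarityClassifier(ClassifierMixin, BaseEstimator):
    """Few-shot classifier: siamese pair-similarity network + aggregation.

    ``fit(X, y)`` takes per-peptide embedding vectors with binary class
    labels, builds balanced pair datasets from the two classes, and trains
    the shared-encoder network on the pair-similarity task with the iterative
    re-pairing strategy. ``decision_function(X)`` scores each new embedding
    against every stored training embedding and aggregates:

    ``rho = ((1 - C_N / |N|) + C_O / |O|) / 2``

    where ``C_O`` (``C_N``) is the summed predicted similarity to the
    positive (negative) training pool, so ``rho`` is in [0, 1] and behaves as
    the predicted probability of the positive class. ``predict`` thresholds
    ``rho`` at ``decision_threshold`` (boundary inclusive).

    Parameters
    ----------
    encoder_widths : tuple of int, default (512, 128, 64, 32)
        Dense ReLU encoder layer sizes (shared by both channels).
    head_width : int, default 16
        Units in the ReLU layer applied to the latent |difference|.
    dropout : float, default 0.2
        Dropout rate after every hidden layer (training only).
    learning_rate : float, default 0.001
        Adam step size.
    epochs_per_round : int, default 5
        Epochs trained on each balanced pair dataset before the stability
        check.
    max_rounds : int, default 20
        Upper bound on re-pairing rounds.
    stability_tol : float, default 0.005
        Training counts as stable when the range of the last
        ``epochs_per_round`` per-epoch training accuracies falls below this.
    batch_size : int, default 32
    decision_threshold : float, default 0.5
    random_state : int or None
        Seeds parameter initialization, pairing, shuffling and dropout.

    Attributes
    ----------
    net_ : SimilarityNet
        The trained network.
    classes_ : ndarray of shape (2,)
        Sorted class labels; ``classes_[1]`` is the positive class.
    X_pos_, X_neg_ : ndarray
        Stored training embeddings per class (the aggregation reference set).
    history_ : pandas.DataFrame
        Per-epoch rows: round, epoch, loss, accuracy.
    n_rounds_ : int
        Re-pairing rounds actually run.
    """

    def __init__(
        self,
        encoder_widths=(512, 128, 64, 32),
        head_width=16,
        dropout=0.2,
        learning_rate=0.001,
        epochs_per_round=5,
        max_rounds=20,
        stability_tol=0.005,
        batch_size=32,
        decision_threshold=0.5,
        random_state=None,
    ):
        self.encoder_widths = encoder_widths
        self.head_width = head_width
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.epochs_per_round = epochs_per_round
        self.max_rounds = max_rounds
        self.stability_tol = stability_tol
        self.batch_size = batch_size
        self.decision_threshold = decision_threshold
        self.random_state = random_state

    # -- fitting ---------------------------------------------------------------

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ModelError(f"need exactly 2 classes, got {list(self.classes_)}")
        self.n_features_in_ = X.shape[1]
        pos_idx = np.flatnonzero(y == self.classes_[1])
        neg_idx = np.flatnonzero(y == self.classes_[0])
        if len(pos_idx) < 2 or len(neg_idx) < 2:
            raise PairingError("need at least 2 members per class to form pairs")
        self.X_pos_ = X[pos_idx]
        self.X_neg_ = X[neg_idx]

        root = np.random.default_rng(self.random_state)
        init_rng = np.random.default_rng(root.integers(2**31))
        self.net_ = SimilarityNet(
            input_dim=self.n_features_in_,
            encoder_widths=self.encoder_widths,
            head_width=self.head_width,
            dropout=self.dropout,
            rng=init_rng,
        )

        index = {("P", i): self.X_pos_[i] for i in range(len(pos_idx))}
        index.update({("N", i): self.X_neg_[i] for i in range(len(neg_idx))})
        pos_ids = [("P", i) for i in range(len(pos_idx))]
        neg_ids = [("N", i) for i in range(len(neg_idx))]

        history: list[dict] = []
        epoch_acc: list[float] = []
        rounds_run = 0
        for rnd in range(int(self.max_rounds)):
            rounds_run = rnd + 1
            pair_seed = int(root.integers(2**31))
            dataset = cons_train(pos_ids, neg_ids, seed=pair_seed)
            examples = dataset.examples
            Xa = np.stack([index[e.left] for e in examples])
            Xb = np.stack([index[e.right] for e in examples])
            yy = np.array([e.y for e in examples], dtype=float)

            epoch_rng = np.random.default_rng(root.integers(2**31))
            for epoch in range(int(self.epochs_per_round)):
                order = epoch_rng.permutation(len(yy))
                for start in range(0, len(yy), int(self.batch_size)):
                    sel = order[start:start + int(self.batch_size)]
                    y_hat, cache = self.net_.forward(Xa[sel], Xb[sel], rng=epoch_rng)
                    if not np.all(np.isfinite(y_hat)):
                        raise ModelError(
                            f"non-finite predictions in round {rnd + 1}, epoch {epoch + 1}"
                        )
                    grads = self.net_.backward(cache, yy[sel])
                    self.net_.adam_step(grads, lr=float(self.learning_rate))
                scores = self.net_.pair_scores(Xa, Xb)
                loss = bce_loss(yy, scores)
                acc = float(np.mean((scores >= 0.5) == (yy == 1.0)))
                epoch_acc.append(acc)
                history.append(
                    {"round": rnd + 1, "epoch": len(epoch_acc), "loss": loss, "accuracy": acc}
                )

            recent = epoch_acc[-int(self.epochs_per_round):]
            if max(recent) - min(recent) < float(self.stability_tol):
                break

        self.history_ = pd.DataFrame(history)
        self.n_rounds_ = rounds_run
        return self

    # -- inference -------------------------------------------------------------

    def pair_similarity(self, XA, XB) -> np.ndarray:
        """Similarity score in [0, 1] for row-aligned embedding pairs."""
        check_is_fitted(self, "net_")
        XA = check_array(np.atleast_2d(XA), dtype=float)
        XB = check_array(np.atleast_2d(XB), dtype=float)
        if XA.shape != XB.shape:
            raise ModelError(f"pair batches differ in shape: {XA.shape} vs {XB.shape}")
        return self.net_.pair_scores(XA, XB)

    def decision_function(self, X) -> np.ndarray:
        """Aggregated positive-class probability ``rho`` for each row of X."""
        check_is_fitted(self, "net_")
        X = check_array(np.atleast_2d(X), dtype=float)
        s_pos = self.net_.cross_scores(X, self.X_pos_)
        s_neg = self.net_.cross_scores(X, self.X_neg_)
        c_o = s_pos.sum(axis=1)
        c_n = s_neg.sum(axis=1)
        zeta = (1.0 - c_n / self.X_neg_.shape[0]) + c_o / self.X_pos_.shape[0]
        return zeta / 2.0

    def predict_proba(self, X) -> np.ndarray:
        rho = self.decision_function(X)
        return np.column_stack([1.0 - rho, rho])

    def predict(self, X) -> np.ndarray:
        rho = self.decision_function(X)
        return self.classes_[(rho >= float(self.decision_threshold)).astype(int)]


def save_model(clf: SiameseSimilarityClassifier, directory) -> None:
    """Persist a fitted classifier: weights + training pools as ``.npz``,
    hyperparameters as JSON, history as CSV."""
    import json
    from pathlib import Path

    check_is_fitted(clf, "net_")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    weights = {f"w{i}": w for i, w in enumerate(clf.net_.get_weights())}
    np.savez(directory / "weights.npz", X_pos=clf.X_pos_, X_neg=clf.X_neg_,
             classes=clf.classes_, **weights)
    params = clf.get_params()
    params["encoder_widths"] = list(params["encoder_widths"])
    (directory / "config.json").write_text(
        json.dumps({"params": params, "n_rounds": clf.n_rounds_}, indent=2),
        encoding="utf-8",
    )
    clf.history_.to_csv(directory / "history.csv", index=False)


def load_model(directory) -> SiameseSimilarityClassifier:
    """Restore a classifier saved by :func:`save_model`."""
    import json
    from pathlib import Path

    directory = Path(directory)
    meta = json.loads((directory / "config.json").read_text(encoding="utf-8"))
    params = meta["params"]
    params["encoder_widths"] = tuple(params["encoder_widths"])
    clf = SiameseSimilarityClassifier(**params)
    data = np.load(directory / "weights.npz")
    clf.X_pos_ = data["X_pos"]
    clf.X_neg_ = data["X_neg"]
    clf.classes_ = data["classes"]
    clf.n_features_in_ = clf.X_pos_.shape[1]
    clf.net_ = SimilarityNet(
        input_dim=clf.n_features_in_,
        encoder_widths=clf.encoder_widths,
        head_width=clf.head_width,
        dropout=clf.dropout,
    )
    n_params = len(clf.net_.get_weights())
    clf.net_.set_weights([data[f"w{i}"] for i in range(n_params)])
    clf.history_ = pd.read_csv(directory / "history.csv")
    clf.n_rounds_ = int(meta["n_rounds"])
    return clf


def train_iterative(O, N, backend, config: Optional[NetConfig] = None) -> SiameseSimilarityClassifier:
    """Embed the positive/negative training sets and fit the pair classifier.

    Thin functional wrapper over :class:`SiameseSimilarityClassifier` for
    callers holding :class:`~simpep.peptide_io.PeptideSet` objects and an
    embedding backend rather than matrices.
    """
    from simpep.embedding import embed_set

    config = config or NetConfig(input_dim=backend.dim)
    X_pos = embed_set(O, backend)
    X_neg = embed_set(N, backend)
    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(len(X_pos)), np.zeros(len(X_neg))])
    clf = SiameseSimilarityClassifier(
        encoder_widths=config.encoder_widths,
        head_width=config.head_width,
        dropout=config.dropout,
        learning_rate=config.learning_rate,
        epochs_per_round=config.epochs_per_round,
        max_rounds=config.max_rounds,
        stability_tol=config.stability_tol,
        batch_size=config.batch_size,
        random_state=config.seed,
    )
    return clf.fit(X, y)
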