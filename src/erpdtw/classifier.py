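"""Scikit-learn estimator wrapping the transformer epoch classifier."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import LabelEncoder
from sklearn.utils.validation import check_is_fitted

from .nn import Adam, ErpTransformerNet


class ErpTransformerClassifier(ClassifierMixin, BaseEstimator):
    """Transformer-encoder classifier for fixed-length multichannel epochs.

    ``X`` has shape ``(n_trials, n_samples, n_channels)``; ``y`` is any
    binary (or n-ary) label array.  Defaults follow the published operating
    point: 3 encoders, 5 attention heads with head dimension equal to the
    channel count, dropout 0.5, Adam at learning rate 5e-4, batch size 256
    (capped at the training-set size), 100 training epochs.

    Parameters
    ----------
    num_encoders, num_heads, head_dim, ffn_hidden, dropout_p, attention_scale
        Architecture knobs; ``head_dim=None`` uses the channel count,
        ``attention_scale`` is ``"num_heads"`` (scores times
        ``num_heads**-0.5``) or the conventional ``"head_dim"``.
    n_epochs, batch_size, lr
        Training-loop controls.
    random_state : int or None
        Seeds parameter initialisation, batch shuffling and dropout.

    Attributes
    ----------
    classes_ : ndarray of class labels.
    net_ : the fitted :class:`~erpdtw.nn.ErpTransformerNet`.
    loss_history_ : per-epoch mean training loss.
    eval_pred_history_ : list of per-epoch predicted labels on ``eval_set``
        (present only when ``fit`` received one).
    """

    def __init__(self, num_encoders=3, num_heads=5, head_dim=None,
                 ffn_hidden=64, dropout_p=0.5, attention_scale="num_heads",
                 n_epochs=100, batch_size=256, lr=5e-4,
                 use_positional_encoding=True, random_state=None):
        self.num_encoders = num_encoders
        self.num_heads = num_heads
        self.head_dim = head_dim
        self.ffn_hidden = ffn_hidden
        self.dropout_p = dropout_p
        self.attention_scale = attention_scale
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.lr = lr
        self.use_positional_encoding = use_positional_encoding
        self.random_state = random_state

    def _validate_X(self, X, fitted=False):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError(
                f"X must be (n_trials, n_samples, n_channels), got shape {X.shape}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if fitted and X.shape[1:] != self._epoch_shape_:
            raise ValueError(
                f"expected epochs of shape {self._epoch_shape_}, got {X.shape[1:]}"
            )
        return X

    def fit(self, X, y, eval_set=None):
        """Train with mini-batch Adam on softmax cross-entropy.

        ``eval_set=(X_val, y_val)`` triggers an evaluation after every epoch;
        predictions are recorded in ``eval_pred_history_`` so callers can
        derive per-epoch confusion counts without re-predicting.
        """
        X = self._validate_X(X)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        self._le_ = LabelEncoder().fit(y)
        self.classes_ = self._le_.classes_
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        y_idx = self._le_.transform(y)
        self._epoch_shape_ = X.shape[1:]
        self.n_features_in_ = X.shape[1] * X.shape[2]

        seed = 0 if self.random_state is None else int(self.random_state)
        ss = np.random.SeedSequence(seed)
        init_seed, loop_seed = ss.spawn(2)
        self.net_ = ErpTransformerNet(
            seq_len=X.shape[1], input_dim=X.shape[2],
            num_encoders=self.num_encoders, num_heads=self.num_heads,
            head_dim=self.head_dim, ffn_hidden=self.ffn_hidden,
            dropout_p=self.dropout_p, attention_scale=self.attention_scale,
            num_classes=len(self.classes_),
            use_positional_encoding=self.use_positional_encoding,
            seed=init_seed.generate_state(1)[0] % (2 ** 31),
        )
        opt = Adam(self.net_.params(), lr=self.lr)
        rng = np.random.default_rng(loop_seed)
        n = X.shape[0]
        bs = min(self.batch_size, n)
        self.loss_history_ = []
        self.eval_pred_history_ = [] if eval_set is not None else None
        for _ in range(self.n_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                loss = self.net_.loss_and_grad(X[idx], y_idx[idx], rng)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {len(self.loss_history_)}"
                    )
                opt.step()
                losses.append(loss)
            self.loss_history_.append(float(np.mean(losses)))
            if eval_set is not None:
                self.eval_pred_history_.append(self.predict(eval_set[0]))
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "net_")
        X = self._validate_X(X, fitted=True)
        return self.net_.predict_proba(X)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def save(self, path):
        """Persist weights + architecture to an ``.npz`` checkpoint."""
        check_is_fitted(self, "net_")
        self.net_.save(path, extra={"classes": np.asarray(self.classes_)})

    @classmethod
    def from_checkpoint(cls, path):
        net, extra = ErpTransformerNet.load(path, extra_keys=("classes",))
        clf = cls()
        clf.net_ = net
        clf.classes_ = extra["classes"]
        clf._le_ = LabelEncoder().fit(clf.classes_)
        clf._epoch_shape_ = (net.seq_len, net.input_dim)
        clf.n_features_in_ = net.seq_len * net.input_dim
        return clf
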