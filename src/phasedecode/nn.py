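"""A small fully connected softmax classifier trained with momentum SGD.

Architecture: input -> [dense -> batch norm -> ELU(alpha) -> dropout] x 2 ->
dense -> softmax.  Training uses stochastic gradient descent with momentum,
mini-batches, periodic validation and early stopping on validation loss,
keeping the best-validation weights.  The network is tiny (tens of units), so
plain numpy is entirely adequate; everything is seeded and single-threaded
deterministic.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError


def _elu(x: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(x > 0, x, alpha * np.expm1(x))


def _elu_grad(x: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(x > 0, 1.0, alpha * np.exp(x))


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class FullyConnectedClassifier:
    """Two-hidden-layer batch-normalized ELU network with a softmax head."""

    def __init__(
        self,
        n_features: int,
        n_classes: int,
        hidden=(44, 44),
        elu_alpha: float = 1.0,
        dropout: float = 0.2,
        seed=None,
    ):
        rng = np.random.default_rng(seed)
        self.elu_alpha = elu_alpha
        self.dropout = dropout
        self.rng = rng
        dims = [n_features, *hidden, n_classes]
        self.W = [
            rng.standard_normal((dims[i], dims[i + 1])) * np.sqrt(2.0 / dims[i])
            for i in range(len(dims) - 1)
        ]
        self.b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        # batch-norm parameters per hidden layer
        self.gamma = [np.ones(h) for h in hidden]
        self.beta = [np.zeros(h) for h in hidden]
        self.run_mean = [np.zeros(h) for h in hidden]
        self.run_var = [np.ones(h) for h in hidden]
        self.bn_momentum = 0.9
        self.eps = 1e-5

    # -- forward -----------------------------------------------------------
    def _forward(self, X, training: bool):
        cache = {"X": X, "layers": []}
        a = X
        for li in range(len(self.gamma)):
            z = a @ self.W[li] + self.b[li]
            if training:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                self.run_mean[li] = (
                    self.bn_momentum * self.run_mean[li] + (1 - self.bn_momentum) * mu
                )
                self.run_var[li] = (
                    self.bn_momentum * self.run_var[li] + (1 - self.bn_momentum) * var
                )
            else:
                mu, var = self.run_mean[li], self.run_var[li]
            zhat = (z - mu) / np.sqrt(var + self.eps)
            bn = self.gamma[li] * zhat + self.beta[li]
            act = _elu(bn, self.elu_alpha)
            if training and self.dropout > 0:
                keep = (self.rng.random(act.shape) >= self.dropout) / (1 - self.dropout)
                out = act * keep
            else:
                keep = None
                out = act
            cache["layers"].append(
                dict(a_in=a, z=z, mu=mu, var=var, zhat=zhat, bn=bn, keep=keep)
            )
            a = out
        logits = a @ self.W[-1] + self.b[-1]
        cache["a_last"] = a
        cache["probs"] = _softmax(logits)
        return cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities in evaluation mode (running BN stats, no dropout)."""
        return self._forward(np.asarray(X, float), training=False)["probs"]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    # -- backward ----------------------------------------------------------
    def _backward(self, cache, y_onehot):
        grads_W = [None] * len(self.W)
        grads_b = [None] * len(self.b)
        grads_g = [None] * len(self.gamma)
        grads_be = [None] * len(self.beta)
        n = y_onehot.shape[0]
        delta = (cache["probs"] - y_onehot) / n
        grads_W[-1] = cache["a_last"].T @ delta
        grads_b[-1] = delta.sum(axis=0)
        d_a = delta @ self.W[-1].T
        for li in reversed(range(len(self.gamma))):
            lay = cache["layers"][li]
            if lay["keep"] is not None:
                d_a = d_a * lay["keep"]
            d_bn = d_a * _elu_grad(lay["bn"], self.elu_alpha)
            grads_g[li] = (d_bn * lay["zhat"]).sum(axis=0)
            grads_be[li] = d_bn.sum(axis=0)
            # batch-norm backward (batch statistics)
            inv_std = 1.0 / np.sqrt(lay["var"] + self.eps)
            d_zhat = d_bn * self.gamma[li]
            m = d_zhat.shape[0]
            d_z = (
                inv_std / m
                * (m * d_zhat - d_zhat.sum(axis=0)
                   - lay["zhat"] * (d_zhat * lay["zhat"]).sum(axis=0))
            )
            grads_W[li] = lay["a_in"].T @ d_z
            grads_b[li] = d_z.sum(axis=0)
            d_a = d_z @ self.W[li].T
        return grads_W, grads_b, grads_g, grads_be

    # -- training ----------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray = None,
        y_val: np.ndarray = None,
        epochs: int = 50,
        batch_size: int = 64,
        learning_rate: float = 0.01,
        momentum: float = 0.9,
        val_every: int = 50,
        patience: int = 15,
    ):
        """Momentum-SGD training with early stopping on validation loss.

        Validation runs every ``val_every`` mini-batches; training stops when
        the validation loss has not improved for ``patience`` validation
        steps, and the best-validation weights are restored.  Non-finite loss
        aborts with a diagnostic.
        """
        X = np.asarray(X, float)
        y = np.asarray(y, int)
        if not np.isfinite(X).all():
            raise ValidationError("features must be finite")
        K = self.W[-1].shape[1]
        onehot = np.eye(K)[y]
        vel = {
            "W": [np.zeros_like(w) for w in self.W],
            "b": [np.zeros_like(b) for b in self.b],
            "g": [np.zeros_like(g) for g in self.gamma],
            "be": [np.zeros_like(b) for b in self.beta],
        }
        use_val = X_val is not None and len(X_val) > 0
        best_loss = np.inf
        best_state = None
        stale = 0
        iteration = 0
        stop = False
        for _ in range(epochs):
            order = self.rng.permutation(len(X))
            for start in range(0, len(X), batch_size):
                sel = order[start : start + batch_size]
                cache = self._forward(X[sel], training=True)
                loss = -np.mean(
                    np.log(cache["probs"][np.arange(len(sel)), y[sel]] + 1e-12)
                )
                if not np.isfinite(loss):
                    raise ValidationError(
                        f"non-finite training loss at iteration {iteration}"
                    )
                gW, gb, gg, gbe = self._backward(cache, onehot[sel])
                for li in range(len(self.W)):
                    vel["W"][li] = momentum * vel["W"][li] - learning_rate * gW[li]
                    self.W[li] += vel["W"][li]
                    vel["b"][li] = momentum * vel["b"][li] - learning_rate * gb[li]
                    self.b[li] += vel["b"][li]
                for li in range(len(self.gamma)):
                    vel["g"][li] = momentum * vel["g"][li] - learning_rate * gg[li]
                    self.gamma[li] += vel["g"][li]
                    vel["be"][li] = momentum * vel["be"][li] - learning_rate * gbe[li]
                    self.beta[li] += vel["be"][li]
                iteration += 1
                if use_val and iteration % val_every == 0:
                    probs = self.predict_proba(X_val)
                    vloss = -np.mean(
                        np.log(probs[np.arange(len(y_val)), y_val] + 1e-12)
                    )
                    if vloss < best_loss - 1e-9:
                        best_loss = vloss
                        best_state = self._snapshot()
                        stale = 0
                    else:
                        stale += 1
                        if stale >= patience:
                            stop = True
                            break
            if stop:
                break
        if use_val and best_state is not None:
            self._restore(best_state)
        return self

    def _snapshot(self):
        return (
            [w.copy() for w in self.W],
            [b.copy() for b in self.b],
            [g.copy() for g in self.gamma],
            [b.copy() for b in self.beta],
            [m.copy() for m in self.run_mean],
            [v.copy() for v in self.run_var],
        )

    def _restore(self, state):
        self.W, self.b, self.gamma, self.beta, self.run_mean, self.run_var = (
            [a.copy() for a in part] for part in state
        )
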