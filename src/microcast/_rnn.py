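"""NumPy recurrent networks for short-lag sequence regression.

Stacked LSTM/GRU layers with a linear dense head, trained by backpropagation
through time with the Adam optimizer and mean-absolute-error loss. Sequences
here are short lag windows (typically 3 steps), so exact full BPTT in NumPy is
cheap; gradient correctness is pinned by a finite-difference check in the test
suite.

Conventions: gates use the logistic function; the candidate/state activation
is configurable (ReLU or tanh). Inverted dropout with a per-sample mask shared
across time steps is applied to each layer's output sequence during training.
Gradients are globally norm-clipped for stability under ReLU dynamics.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


_ACTIVATIONS = {
    "relu": (
        lambda z: np.maximum(z, 0.0),
        lambda z, a: (z > 0).astype(z.dtype),
    ),
    "tanh": (
        np.tanh,
        lambda z, a: 1.0 - a * a,
    ),
    "linear": (
        lambda z: z,
        lambda z, a: np.ones_like(z),
    ),
}


def _glorot(rng: np.random.Generator, shape: tuple) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, shape)


class _Cell:
    """One recurrent layer; processes a full (N, T, D) sequence."""

    def __init__(self, cell_type: str, input_dim: int, hidden: int,
                 activation: str, rng: np.random.Generator):
        self.cell_type = cell_type
        self.hidden = hidden
        self.activation = activation
        n_gates = 4 if cell_type == "lstm" else 3
        self.params = {
            "Wx": _glorot(rng, (input_dim, n_gates * hidden)),
            "Wh": _glorot(rng, (hidden, n_gates * hidden)),
            "b": np.zeros(n_gates * hidden),
        }
        if cell_type == "lstm":
            # forget-gate bias 1: standard stabilization
            self.params["b"][hidden : 2 * hidden] = 1.0

    def forward(self, X: np.ndarray):
        """Return the hidden sequence (N, T, H) and a BPTT cache."""
        act, _ = _ACTIVATIONS[self.activation]
        N, T, _ = X.shape
        H = self.hidden
        p = self.params
        h = np.zeros((N, H))
        HS = np.empty((N, T, H))
        steps = []
        if self.cell_type == "lstm":
            c = np.zeros((N, H))
            for t in range(T):
                x = X[:, t, :]
                z = x @ p["Wx"] + h @ p["Wh"] + p["b"]
                zi, zf, zo, zg = np.split(z, 4, axis=1)
                i, f, o = _sigmoid(zi), _sigmoid(zf), _sigmoid(zo)
                g = act(zg)
                c_new = f * c + i * g
                hc = act(c_new)
                h_new = o * hc
                steps.append(dict(x=x, h_prev=h, c_prev=c, i=i, f=f, o=o,
                                  g=g, zg=zg, c=c_new, hc=hc))
                h, c = h_new, c_new
                HS[:, t, :] = h
        else:  # gru
            for t in range(T):
                x = X[:, t, :]
                zx = x @ p["Wx"] + p["b"]
                zh = h @ p["Wh"]
                zxz, zxr, zxn = np.split(zx, 3, axis=1)
                zhz, zhr, zhn = np.split(zh, 3, axis=1)
                u = _sigmoid(zxz + zhz)      # update gate
                r = _sigmoid(zxr + zhr)      # reset gate
                zn = zxn + r * zhn
                n = act(zn)
                h_new = u * h + (1.0 - u) * n
                steps.append(dict(x=x, h_prev=h, u=u, r=r, n=n, zn=zn, zhn=zhn))
                h = h_new
                HS[:, t, :] = h
        return HS, {"steps": steps, "X_shape": X.shape}

    def backward(self, cache, dHS: np.ndarray):
        """Backprop a gradient on the full hidden sequence.

        Returns (parameter grads, gradient w.r.t. the input sequence).
        """
        _, dact = _ACTIVATIONS[self.activation]
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dX = np.zeros(cache["X_shape"])
        steps = cache["steps"]
        dh_carry = np.zeros((cache["X_shape"][0], self.hidden))
        if self.cell_type == "lstm":
            dc = np.zeros_like(dh_carry)
            for t in range(len(steps) - 1, -1, -1):
                step = steps[t]
                dh = dHS[:, t, :] + dh_carry
                i, f, o, g = step["i"], step["f"], step["o"], step["g"]
                do = dh * step["hc"]
                dc = dc + dh * o * dact(step["c"], step["hc"])
                di = dc * g
                df = dc * step["c_prev"]
                dg = dc * i
                dzi = di * i * (1 - i)
                dzf = df * f * (1 - f)
                dzo = do * o * (1 - o)
                dzg = dg * dact(step["zg"], g)
                dz = np.hstack([dzi, dzf, dzo, dzg])
                grads["Wx"] += step["x"].T @ dz
                grads["Wh"] += step["h_prev"].T @ dz
                grads["b"] += dz.sum(axis=0)
                dX[:, t, :] = dz @ p["Wx"].T
                dh_carry = dz @ p["Wh"].T
                dc = dc * f
        else:
            for t in range(len(steps) - 1, -1, -1):
                step = steps[t]
                dh = dHS[:, t, :] + dh_carry
                u, r, n, h_prev = step["u"], step["r"], step["n"], step["h_prev"]
                du = dh * (h_prev - n)
                dn = dh * (1.0 - u)
                dh_prev = dh * u
                dzn = dn * dact(step["zn"], n)
                dr = dzn * step["zhn"]
                dzu = du * u * (1 - u)
                dzr = dr * r * (1 - r)
                dzx = np.hstack([dzu, dzr, dzn])
                grads["Wx"] += step["x"].T @ dzx
                grads["b"] += dzx.sum(axis=0)
                # recurrent kernel sees [update, reset, r*candidate] paths
                dzh = np.hstack([dzu, dzr, dzn * r])
                grads["Wh"] += h_prev.T @ dzh
                dX[:, t, :] = dzx @ p["Wx"].T
                dh_carry = dh_prev + dzh @ p["Wh"].T
        return grads, dX


class RecurrentNet:
    """Stacked recurrent layers (LSTM or GRU) plus a linear output layer."""

    def __init__(
        self,
        cell_type: str,
        input_dim: int,
        hidden: int,
        output_dim: int,
        layers: int = 1,
        activation: str = "relu",
        dropout: float = 0.2,
        seed: int = 0,
    ):
        if cell_type not in ("lstm", "gru"):
            raise ValueError(f"unknown cell type {cell_type!r}")
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        if not 0 <= dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if layers < 1:
            raise ValueError("layers must be >= 1")
        self.cell_type = cell_type
        self.input_dim = input_dim
        self.hidden = hidden
        self.output_dim = output_dim
        self.layers = layers
        self.activation = activation
        self.dropout = dropout
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.cells = [
            _Cell(cell_type, input_dim if i == 0 else hidden, hidden,
                  activation, rng)
            for i in range(layers)
        ]
        self.head = {"Wy": _glorot(rng, (hidden, output_dim)),
                     "by": np.zeros(output_dim)}
        self._rng = rng
        self.history: dict = {"loss": [], "val_loss": []}
        self.stopped_epoch: int | None = None

    # -- parameter flattening (for Adam and serialization) ------------------

    def _param_items(self):
        for i, cell in enumerate(self.cells):
            for k, v in cell.params.items():
                yield f"l{i}_{k}", v
        yield "Wy", self.head["Wy"]
        yield "by", self.head["by"]

    def get_params(self) -> dict:
        return {k: v.copy() for k, v in self._param_items()}

    def set_params(self, params: dict) -> None:
        for i, cell in enumerate(self.cells):
            for k in cell.params:
                cell.params[k] = np.asarray(params[f"l{i}_{k}"], dtype=float)
        self.head["Wy"] = np.asarray(params["Wy"], dtype=float)
        self.head["by"] = np.asarray(params["by"], dtype=float)

    # -- forward / backward --------------------------------------------------

    def _forward(self, X: np.ndarray, train: bool = False):
        seq = X
        caches = []
        masks = []
        for cell in self.cells:
            HS, cache = cell.forward(seq)
            if train and self.dropout > 0:
                keep = 1.0 - self.dropout
                # per-sample mask shared across time steps
                mask = (self._rng.random((HS.shape[0], 1, HS.shape[2])) < keep) / keep
                HS = HS * mask
            else:
                mask = None
            caches.append(cache)
            masks.append(mask)
            seq = HS
        h_last = seq[:, -1, :]
        y = h_last @ self.head["Wy"] + self.head["by"]
        return y, {"caches": caches, "masks": masks, "h_last": h_last}

    def predict(self, X: np.ndarray) -> np.ndarray:
        y, _ = self._forward(np.asarray(X, dtype=float), train=False)
        return y

    def _backward(self, cache, dY: np.ndarray) -> dict:
        grads = {"Wy": cache["h_last"].T @ dY, "by": dY.sum(axis=0)}
        dh_last = dY @ self.head["Wy"].T
        N = dY.shape[0]
        dHS = None
        for i in range(len(self.cells) - 1, -1, -1):
            cell = self.cells[i]
            if dHS is None:
                T = len(cache["caches"][i]["steps"])
                dHS = np.zeros((N, T, cell.hidden))
                dHS[:, -1, :] = dh_last
            if cache["masks"][i] is not None:
                dHS = dHS * cache["masks"][i]
            cell_grads, dX = cell.backward(cache["caches"][i], dHS)
            for k, v in cell_grads.items():
                grads[f"l{i}_{k}"] = v
            dHS = dX
        return grads

    # -- training ------------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        max_epochs: int = 200,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        patience: int = 10,
        clipnorm: float = 1.0,
        tol: float = 0.0,
    ) -> "RecurrentNet":
        """Adam + MAE loss with early stopping on the validation loss.

        With no validation set, early stopping monitors the training loss.
        The best weights (lowest monitored loss) are restored on exit.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        N = len(X)
        params = dict(self._param_items())
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v2 = {k: np.zeros_like(v) for k, v in params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best = np.inf
        best_params = self.get_params()
        wait = 0
        for epoch in range(1, max_epochs + 1):
            order = self._rng.permutation(N)
            epoch_loss = 0.0
            for start in range(0, N, batch_size):
                idx = order[start : start + batch_size]
                yb = y[idx]
                pred, cache = self._forward(X[idx], train=True)
                resid = pred - yb
                loss = float(np.mean(np.abs(resid)))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}"
                    )
                epoch_loss += loss * len(idx)
                dY = np.sign(resid) / resid.size
                grads = self._backward(cache, dY)
                norm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
                if clipnorm and norm > clipnorm:
                    grads = {k: g * (clipnorm / (norm + 1e-12))
                             for k, g in grads.items()}
                step += 1
                for k in params:
                    m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                    v2[k] = beta2 * v2[k] + (1 - beta2) * grads[k] ** 2
                    mhat = m[k] / (1 - beta1**step)
                    vhat = v2[k] / (1 - beta2**step)
                    # in-place update on the live parameter arrays
                    params[k] -= learning_rate * mhat / (np.sqrt(vhat) + eps)
            epoch_loss /= N
            self.history["loss"].append(epoch_loss)
            if X_val is not None and len(X_val):
                monitored = self.mae_loss(X_val, y_val)
                self.history["val_loss"].append(monitored)
            else:
                monitored = epoch_loss
            if monitored < best - tol:
                best = monitored
                best_params = self.get_params()
                wait = 0
            else:
                wait += 1
                if wait > patience:
                    self.stopped_epoch = epoch
                    break
        if self.stopped_epoch is None:
            self.stopped_epoch = len(self.history["loss"])
        self.set_params(best_params)
        return self

    # -- (de)serialization ----------------------------------------------------

    def get_config(self) -> dict:
        return {
            "cell_type": self.cell_type,
            "input_dim": self.input_dim,
            "hidden": self.hidden,
            "output_dim": self.output_dim,
            "layers": self.layers,
            "activation": self.activation,
            "dropout": self.dropout,
            "seed": self.seed,
        }

    @classmethod
    def from_config(cls, config: dict, params: dict) -> "RecurrentNet":
        net = cls(**config)
        net.set_params(params)
        return net

    def mae_loss(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(np.abs(self.predict(X) - np.asarray(y, dtype=float))))
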