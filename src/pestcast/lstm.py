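"""A small from-scratch LSTM binary classifier for weekly pest forecasting.

The network is the classic gated cell, written directly from its equations:

    i_t = sigmoid(W_i [h_{t-1}, x_t] + b_i)        input gate
    f_t = sigmoid(W_f [h_{t-1}, x_t] + b_f)        forget gate
    o_t = sigmoid(W_o [h_{t-1}, x_t] + b_o)        output gate
    g_t = tanh   (W_c [h_{t-1}, x_t] + b_c)        candidate
    C_t = f_t * C_{t-1} + i_t * g_t
    h_t = o_t * tanh(C_t)

unrolled over a fixed window of ``timesteps`` weekly records (default 4,
each with 8 weather features plus, optionally, the pest value as a 9th).
The hidden vector of the last step goes through dropout, a small ReLU layer
and a 1-unit sigmoid head, producing the probability that pests occur in
the week immediately after the window.  Training minimises mean binary
cross-entropy with exact backpropagation-through-time gradients and either
plain SGD or RMSProp updates.

Everything is plain float64 numpy; there is no autodiff — the analytic
gradients are validated against central finite differences in the tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .datatypes import PEST_VALUE_COLUMN, WEATHER_FEATURES, PestDataset
from .errors import (DataError, DegenerateLabelsError, InsufficientDataError,
                     InvalidArgumentError)

__all__ = [
    "WindowedDataset", "make_windows", "CellState", "LSTMParameters",
    "TrainingConfig", "lstm_cell_forward", "forward", "bce_loss",
    "loss_and_gradients", "gradients", "sgd_step", "rmsprop_step",
    "init_rmsprop_state", "train", "predict",
]

_GATES = ("i", "f", "o", "c")


# ---------------------------------------------------------------------------
# windowing

@dataclass
class WindowedDataset:
    """Sliding windows (N, timesteps, n_features) with strictly-future labels.

    Window ``i`` covers weeks ``i .. i+timesteps-1`` and its label is the
    occurrence at week ``i+timesteps``, so the label never leaks into the
    features.
    """

    windows: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, float)
        self.labels = np.asarray(self.labels, int)
        if self.windows.ndim != 3:
            raise InvalidArgumentError("windows must have shape (N, T, F)")
        if len(self.windows) != len(self.labels):
            raise InvalidArgumentError("windows/labels length mismatch")

    def __len__(self) -> int:
        return len(self.windows)

    def __getitem__(self, key: slice) -> "WindowedDataset":
        if not isinstance(key, slice):
            raise InvalidArgumentError("WindowedDataset supports slices only")
        return WindowedDataset(self.windows[key], self.labels[key],
                               self.feature_names)

    @property
    def timesteps(self) -> int:
        return self.windows.shape[1]

    @property
    def n_features(self) -> int:
        return self.windows.shape[2]


def make_windows(ds: PestDataset, timesteps: int = 4,
                 include_pest_history: bool = True,
                 standardize_fraction: float | None = 0.75) -> WindowedDataset:
    """Tensorize a weekly series into training windows.

    Features are standardized per feature to zero mean / unit variance using
    only the rows that appear in the first ``standardize_fraction`` of the
    windows (the chronological training portion), so test-period statistics
    never leak into the scaling.  Pass ``standardize_fraction=None`` to skip
    scaling.  With ``include_pest_history`` the pest value joins the eight
    weather factors as a 9th feature.
    """
    if timesteps < 1:
        raise InvalidArgumentError("timesteps must be >= 1")
    length = len(ds)
    if length <= timesteps:
        raise InsufficientDataError(
            f"series of length {length} has no strictly-future label for "
            f"timesteps={timesteps}")
    names = list(WEATHER_FEATURES)
    feat = ds.weather
    if include_pest_history:
        feat = np.column_stack([feat, ds.pest_value])
        names.append(PEST_VALUE_COLUMN)
    feat = feat.astype(float)

    n_samp = length - timesteps
    if standardize_fraction is not None:
        if not 0.0 < standardize_fraction <= 1.0:
            raise InvalidArgumentError("standardize_fraction must be in (0, 1]")
        n_train = max(1, math.floor(standardize_fraction * n_samp))
        # rows entering the features of the first n_train windows
        fit_rows = feat[:n_train + timesteps - 1]
        mean = fit_rows.mean(axis=0)
        sd = fit_rows.std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        feat = (feat - mean) / sd

    windows = np.stack([feat[i:i + timesteps] for i in range(n_samp)])
    labels = ds.occurrence[timesteps:]
    return WindowedDataset(windows, labels, tuple(names))


# ---------------------------------------------------------------------------
# parameters

@dataclass
class LSTMParameters:
    """All trainable arrays, keyed by block name.

    Gate weights ``lstm<l>.W_<g>`` have shape (units, units + fan_in) and act
    on the concatenation ``[h_{t-1}, x_t]``; the head is a ReLU layer
    ``fc1`` (fc_hidden units) and a sigmoid unit ``fc2``.
    """

    blocks: dict[str, np.ndarray]
    units: int
    n_features: int
    n_layers: int = 1
    fc_hidden: int = 5

    def __getitem__(self, key: str) -> np.ndarray:
        return self.blocks[key]

    def keys(self):
        return self.blocks.keys()

    def layer(self, l: int) -> dict[str, np.ndarray]:
        """Weights of recurrent layer ``l`` keyed W_i..b_c."""
        return {f"{kind}_{g}": self.blocks[f"lstm{l}.{kind}_{g}"]
                for g in _GATES for kind in ("W", "b")}

    def copy(self) -> "LSTMParameters":
        return LSTMParameters({k: v.copy() for k, v in self.blocks.items()},
                              self.units, self.n_features, self.n_layers,
                              self.fc_hidden)

    @classmethod
    def initialize(cls, n_features: int, units: int = 5, n_layers: int = 1,
                   fc_hidden: int = 5, seed: int = 0, scale: float = 0.1,
                   forget_bias: float = 1.0) -> "LSTMParameters":
        """Seeded uniform(-scale, scale) weights; forget-gate bias starts at
        ``forget_bias`` (a standard stabiliser for short sequences)."""
        rng = np.random.default_rng(seed)
        blocks: dict[str, np.ndarray] = {}
        fan_in = n_features
        for l in range(n_layers):
            for g in _GATES:
                blocks[f"lstm{l}.W_{g}"] = rng.uniform(
                    -scale, scale, size=(units, units + fan_in))
                blocks[f"lstm{l}.b_{g}"] = np.zeros(units)
            blocks[f"lstm{l}.b_f"] = np.full(units, forget_bias)
            fan_in = units
        blocks["fc1.W"] = rng.uniform(-scale, scale, size=(fc_hidden, units))
        blocks["fc1.b"] = np.zeros(fc_hidden)
        blocks["fc2.W"] = rng.uniform(-scale, scale, size=(1, fc_hidden))
        blocks["fc2.b"] = np.zeros(1)
        return cls(blocks, units, n_features, n_layers, fc_hidden)

    def save(self, path) -> None:
        doc = {
            "meta": {"units": self.units, "n_features": self.n_features,
                     "n_layers": self.n_layers, "fc_hidden": self.fc_hidden},
            "blocks": {k: v.tolist() for k, v in self.blocks.items()},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "LSTMParameters":
        with open(path) as fh:
            doc = json.load(fh)
        blocks = {k: np.asarray(v, float) for k, v in doc["blocks"].items()}
        return cls(blocks, **doc["meta"])


# ---------------------------------------------------------------------------
# forward pass

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class CellState:
    """Hidden/memory vectors plus the gate activations of the last step."""

    h: np.ndarray
    c: np.ndarray
    i: np.ndarray | None = None
    f: np.ndarray | None = None
    o: np.ndarray | None = None
    g: np.ndarray | None = None


def lstm_cell_forward(x_t: np.ndarray, state: CellState,
                      weights: dict[str, np.ndarray]) -> CellState:
    """One cell step.  ``x_t`` may be a single feature vector or a batch
    (B, F); ``weights`` maps ``W_i..b_c`` as returned by
    :meth:`LSTMParameters.layer`."""
    x_t = np.asarray(x_t, float)
    if not np.all(np.isfinite(x_t)):
        raise DataError("non-finite input to LSTM cell")
    z = np.concatenate([state.h, x_t], axis=-1)
    i = _sigmoid(z @ weights["W_i"].T + weights["b_i"])
    f = _sigmoid(z @ weights["W_f"].T + weights["b_f"])
    o = _sigmoid(z @ weights["W_o"].T + weights["b_o"])
    g = np.tanh(z @ weights["W_c"].T + weights["b_c"])
    c = f * state.c + i * g
    h = o * np.tanh(c)
    return CellState(h=h, c=c, i=i, f=f, o=o, g=g)


def _forward_cached(x: np.ndarray, params: LSTMParameters,
                    dropout_mask: np.ndarray | None):
    """Unrolled forward over (B, T, F) returning probabilities and caches."""
    batch, timesteps, _ = x.shape
    layer_caches = []
    inp = x
    for l in range(params.n_layers):
        weights = params.layer(l)
        state = CellState(h=np.zeros((batch, params.units)),
                          c=np.zeros((batch, params.units)))
        steps = []
        hs = np.empty((batch, timesteps, params.units))
        for t in range(timesteps):
            prev = state
            state = lstm_cell_forward(inp[:, t], prev, weights)
            steps.append((prev, state))
            hs[:, t] = state.h
        layer_caches.append({"input": inp, "steps": steps})
        inp = hs
    h_last = layer_caches[-1]["steps"][-1][1].h
    h_drop = h_last * dropout_mask if dropout_mask is not None else h_last
    z1 = h_drop @ params["fc1.W"].T + params["fc1.b"]
    a1 = np.maximum(z1, 0.0)
    logit = (a1 @ params["fc2.W"].T + params["fc2.b"]).ravel()
    prob = _sigmoid(logit)
    head = {"h_drop": h_drop, "z1": z1, "a1": a1, "logit": logit}
    return prob, layer_caches, head


def forward(window: np.ndarray, params: LSTMParameters,
            dropout_mask: np.ndarray | None = None) -> np.ndarray | float:
    """Probability of occurrence for one window (T, F) or a batch (B, T, F).

    ``dropout_mask`` (already scaled by 1/(1-rate)) is applied to the last
    hidden vector during training only; omit it for inference.
    """
    x = np.asarray(window, float)
    single = x.ndim == 2
    if single:
        x = x[None]
    if x.ndim != 3:
        raise InvalidArgumentError("window must have shape (T, F) or (B, T, F)")
    if x.shape[2] != params.n_features:
        raise InvalidArgumentError(
            f"window has {x.shape[2]} features, parameters expect "
            f"{params.n_features}")
    prob, _, _ = _forward_cached(x, params, dropout_mask)
    return float(prob[0]) if single else prob


def bce_loss(y_true, y_pred, eps_clip: float = 1e-7) -> float:
    """Mean binary cross-entropy with predictions clipped away from {0, 1}."""
    y = np.asarray(y_true, float).ravel()
    p = np.asarray(y_pred, float).ravel()
    if y.shape != p.shape:
        raise InvalidArgumentError("y_true and y_pred lengths differ")
    p = np.clip(p, eps_clip, 1.0 - eps_clip)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


# ---------------------------------------------------------------------------
# backward pass (BPTT)

def loss_and_gradients(windows: np.ndarray, labels, params: LSTMParameters,
                       dropout_mask: np.ndarray | None = None
                       ) -> tuple[float, dict[str, np.ndarray]]:
    """Mean BCE loss and its exact gradients for a batch of windows."""
    x = np.asarray(windows, float)
    if x.ndim != 3:
        raise InvalidArgumentError("windows must have shape (B, T, F)")
    y = np.asarray(labels, float).ravel()
    if len(y) != len(x):
        raise InvalidArgumentError("windows/labels length mismatch")
    batch, timesteps, _ = x.shape

    prob, layer_caches, head = _forward_cached(x, params, dropout_mask)
    loss = bce_loss(y, prob)

    grads = {k: np.zeros_like(v) for k, v in params.blocks.items()}

    # head: d(mean BCE)/d(logit) = (sigmoid(logit) - y) / B
    dlogit = ((prob - y) / batch)[:, None]                 # (B, 1)
    grads["fc2.W"] = dlogit.T @ head["a1"]
    grads["fc2.b"] = dlogit.sum(axis=0)
    da1 = dlogit @ params["fc2.W"]                         # (B, H)
    dz1 = da1 * (head["z1"] > 0)
    grads["fc1.W"] = dz1.T @ head["h_drop"]
    grads["fc1.b"] = dz1.sum(axis=0)
    dh_last = dz1 @ params["fc1.W"]                        # (B, U)
    if dropout_mask is not None:
        dh_last = dh_last * dropout_mask

    # gradient flowing into each layer's hidden sequence, (B, T, U)
    d_hidden = np.zeros((batch, timesteps, params.units))
    d_hidden[:, -1] = dh_last

    for l in range(params.n_layers - 1, -1, -1):
        cache = layer_caches[l]
        inp = cache["input"]
        weights = params.layer(l)
        d_input = np.zeros_like(inp)
        dh_next = np.zeros((batch, params.units))
        dc_next = np.zeros((batch, params.units))
        for t in range(timesteps - 1, -1, -1):
            prev, cur = cache["steps"][t]
            dh = d_hidden[:, t] + dh_next
            tanh_c = np.tanh(cur.c)
            do = dh * tanh_c
            dc = dc_next + dh * cur.o * (1.0 - tanh_c ** 2)
            di = dc * cur.g
            df = dc * prev.c
            dg = dc * cur.i
            dz = {
                "i": di * cur.i * (1.0 - cur.i),
                "f": df * cur.f * (1.0 - cur.f),
                "o": do * cur.o * (1.0 - cur.o),
                "c": dg * (1.0 - cur.g ** 2),
            }
            z = np.concatenate([prev.h, inp[:, t]], axis=-1)   # (B, U+F)
            dconcat = np.zeros_like(z)
            for g in _GATES:
                grads[f"lstm{l}.W_{g}"] += dz[g].T @ z
                grads[f"lstm{l}.b_{g}"] += dz[g].sum(axis=0)
                dconcat += dz[g] @ weights[f"W_{g}"]
            dh_next = dconcat[:, :params.units]
            d_input[:, t] = dconcat[:, params.units:]
            dc_next = dc * cur.f
        if l > 0:
            d_hidden = d_input
    return loss, grads


def gradients(windows, labels, params: LSTMParameters,
              dropout_mask: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Exact BPTT gradients of the mean BCE loss (see
    :func:`loss_and_gradients`)."""
    return loss_and_gradients(windows, labels, params, dropout_mask)[1]


# ---------------------------------------------------------------------------
# optimizers

def _tree_blocks(params):
    return params.blocks if isinstance(params, LSTMParameters) else params


def _tree_rewrap(params, blocks):
    if isinstance(params, LSTMParameters):
        return LSTMParameters(blocks, params.units, params.n_features,
                              params.n_layers, params.fc_hidden)
    return blocks


def sgd_step(params, grads: dict[str, np.ndarray], lr: float):
    """Plain gradient descent: theta <- theta - lr * g (pure, returns new)."""
    if lr <= 0:
        raise InvalidArgumentError("learning rate must be positive")
    blocks = _tree_blocks(params)
    new = {k: v - lr * grads[k] for k, v in blocks.items()}
    return _tree_rewrap(params, new)


def init_rmsprop_state(params) -> dict[str, np.ndarray]:
    """Zero-initialized running second-moment estimate v."""
    return {k: np.zeros_like(v) for k, v in _tree_blocks(params).items()}


def rmsprop_step(params, grads: dict[str, np.ndarray],
                 state: dict[str, np.ndarray], lr: float = 0.001,
                 gamma: float = 0.9, eps: float = 1e-8):
    """RMSProp: v <- gamma v + (1-gamma) g^2; theta <- theta - lr g/(sqrt(v)+eps).

    Returns (new params, new state); both inputs are left untouched.
    """
    if lr <= 0:
        raise InvalidArgumentError("learning rate must be positive")
    if not 0.0 <= gamma < 1.0:
        raise InvalidArgumentError("forgetting factor gamma must be in [0, 1)")
    blocks = _tree_blocks(params)
    new_state = {k: gamma * state[k] + (1.0 - gamma) * grads[k] ** 2
                 for k in blocks}
    new = {k: v - lr * grads[k] / (np.sqrt(new_state[k]) + eps)
           for k, v in blocks.items()}
    return _tree_rewrap(params, new), new_state


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainingConfig:
    """Hyper-parameters for :func:`train`.

    Defaults follow the architecture used throughout this package: one
    recurrent layer of 5 units, a [5, 1] fully-connected head, dropout 0.1
    on the last hidden vector, RMSProp with learning rate 1e-3 and
    forgetting factor 0.9, batches of 32 for up to 200 epochs with early
    stopping after 20 epochs without training-loss improvement.
    """

    learning_rate: float = 0.001
    gamma: float = 0.9
    epsilon: float = 1e-8
    batch_size: int = 32
    epochs: int = 200
    dropout: float = 0.1
    optimizer: str = "rmsprop"
    seed: int = 0
    units: int = 5
    n_layers: int = 1
    fc_hidden: int = 5
    patience: int = 20

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise InvalidArgumentError("learning_rate must be positive")
        if not 0.0 <= self.gamma < 1.0:
            raise InvalidArgumentError("gamma must be in [0, 1)")
        if not 0.0 <= self.dropout < 1.0:
            raise InvalidArgumentError("dropout must be in [0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise InvalidArgumentError("batch_size and epochs must be >= 1")
        if self.optimizer not in ("sgd", "rmsprop"):
            raise InvalidArgumentError("optimizer must be 'sgd' or 'rmsprop'")


def train(data: WindowedDataset, config: TrainingConfig | None = None
          ) -> tuple[LSTMParameters, list[float]]:
    """Mini-batch training, fully determined by ``config.seed``.

    The seed controls parameter initialization, batch shuffling and dropout
    masks, so repeated runs yield identical parameters.  Returns the final
    parameters and the per-epoch mean training loss.
    """
    config = config or TrainingConfig()
    x, y = data.windows, data.labels
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateLabelsError(
            f"training labels contain a single class {classes.tolist()}")
    n = len(x)
    rng = np.random.default_rng(config.seed)
    params = LSTMParameters.initialize(
        data.n_features, units=config.units, n_layers=config.n_layers,
        fc_hidden=config.fc_hidden,
        seed=int(rng.integers(0, 2 ** 31 - 1)))
    opt_state = init_rmsprop_state(params)

    history: list[float] = []
    best = np.inf
    wait = 0
    for _ in range(config.epochs):
        perm = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            mask = None
            if config.dropout > 0.0:
                keep = rng.random((len(idx), config.units)) >= config.dropout
                mask = keep / (1.0 - config.dropout)
            loss, grads = loss_and_gradients(x[idx], y[idx], params, mask)
            if config.optimizer == "sgd":
                params = sgd_step(params, grads, config.learning_rate)
            else:
                params, opt_state = rmsprop_step(
                    params, grads, opt_state, config.learning_rate,
                    config.gamma, config.epsilon)
            total += loss * len(idx)
        epoch_loss = total / n
        history.append(epoch_loss)
        if epoch_loss < best - 1e-6:
            best = epoch_loss
            wait = 0
        else:
            wait += 1
            if wait >= config.patience:
                break
    return params, history


def predict(params: LSTMParameters, windows, threshold: float = 0.5
            ) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels (``score >= threshold``) and raw scores, no dropout."""
    x = windows.windows if isinstance(windows, WindowedDataset) else \
        np.asarray(windows, float)
    scores = forward(x, params)
    scores = np.atleast_1d(np.asarray(scores, float))
    return (scores >= threshold).astype(int), scores
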