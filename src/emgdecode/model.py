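"""Channel-wise convolutional regression model ("force-pattern" CNN).

Architecture: the input is one 60 x 32 envelope window (500 ms x 32
channels at 120 Hz). A bank of six 60 x 1 temporal filters, shared across
channels and applied with stride 1 and no padding, collapses the time axis
so each filter produces one value per channel; tanh gives a 6 x 32 feature
map with no channel mixing. The feature map is flattened feature-map-major
(fm^1 channels 1..32, then fm^2, ...) into a 192-vector and mapped linearly
to the three joint angles:

    angle_i = W_i . fm + b_i,   i = 1 (WF/WE), 2 (P/S), 3 (HG/HO)

With the default shapes the model has 6*60 + 6 + 3*192 + 3 = 945
parameters. Because each FC row splits into six 32-long blocks aligned with
channels, the weights can be backtracked onto the electrode grid (see
:mod:`emgdecode.geometry`).

The forward pass, analytic gradients and parameter bookkeeping are written
directly in NumPy; the model is small enough that a framework would add
nothing but a dependency, and the gradients are verified against central
finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .errors import ShapeError

N_FILTERS = 6
WIN_LEN = 60
N_CHANNELS = 32
N_OUTPUTS = 3


@dataclass
class ModelParams:
    """All trainable parameters of the two-layer model."""

    conv_filters: np.ndarray  # (n_filters, win_len)
    conv_biases: np.ndarray  # (n_filters,)
    fc_weights: np.ndarray  # (n_outputs, n_filters * n_channels)
    fc_biases: np.ndarray  # (n_outputs,)
    use_conv_bias: bool = True
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.conv_filters = np.asarray(self.conv_filters, dtype=float)
        self.conv_biases = np.asarray(self.conv_biases, dtype=float)
        self.fc_weights = np.asarray(self.fc_weights, dtype=float)
        self.fc_biases = np.asarray(self.fc_biases, dtype=float)
        if self.conv_filters.ndim != 2:
            raise ShapeError("conv_filters must be (n_filters, win_len)")
        nf = self.conv_filters.shape[0]
        if self.conv_biases.shape != (nf,):
            raise ShapeError(f"conv_biases must be ({nf},), got {self.conv_biases.shape}")
        if self.fc_weights.ndim != 2 or self.fc_weights.shape[1] % nf != 0:
            raise ShapeError(
                "fc_weights must be (n_outputs, n_filters * n_channels), "
                f"got {self.fc_weights.shape}"
            )
        if self.fc_biases.shape != (self.fc_weights.shape[0],):
            raise ShapeError("fc_biases length must match fc_weights rows")
        for name in ("conv_filters", "conv_biases", "fc_weights", "fc_biases"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ShapeError(f"{name} contains non-finite values")

    @property
    def n_filters(self) -> int:
        return self.conv_filters.shape[0]

    @property
    def win_len(self) -> int:
        return self.conv_filters.shape[1]

    @property
    def n_channels(self) -> int:
        return self.fc_weights.shape[1] // self.n_filters

    @property
    def n_outputs(self) -> int:
        return self.fc_weights.shape[0]

    def copy(self) -> "ModelParams":
        return replace(
            self,
            conv_filters=self.conv_filters.copy(),
            conv_biases=self.conv_biases.copy(),
            fc_weights=self.fc_weights.copy(),
            fc_biases=self.fc_biases.copy(),
        )


def init_model(
    seed: int = 0,
    n_filters: int = N_FILTERS,
    win_len: int = WIN_LEN,
    n_channels: int = N_CHANNELS,
    n_outputs: int = N_OUTPUTS,
    use_conv_bias: bool = True,
) -> ModelParams:
    """Scaled-uniform fan-in initialization, deterministic given seed."""
    rng = np.random.default_rng(seed)
    conv_scale = 1.0 / np.sqrt(win_len)
    fc_scale = 1.0 / np.sqrt(n_filters * n_channels)
    conv_filters = rng.uniform(-conv_scale, conv_scale, size=(n_filters, win_len))
    conv_biases = (
        rng.uniform(-conv_scale, conv_scale, size=n_filters)
        if use_conv_bias
        else np.zeros(n_filters)
    )
    fc_weights = rng.uniform(-fc_scale, fc_scale, size=(n_outputs, n_filters * n_channels))
    fc_biases = rng.uniform(-fc_scale, fc_scale, size=n_outputs)
    return ModelParams(conv_filters, conv_biases, fc_weights, fc_biases,
                       use_conv_bias=use_conv_bias, seed=seed)


def _check_window(params: ModelParams, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    expected = (params.win_len, params.n_channels)
    if X.shape[-2:] != expected:
        raise ShapeError(f"window must have shape {expected}, got {X.shape}")
    return X


def conv_forward(params: ModelParams, X: np.ndarray) -> np.ndarray:
    """Feature map fm[j, c] = tanh(sum_t filter_j[t] X[t, c] + bias_j).

    The 60-tap filter spans the whole time axis (stride 1, no padding), so
    the time dimension collapses to one value per channel; channels never
    mix.
    """
    X = _check_window(params, X)
    z = params.conv_filters @ X + params.conv_biases[:, None]
    return np.tanh(z)


def flatten_feature_map(fm: np.ndarray) -> np.ndarray:
    """Feature-map-major flattening: fm^1 ch1..32, then fm^2, ... (C order)."""
    return np.asarray(fm).reshape(-1)


def unflatten_feature_map(v: np.ndarray, n_filters: int = N_FILTERS) -> np.ndarray:
    v = np.asarray(v)
    if v.size % n_filters != 0:
        raise ShapeError(f"cannot unflatten length {v.size} into {n_filters} maps")
    return v.reshape(n_filters, -1)


def fc_forward(params: ModelParams, fm: np.ndarray) -> np.ndarray:
    """Linear readout: angle_i = W_i . flatten(fm) + b_i (no activation)."""
    v = flatten_feature_map(fm)
    if v.size != params.fc_weights.shape[1]:
        raise ShapeError(
            f"feature vector length {v.size} != FC input {params.fc_weights.shape[1]}"
        )
    return params.fc_weights @ v + params.fc_biases


def forward(params: ModelParams, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """(feature map, angle 3-vector) for one window."""
    fm = conv_forward(params, X)
    return fm, fc_forward(params, fm)


def forward_batch(params: ModelParams, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized forward over a batch (B, 60, 32) -> fm (B, 6, 32), pred (B, 3)."""
    X = _check_window(params, X)
    if X.ndim == 2:
        X = X[None]
    z = np.einsum("ft,btc->bfc", params.conv_filters, X) + params.conv_biases[None, :, None]
    fm = np.tanh(z)
    v = fm.reshape(fm.shape[0], -1)
    pred = v @ params.fc_weights.T + params.fc_biases
    return fm, pred


def count_parameters(params: ModelParams) -> int:
    """Total trainable scalars (945 for the default shapes)."""
    n = params.conv_filters.size + params.fc_weights.size + params.fc_biases.size
    if params.use_conv_bias:
        n += params.conv_biases.size
    return int(n)


def mse_loss_and_grads(
    params: ModelParams, X: np.ndarray, y: np.ndarray, freeze_conv: bool = False
) -> Tuple[float, Dict[str, np.ndarray]]:
    """Mean-squared-error loss and analytic gradients for a batch.

    Loss is the mean of squared errors over all batch elements and all three
    outputs (the standard elementwise-mean MSE). Backprop through the linear
    FC layer and the tanh channel-wise convolution is written out directly.
    With ``freeze_conv`` the convolutional gradients are returned as zeros.
    """
    X = _check_window(params, X)
    if X.ndim == 2:
        X = X[None]
    y = np.atleast_2d(np.asarray(y, dtype=float))
    B = X.shape[0]
    z = np.einsum("ft,btc->bfc", params.conv_filters, X) + params.conv_biases[None, :, None]
    fm = np.tanh(z)
    v = fm.reshape(B, -1)
    pred = v @ params.fc_weights.T + params.fc_biases
    err = pred - y
    loss = float(np.mean(err**2))

    dpred = 2.0 * err / err.size  # d loss / d pred
    grads = {
        "fc_weights": dpred.T @ v,
        "fc_biases": dpred.sum(axis=0),
    }
    if freeze_conv:
        grads["conv_filters"] = np.zeros_like(params.conv_filters)
        grads["conv_biases"] = np.zeros_like(params.conv_biases)
    else:
        dv = dpred @ params.fc_weights  # (B, 192)
        dfm = dv.reshape(fm.shape)
        dz = dfm * (1.0 - fm**2)
        grads["conv_filters"] = np.einsum("bfc,btc->ft", dz, X)
        grads["conv_biases"] = (
            dz.sum(axis=(0, 2))
            if params.use_conv_bias
            else np.zeros_like(params.conv_biases)
        )
    return loss, grads


def save_model(params: ModelParams, path) -> None:
    """NPZ checkpoint with a JSON hyperparameter header; bit-exact round trip."""
    header = json.dumps(
        {
            "n_filters": params.n_filters,
            "win_len": params.win_len,
            "n_channels": params.n_channels,
            "n_outputs": params.n_outputs,
            "use_conv_bias": params.use_conv_bias,
            "seed": params.seed,
        }
    )
    np.savez(
        path,
        conv_filters=params.conv_filters,
        conv_biases=params.conv_biases,
        fc_weights=params.fc_weights,
        fc_biases=params.fc_biases,
        header=np.array(header),
    )


def load_model(path) -> ModelParams:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        return ModelParams(
            conv_filters=data["conv_filters"],
            conv_biases=data["conv_biases"],
            fc_weights=data["fc_weights"],
            fc_biases=data["fc_biases"],
            use_conv_bias=bool(header["use_conv_bias"]),
            seed=header["seed"],
        )
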