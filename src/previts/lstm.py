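"""Distributional ITS forecasting with a NumPy LSTM.

A sliding-window sequence-to-one recurrent network reads ``window`` weeks
of features (the prevalence value plus the binary intervention indicators)
and predicts the next week's prevalence as a Gaussian: an LSTM layer feeds
two parallel linear heads for the mean and the variance, the variance head
passing through a Softplus to stay positive.  Training minimizes the mean
Gaussian negative log-likelihood

    L(y, mu, sigma) = 1/2 log(2 pi sigma^2) + (y - mu)^2 / (2 sigma^2)

with Adam.  The implementation is pure NumPy — forward pass and
backpropagation through time are written out explicitly — so training is
deterministic under a fixed seed and has no framework dependency; the
analytic gradients are validated against finite differences in the test
suite.

95% predictive intervals are mu_t +/- 1.96 sigma_t, reported on the raw
prevalence scale (inputs are standardized by train-split statistics and
predictions de-standardized).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .interventions import DesignMatrix
from .weekly import WeeklySeries


def softplus(x):
    """Overflow-safe softplus log(1 + e^x) (elementwise)."""
    x = np.asarray(x, dtype=float)
    out = np.where(x > 0, x + np.log1p(np.exp(-np.abs(x))), np.log1p(np.exp(np.minimum(x, 0))))
    return out if out.ndim else float(out)


def gaussian_nll(y, mu, sigma):
    """Gaussian negative log-likelihood; mean over elements for arrays."""
    y, mu, sigma = np.asarray(y, float), np.asarray(mu, float), np.asarray(sigma, float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    val = 0.5 * np.log(2 * np.pi * sigma ** 2) + (y - mu) ** 2 / (2 * sigma ** 2)
    return float(np.mean(val))


def rmse(predicted, observed) -> float:
    """Root mean squared error between two equal-length vectors."""
    p, o = np.asarray(predicted, float), np.asarray(observed, float)
    if p.shape != o.shape or p.size == 0:
        raise ValueError("predicted and observed must be non-empty and equal-length")
    return float(np.sqrt(np.mean((p - o) ** 2)))


@dataclass
class LstmConfig:
    """Hyper-parameters of the mean-variance LSTM."""

    window: int = 12
    learning_rate: float = 0.001
    epochs: int = 10
    hidden_units: int = 32
    layers: int = 1
    train_fraction: float = 0.8
    batch_size: int = 4
    seed: int = 0
    optimizer: str = "adam"
    sigma_floor: float = 1e-6

    def __post_init__(self):
        if self.window < 1:
            raise ValueError("window must be at least 1")
        if self.epochs < 1:
            raise ValueError("epochs must be at least 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.layers < 1:
            raise ValueError("layers must be positive")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer: {self.optimizer!r}")


@dataclass
class WindowedDataset:
    """Chronological sliding windows over a weekly series + design.

    ``inputs`` has shape (n_samples, window, n_features) with the
    standardized prevalence as feature 0 and the intervention indicators
    after it; ``targets`` (standardized) is the following week's value.
    Train windows strictly precede test windows.
    """

    inputs: np.ndarray
    targets: np.ndarray
    target_weeks: np.ndarray          # 0-based week index of each target
    split: int                        # first test-sample index
    mean: float                       # train-split standardization stats
    sd: float
    raw_targets: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.inputs.shape[0]

    def train_arrays(self):
        return self.inputs[: self.split], self.targets[: self.split]

    def test_arrays(self):
        return self.inputs[self.split:], self.targets[self.split:]


def make_windows(
    series: WeeklySeries,
    design: DesignMatrix | None,
    config: LstmConfig,
) -> WindowedDataset:
    """Build the windowed dataset (n - window samples, chronological split)."""
    z = np.asarray(series.values, dtype=float)
    n = z.size
    w = config.window
    if n <= w:
        raise ValueError(f"series of {n} weeks is too short for window {w}")
    if np.isnan(z).any():
        raise ValueError("series has missing weeks; fill or interpolate first")
    if design is not None:
        if design.n_weeks != n:
            raise ValueError("design matrix must align with the series calendar")
        feats = np.column_stack([z, design.matrix])
    else:
        feats = z[:, None]

    n_samples = n - w
    split = int(np.floor(config.train_fraction * n_samples))
    mean = float(z[: split + w].mean())     # stats from weeks seen by training
    sd = float(z[: split + w].std())
    if sd == 0:
        sd = 1.0
    feats = feats.copy()
    feats[:, 0] = (feats[:, 0] - mean) / sd

    inputs = np.stack([feats[i:i + w] for i in range(n_samples)])
    raw_targets = z[w:]
    targets = (raw_targets - mean) / sd
    return WindowedDataset(
        inputs=inputs,
        targets=targets,
        target_weeks=np.arange(w, n),
        split=split,
        mean=mean,
        sd=sd,
        raw_targets=raw_targets,
    )


@dataclass
class ForecastDistribution:
    """Per-week predictive Gaussian on the raw prevalence scale."""

    target_weeks: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        if np.any(self.sigma <= 0):
            raise ValueError("predicted sigma must be strictly positive")

    @property
    def lower(self) -> np.ndarray:
        return self.mu - 1.96 * self.sigma

    @property
    def upper(self) -> np.ndarray:
        return self.mu + 1.96 * self.sigma

    def coverage(self, observed: np.ndarray) -> float:
        o = np.asarray(observed, float)
        return float(np.mean((o >= self.lower) & (o <= self.upper)))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class MeanVarianceLSTM:
    """Stacked LSTM with linear mean and Softplus variance heads.

    Weights follow the usual uniform(-1/sqrt(H), 1/sqrt(H)) initialization.
    Gate layout within the packed matrices is [input, forget, cell, output].
    """

    def __init__(self, n_features: int, config: LstmConfig):
        self.config = config
        H = config.hidden_units
        rng = np.random.default_rng(config.seed)
        k = 1.0 / np.sqrt(H)
        self.params: dict[str, np.ndarray] = {}
        f_in = n_features
        for layer in range(config.layers):
            self.params[f"Wx{layer}"] = rng.uniform(-k, k, (f_in, 4 * H))
            self.params[f"Wh{layer}"] = rng.uniform(-k, k, (H, 4 * H))
            self.params[f"b{layer}"] = rng.uniform(-k, k, 4 * H)
            f_in = H
        self.params["Wm"] = rng.uniform(-k, k, (H, 1))
        self.params["bm"] = rng.uniform(-k, k, 1)
        self.params["Wv"] = rng.uniform(-k, k, (H, 1))
        self.params["bv"] = rng.uniform(-k, k, 1)
        self._adam_m = {kk: np.zeros_like(v) for kk, v in self.params.items()}
        self._adam_v = {kk: np.zeros_like(v) for kk, v in self.params.items()}
        self._adam_t = 0

    # ---------------------------------------------------------------- forward
    def _forward(self, x: np.ndarray, keep_cache: bool = False):
        """x: (B, T, F) -> (mu, var, cache). mu/var are (B,)."""
        B, T, _ = x.shape
        H = self.config.hidden_units
        seq = x
        caches = []
        for layer in range(self.config.layers):
            Wx, Wh, b = (self.params[f"Wx{layer}"], self.params[f"Wh{layer}"],
                         self.params[f"b{layer}"])
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            steps = []
            hs = np.empty((B, T, H))
            for t in range(T):
                a = seq[:, t] @ Wx + h @ Wh + b
                i = _sigmoid(a[:, :H])
                f = _sigmoid(a[:, H:2 * H])
                g = np.tanh(a[:, 2 * H:3 * H])
                o = _sigmoid(a[:, 3 * H:])
                c_prev, h_prev = c, h
                c = f * c_prev + i * g
                tc = np.tanh(c)
                h = o * tc
                hs[:, t] = h
                if keep_cache:
                    steps.append((seq[:, t], h_prev, c_prev, i, f, g, o, tc))
            caches.append((steps, seq))
            seq = hs
        hT = seq[:, -1]
        mu = (hT @ self.params["Wm"] + self.params["bm"])[:, 0]
        s = (hT @ self.params["Wv"] + self.params["bv"])[:, 0]
        var = softplus(s) + self.config.sigma_floor
        cache = (caches, hT, s, x.shape) if keep_cache else None
        return mu, var, cache

    def predict(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Standardized-scale (mu, sigma) for inputs of shape (B, T, F)."""
        mu, var, _ = self._forward(np.asarray(x, float))
        return mu, np.sqrt(var)

    # --------------------------------------------------------------- backward
    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Mean Gaussian NLL over the batch and gradients for all params."""
        mu, var, cache = self._forward(x, keep_cache=True)
        caches, hT, s, (B, T, F) = cache
        H = self.config.hidden_units
        loss = float(np.mean(0.5 * np.log(2 * np.pi * var) + (y - mu) ** 2 / (2 * var)))

        grads = {kk: np.zeros_like(v) for kk, v in self.params.items()}
        dmu = (mu - y) / var / B
        dvar = 0.5 * (1.0 / var - (y - mu) ** 2 / var ** 2) / B
        ds = dvar * _sigmoid(s)     # d softplus
        grads["Wm"] = hT.T @ dmu[:, None]
        grads["bm"] = np.array([dmu.sum()])
        grads["Wv"] = hT.T @ ds[:, None]
        grads["bv"] = np.array([ds.sum()])
        dh_top = dmu[:, None] @ self.params["Wm"].T + ds[:, None] @ self.params["Wv"].T

        # gradient w.r.t. the top layer's output sequence: only final step
        dseq = np.zeros((B, T, H))
        dseq[:, -1] = dh_top
        for layer in reversed(range(self.config.layers)):
            steps, seq_in = caches[layer]
            Wx, Wh = self.params[f"Wx{layer}"], self.params[f"Wh{layer}"]
            dWx = np.zeros_like(Wx)
            dWh = np.zeros_like(Wh)
            db = np.zeros_like(self.params[f"b{layer}"])
            f_in = seq_in.shape[2]
            dseq_below = np.zeros((B, T, f_in))
            dh = np.zeros((B, H))
            dc = np.zeros((B, H))
            for t in reversed(range(T)):
                x_t, h_prev, c_prev, i, f, g, o, tc = steps[t]
                dh = dh + dseq[:, t]
                do = dh * tc
                dc = dc + dh * o * (1 - tc ** 2)
                di = dc * g
                dg = dc * i
                df = dc * c_prev
                dc = dc * f
                da = np.concatenate(
                    [di * i * (1 - i), df * f * (1 - f), dg * (1 - g ** 2), do * o * (1 - o)],
                    axis=1,
                )
                dWx += x_t.T @ da
                dWh += h_prev.T @ da
                db += da.sum(axis=0)
                dseq_below[:, t] = da @ Wx.T
                dh = da @ Wh.T
            grads[f"Wx{layer}"] = dWx
            grads[f"Wh{layer}"] = dWh
            grads[f"b{layer}"] = db
            dseq = dseq_below
        return loss, grads

    def adam_step(self, grads: dict[str, np.ndarray]) -> None:
        cfg = self.config
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for kk, g in grads.items():
            self._adam_m[kk] = b1 * self._adam_m[kk] + (1 - b1) * g
            self._adam_v[kk] = b2 * self._adam_v[kk] + (1 - b2) * g ** 2
            mhat = self._adam_m[kk] / (1 - b1 ** self._adam_t)
            vhat = self._adam_v[kk] / (1 - b2 ** self._adam_t)
            self.params[kk] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    train_mse: list[float] = field(default_factory=list)
    test_mse: list[float] = field(default_factory=list)

    def best_epoch(self) -> int:
        """1-based epoch with minimum test MSE (for epoch selection)."""
        return int(np.argmin(self.test_mse)) + 1


def _raw_mse(model: MeanVarianceLSTM, x, y_std, mean, sd) -> float:
    mu, _ = model.predict(x)
    return float(np.mean(((mu - y_std) * sd) ** 2))


def train(
    dataset: WindowedDataset, config: LstmConfig
) -> tuple[MeanVarianceLSTM, TrainingHistory]:
    """Train the mean-variance LSTM for the configured number of epochs.

    Each epoch is one full pass over the training windows in seeded random
    order, updating after every ``batch_size`` windows with Adam.  Per
    epoch, the mean squared error between predicted means and the ground
    truth (raw prevalence scale, pp^2) is recorded for the train and test
    partitions for epoch selection.
    """
    x_tr, y_tr = dataset.train_arrays()
    x_te, y_te = dataset.test_arrays()
    if x_tr.shape[0] == 0 or x_te.shape[0] == 0:
        raise ValueError("train and test partitions must both be non-empty")
    model = MeanVarianceLSTM(n_features=dataset.inputs.shape[2], config=config)
    rng = np.random.default_rng(config.seed + 1)
    hist = TrainingHistory()
    n = x_tr.shape[0]
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            loss, grads = model.loss_and_grads(x_tr[idx], y_tr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "training loss became non-finite; lower the learning rate "
                    "or standardize the inputs"
                )
            model.adam_step(grads)
            epoch_losses.append(loss)
        hist.train_loss.append(float(np.mean(epoch_losses)))
        hist.train_mse.append(_raw_mse(model, x_tr, y_tr, dataset.mean, dataset.sd))
        hist.test_mse.append(_raw_mse(model, x_te, y_te, dataset.mean, dataset.sd))
    return model, hist


def predict_distribution(
    model: MeanVarianceLSTM, dataset: WindowedDataset
) -> ForecastDistribution:
    """Predictive mean/scale for every constructible window, raw scale."""
    mu_std, sigma_std = model.predict(dataset.inputs)
    return ForecastDistribution(
        target_weeks=dataset.target_weeks,
        mu=mu_std * dataset.sd + dataset.mean,
        sigma=np.maximum(sigma_std * dataset.sd, 1e-12),
    )
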