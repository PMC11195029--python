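"""Fixed-length vector embeddings of variable-length event traces.

Three routes of increasing complexity:

* :func:`extract_features` — a frozen, documented list of 14 summary
  statistics; length-agnostic and training-free;
* :class:`CnnAutoencoder` — a strided 1D-convolutional encoder/decoder for
  fixed-length traces;
* :class:`RnnAutoencoder` — a GRU encoder/decoder over padded-and-masked
  batches, accepting ragged inputs.

Both autoencoders compress to ``latent_dim`` and are trained with Adam on a
mean-squared reconstruction loss; padding never contributes to the RNN loss.
Normalization is the caller's responsibility (see the events module) — the
encoders never re-normalize.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew

from . import _nn
from .errors import ValidationError

FEATURE_NAMES = [
    "mean", "median", "std", "min", "max", "range",
    "argmax_fraction", "auc_per_frame", "skewness", "kurtosis",
    "entropy", "length", "n_local_maxima", "mean_abs_diff",
]


def _trace_features(trace: np.ndarray) -> np.ndarray:
    rng = float(trace.max() - trace.min())
    if rng > 0:
        hist, _ = np.histogram(trace, bins=16)
        p = hist[hist > 0] / len(trace)
        entropy = float(-np.sum(p * np.log2(p)))
        skewness = float(_skew(trace))
        kurt = float(_kurtosis(trace))
        n_max = len(find_peaks(trace, prominence=0.1 * rng)[0])
    else:
        entropy = skewness = kurt = 0.0
        n_max = 0
    return np.array(
        [
            trace.mean(),
            np.median(trace),
            trace.std(),
            trace.min(),
            trace.max(),
            rng,
            np.argmax(trace) / len(trace),
            np.trapezoid(trace) / len(trace),
            skewness,
            kurt,
            entropy,
            len(trace),
            n_max,
            np.abs(np.diff(trace)).mean() if len(trace) > 1 else 0.0,
        ]
    )


def extract_features(
    table: Union[pd.DataFrame, Sequence[np.ndarray]], dropna: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Per-event feature matrix over the frozen 14-feature list.

    Accepts an event table (uses its ``trace`` column) or a plain sequence of
    traces.  With ``dropna`` rows containing any non-finite feature are
    removed.  Returns ``(matrix, feature_names)``.
    """
    traces = table["trace"] if isinstance(table, pd.DataFrame) else table
    rows = []
    for tr in traces:
        tr = np.asarray(tr, dtype=float)
        if tr.size == 0:
            raise ValidationError("zero-length trace")
        rows.append(_trace_features(tr))
    matrix = np.vstack(rows)
    if dropna:
        matrix = matrix[np.all(np.isfinite(matrix), axis=1)]
    return matrix, list(FEATURE_NAMES)


def split_dataset(
    data: Sequence, val_size: float = 0.1, test_size: float = 0.05, seed: int = 0
) -> tuple[list, list, list]:
    """Deterministic shuffled (train, val, test) split by fractions."""
    if not (0 < val_size < 1 and 0 < test_size < 1 and val_size + test_size < 1):
        raise ValidationError("fractions must be in (0,1) and sum to < 1")
    n = len(data)
    n_val = round(n * val_size)
    n_test = round(n * test_size)
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValidationError(f"n={n} too small for the requested splits")
    order = np.random.default_rng(seed).permutation(n)
    as_list = [data[i] for i in order]
    return (
        as_list[:n_train],
        as_list[n_train : n_train + n_val],
        as_list[n_train + n_val :],
    )


@dataclass
class AutoencoderSpec:
    kind: str = "cnn"  # cnn | rnn
    latent_dim: int = 16
    epochs: int = 25
    learning_rate: float = 1e-3
    batch_size: int = 16
    patience: int = 10
    hidden_dim: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("cnn", "rnn"):
            raise ValidationError("kind must be 'cnn' or 'rnn'")
        if self.latent_dim < 1:
            raise ValidationError("latent_dim must be >= 1")


def _is_ragged(traces: Sequence) -> bool:
    lengths = {len(t) for t in traces}
    return len(lengths) > 1


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


class CnnAutoencoder:
    """Strided conv1d encoder with a mirrored upsample/conv decoder.

    Architecture: conv(1->32, k5, s2) - conv(32->64, k5, s2) - dense to the
    latent; the decoder mirrors it with nearest-neighbour upsampling.  Input
    length is padded internally to a multiple of 4.
    """

    def __init__(self, target_length: int, spec: AutoencoderSpec):
        self.spec = spec
        self.target_length = int(target_length)
        self.padded = -(-self.target_length // 4) * 4
        rng = np.random.default_rng(spec.seed)
        mid = 64 * (self.padded // 4)
        self.params = {
            "w1": _nn.parameter((32, 1, 5), rng),
            "b1": _nn.zeros(32),
            "w2": _nn.parameter((64, 32, 5), rng),
            "b2": _nn.zeros(64),
            "we": _nn.parameter((mid, spec.latent_dim), rng),
            "be": _nn.zeros(spec.latent_dim),
            "wd": _nn.parameter((spec.latent_dim, mid), rng),
            "bd": _nn.zeros(mid),
            "w3": _nn.parameter((32, 64, 5), rng),
            "b3": _nn.zeros(32),
            "w4": _nn.parameter((1, 32, 5), rng),
            "b4": _nn.zeros(1),
        }
        self.history: list[dict] = []

    # -- graph -------------------------------------------------------------
    def _pad(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.target_length:
            raise ValidationError(
                f"CNN autoencoder expects length {self.target_length}, "
                f"got {x.shape[1]}"
            )
        return np.pad(x, ((0, 0), (0, self.padded - self.target_length)))

    def _encode_graph(self, x: _nn.Tensor) -> _nn.Tensor:
        p = self.params
        h = _nn.conv1d(x, p["w1"], p["b1"], stride=2, pad=2).relu()
        h = _nn.conv1d(h, p["w2"], p["b2"], stride=2, pad=2).relu()
        flat = h.reshape(h.data.shape[0], -1)
        return flat @ p["we"] + p["be"]

    def _decode_graph(self, z: _nn.Tensor, batch: int) -> _nn.Tensor:
        p = self.params
        h = (z @ p["wd"] + p["bd"]).relu().reshape(batch, 64, self.padded // 4)
        h = _nn.conv1d(_nn.upsample2(h), p["w3"], p["b3"], stride=1, pad=2).relu()
        return _nn.conv1d(_nn.upsample2(h), p["w4"], p["b4"], stride=1, pad=2)

    def _loss(self, batch: np.ndarray) -> _nn.Tensor:
        x = _nn.Tensor(self._pad(batch)[:, None, :])
        recon = self._decode_graph(self._encode_graph(x), batch.shape[0])
        return (recon - x).square().mean()

    # -- API ---------------------------------------------------------------
    def fit(
        self, X_train: np.ndarray, X_val: Optional[np.ndarray] = None
    ) -> list[dict]:
        X_train = np.asarray(X_train, dtype=float)
        rng = np.random.default_rng(self.spec.seed + 1)
        opt = _nn.Adam(self.params.values(), lr=self.spec.learning_rate)
        for epoch in range(self.spec.epochs):
            losses = []
            for idx in _batches(len(X_train), self.spec.batch_size, rng):
                loss = self._loss(X_train[idx])
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if X_val is not None and len(X_val):
                entry["val_loss"] = float(self._loss(np.asarray(X_val, float)).data)
            self.history.append(entry)
        return self.history

    def encode(self, traces: np.ndarray) -> np.ndarray:
        traces = np.asarray(traces, dtype=float)
        x = _nn.Tensor(self._pad(traces)[:, None, :])
        return self._encode_graph(x).data

    def reconstruct(self, traces: np.ndarray) -> np.ndarray:
        traces = np.asarray(traces, dtype=float)
        x = _nn.Tensor(self._pad(traces)[:, None, :])
        out = self._decode_graph(self._encode_graph(x), traces.shape[0])
        return out.data[:, 0, : self.target_length]

    def save(self, path) -> None:
        np.savez(
            path,
            kind="cnn",
            target_length=self.target_length,
            latent_dim=self.spec.latent_dim,
            seed=self.spec.seed,
            **{k: v.data for k, v in self.params.items()},
        )

    @classmethod
    def load(cls, path) -> "CnnAutoencoder":
        blob = np.load(path, allow_pickle=False)
        spec = AutoencoderSpec(
            kind="cnn", latent_dim=int(blob["latent_dim"]), seed=int(blob["seed"])
        )
        model = cls(int(blob["target_length"]), spec)
        for k in model.params:
            model.params[k].data = blob[k]
        return model


def _gru_params(rng, in_dim, hidden):
    p = {}
    for gate in ("z", "r", "n"):
        p[f"wx{gate}"] = _nn.parameter((in_dim, hidden), rng)
        p[f"wh{gate}"] = _nn.parameter((hidden, hidden), rng)
        p[f"b{gate}"] = _nn.zeros(hidden)
    return p


def _gru_step(p, prefix, x, h):
    z = (x @ p[prefix + "wxz"] + h @ p[prefix + "whz"] + p[prefix + "bz"]).sigmoid()
    r = (x @ p[prefix + "wxr"] + h @ p[prefix + "whr"] + p[prefix + "br"]).sigmoid()
    n = (x @ p[prefix + "wxn"] + (r * (h @ p[prefix + "whn"])) + p[prefix + "bn"]).tanh()
    return (1.0 - z) * h + z * n


def pad_ragged(traces: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Zero-pad ragged traces to (N, T_max); returns (padded, mask)."""
    lengths = [len(t) for t in traces]
    Tm = max(lengths)
    out = np.zeros((len(traces), Tm))
    mask = np.zeros((len(traces), Tm))
    for i, t in enumerate(traces):
        out[i, : len(t)] = np.asarray(t, dtype=float)
        mask[i, : len(t)] = 1.0
    return out, mask


class RnnAutoencoder:
    """GRU encoder/decoder over padded, masked batches (ragged-friendly).

    The encoder's hidden state is frozen past each sequence's end, so the
    latent depends only on real frames; decoder reconstruction errors at
    padded positions are masked out of the loss.  Early stopping keeps the
    best validation checkpoint (``patience`` non-improving epochs).
    """

    def __init__(self, spec: AutoencoderSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        H, Z = spec.hidden_dim, spec.latent_dim
        self.params = {}
        for k, v in _gru_params(rng, 1, H).items():
            self.params["enc_" + k] = v
        for k, v in _gru_params(rng, 1, H).items():
            self.params["dec_" + k] = v
        self.params.update(
            {
                "w_lat": _nn.parameter((H, Z), rng),
                "b_lat": _nn.zeros(Z),
                "w_h0": _nn.parameter((Z, H), rng),
                "b_h0": _nn.zeros(H),
                "w_out": _nn.parameter((H, 1), rng),
                "b_out": _nn.zeros(1),
            }
        )
        self.history: list[dict] = []

    def _encode_graph(self, padded: np.ndarray, mask: np.ndarray) -> _nn.Tensor:
        B, T = padded.shape
        h = _nn.Tensor(np.zeros((B, self.spec.hidden_dim)))
        for t in range(T):
            x_t = _nn.Tensor(padded[:, t : t + 1])
            m_t = _nn.Tensor(mask[:, t : t + 1])
            h_new = _gru_step(self.params, "enc_", x_t, h)
            h = m_t * h_new + (1.0 - m_t) * h  # freeze after sequence end
        return h @ self.params["w_lat"] + self.params["b_lat"]

    def _decode_graph(self, z: _nn.Tensor, T: int) -> list[_nn.Tensor]:
        h = (z @ self.params["w_h0"] + self.params["b_h0"]).tanh()
        zero_in = _nn.Tensor(np.zeros((z.data.shape[0], 1)))
        outputs = []
        for _ in range(T):
            h = _gru_step(self.params, "dec_", zero_in, h)
            outputs.append(h @ self.params["w_out"] + self.params["b_out"])
        return outputs

    def batch_loss(self, traces: Sequence[np.ndarray]) -> _nn.Tensor:
        """Masked MSE: summed squared error over real frames / frame count."""
        padded, mask = pad_ragged(traces)
        z = self._encode_graph(padded, mask)
        outputs = self._decode_graph(z, padded.shape[1])
        total = None
        for t, y_t in enumerate(outputs):
            m_t = _nn.Tensor(mask[:, t : t + 1])
            x_t = _nn.Tensor(padded[:, t : t + 1])
            sq = (m_t * (y_t - x_t)).square().sum()
            total = sq if total is None else total + sq
        return total / mask.sum()

    def fit(
        self,
        traces: Sequence[np.ndarray],
        val_traces: Optional[Sequence[np.ndarray]] = None,
    ) -> list[dict]:
        traces = [np.asarray(t, dtype=float) for t in traces]
        if any(len(t) < 2 for t in traces):
            raise ValidationError("all traces must have length >= 2")
        rng = np.random.default_rng(self.spec.seed + 1)
        opt = _nn.Adam(self.params.values(), lr=self.spec.learning_rate)
        best_val = np.inf
        best_state = None
        stale = 0
        for epoch in range(self.spec.epochs):
            losses = []
            for idx in _batches(len(traces), self.spec.batch_size, rng):
                loss = self.batch_loss([traces[i] for i in idx])
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            monitor = entry["train_loss"]
            if val_traces:
                entry["val_loss"] = float(self.batch_loss(val_traces).data)
                monitor = entry["val_loss"]
            self.history.append(entry)
            if monitor < best_val - 1e-12:
                best_val = monitor
                best_state = {k: v.data.copy() for k, v in self.params.items()}
                stale = 0
            else:
                stale += 1
                if stale >= self.spec.patience:
                    break
        if best_state is not None:  # retain the best checkpoint
            for k, v in best_state.items():
                self.params[k].data = v
        return self.history

    def encode(self, traces: Sequence[np.ndarray]) -> np.ndarray:
        padded, mask = pad_ragged([np.asarray(t, dtype=float) for t in traces])
        return self._encode_graph(padded, mask).data

    def save(self, path) -> None:
        np.savez(
            path,
            kind="rnn",
            latent_dim=self.spec.latent_dim,
            hidden_dim=self.spec.hidden_dim,
            seed=self.spec.seed,
            **{k: v.data for k, v in self.params.items()},
        )

    @classmethod
    def load(cls, path) -> "RnnAutoencoder":
        blob = np.load(path, allow_pickle=False)
        spec = AutoencoderSpec(
            kind="rnn",
            latent_dim=int(blob["latent_dim"]),
            hidden_dim=int(blob["hidden_dim"]),
            seed=int(blob["seed"]),
        )
        model = cls(spec)
        for k in model.params:
            model.params[k].data = blob[k]
        return model


def train_cnn_autoencoder(
    traces: Sequence[np.ndarray],
    spec: Optional[AutoencoderSpec] = None,
    val_traces: Optional[np.ndarray] = None,
) -> tuple[CnnAutoencoder, list[dict]]:
    """Train the fixed-length CNN autoencoder; ragged input is an error."""
    spec = spec or AutoencoderSpec(kind="cnn")
    if _is_ragged(traces):
        raise ValidationError(
            "CNN autoencoder requires fixed-length traces; enforce a length first"
        )
    X = np.asarray([np.asarray(t, dtype=float) for t in traces])
    model = CnnAutoencoder(X.shape[1], spec)
    history = model.fit(X, val_traces)
    return model, history


def train_rnn_autoencoder(
    traces: Sequence[np.ndarray],
    spec: Optional[AutoencoderSpec] = None,
    val_traces: Optional[Sequence[np.ndarray]] = None,
) -> tuple[RnnAutoencoder, list[dict]]:
    """Train the ragged-friendly GRU autoencoder."""
    spec = spec or AutoencoderSpec(kind="rnn")
    model = RnnAutoencoder(spec)
    history = model.fit(list(traces), val_traces)
    return model, history


def encode(handle, traces) -> np.ndarray:
    """Row-order-preserving latent matrix from a trained encoder handle."""
    return handle.encode(traces)
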