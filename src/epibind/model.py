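"""The fully connected sequence-binding regressor.

A 2-hidden-layer, 250-node network maps a one-hot framed peptide (247
inputs unshifted, 342 with register shifting) to log10 binding at the
four assay concentrations simultaneously (4 outputs).  Trained with Adam
on a (weighted) mean-squared-error loss; the network is small enough that
training and million-sequence prediction run on one CPU in numpy.

Three dataset transformations are controlled by ablation flags, applied
cumulatively in the order used throughout: ``weighting`` (high-binder
multiplicities as per-example loss weights), ``shifting`` (each training
pair expanded to 6 register-shifted frames with shared targets; at
prediction time every query is submitted in all 6 frames and the highest
predicted value per concentration is kept), and ``composition`` (an OLS
composition model is fitted on the training set, its prediction
subtracted from the targets, and added back at prediction time so outputs
stay on the total log10-binding scale).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import encoding
from .array_io import BindingTable
from .preprocess import (
    CompositionModel,
    WeightingConfig,
    fit_composition,
    predict_composition,
    weight_expand,
)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture, ablation flags and training hyperparameters."""

    hidden_layers: int = 2
    nodes_per_layer: int = 250
    output_dim: int = 4
    weighting: bool = False
    shifting: bool = False
    composition: bool = False
    composition_pooled: bool = False
    weighting_config: WeightingConfig = field(default_factory=WeightingConfig)
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 128
    #: "per_concentration": frame maximum taken independently per output;
    #: "per_sequence": one argmax frame (highest value at any output)
    #: supplies all four outputs
    frame_aggregate: str = "per_concentration"
    seed: int = 0

    @property
    def input_width(self) -> int:
        return encoding.input_width(self.shifting)

    def with_ablation(self, name: str) -> "ModelConfig":
        """Cumulative ablation ladder: baseline -> +weighting -> +shifting -> +composition."""
        from dataclasses import replace

        flags = {
            "baseline": dict(weighting=False, shifting=False, composition=False),
            "+weighting": dict(weighting=True, shifting=False, composition=False),
            "+shifting": dict(weighting=True, shifting=True, composition=False),
            "+composition": dict(weighting=True, shifting=True, composition=True),
        }
        return replace(self, **flags[name])


ABLATION_LADDER = ("baseline", "+weighting", "+shifting", "+composition")


class _MLP:
    """Minimal dense ReLU network with Adam and weighted MSE."""

    def __init__(self, sizes: list[int], rng: np.random.Generator) -> None:
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.weights.append(rng.normal(0, scale, (fan_in, fan_out)).astype(np.float32))
            self.biases.append(np.zeros(fan_out, dtype=np.float32))

    def forward(self, x: np.ndarray) -> np.ndarray:
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            x = np.maximum(x @ w + b, 0.0)
        return x @ self.weights[-1] + self.biases[-1]

    def train_step(self, x, y, sample_weight, adam_state, lr, t):
        acts = [x]
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            acts.append(np.maximum(acts[-1] @ w + b, 0.0))
        pred = acts[-1] @ self.weights[-1] + self.biases[-1]
        wsum = sample_weight.sum()
        delta = (pred - y) * (sample_weight[:, None] / wsum) * (2.0 / y.shape[1])
        loss = float(((pred - y) ** 2).mean(axis=1) @ sample_weight / wsum)
        grads_w, grads_b = [], []
        for layer in range(len(self.weights) - 1, -1, -1):
            grads_w.append(acts[layer].T @ delta)
            grads_b.append(delta.sum(axis=0))
            if layer > 0:
                delta = (delta @ self.weights[layer].T) * (acts[layer] > 0)
        grads_w.reverse()
        grads_b.reverse()
        b1, b2, eps = 0.9, 0.999, 1e-8
        params = self.weights + self.biases
        grads = grads_w + grads_b
        for p, g, (m, v) in zip(params, grads, adam_state):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)
        return loss

    def init_adam(self):
        return [
            (np.zeros_like(p), np.zeros_like(p)) for p in self.weights + self.biases
        ]


@dataclass
class BindingModel:
    """Trained network plus its encoding/ablation configuration."""

    config: ModelConfig
    net: _MLP
    composition_model: CompositionModel | None = None
    concentrations: tuple[float, ...] = (0.125, 0.5, 2.0, 8.0)
    final_loss: float | None = None
    #: weighted column means of the training targets; the network is fit on
    #: centered targets and this offset is added back at prediction
    output_offset: np.ndarray | None = None

    # ------------------------------------------------------------ predict

    def forward_tokens(self, tokens: np.ndarray, group: np.ndarray) -> np.ndarray:
        """Raw network output aggregated per peptide (frame-max per
        concentration when shifting is on); no composition add-back."""
        out_rows = _forward_chunked(self.net, tokens)
        if self.output_offset is not None:
            out_rows = out_rows + self.output_offset.astype(np.float32)
        n_pep = int(group.max()) + 1 if len(group) else 0
        if not self.config.shifting:
            return out_rows
        if self.config.frame_aggregate == "per_sequence":
            row_best = out_rows.max(axis=1)
            best = np.full(n_pep, -np.inf, dtype=np.float32)
            np.maximum.at(best, group, row_best)
            agg = np.zeros((n_pep, out_rows.shape[1]), dtype=np.float32)
            assigned = np.zeros(n_pep, dtype=bool)
            for i in range(len(group)):  # first frame achieving the max wins
                g = group[i]
                if not assigned[g] and row_best[i] == best[g]:
                    agg[g] = out_rows[i]
                    assigned[g] = True
            return agg
        agg = np.full((n_pep, out_rows.shape[1]), -np.inf, dtype=np.float32)
        np.maximum.at(agg, group, out_rows)
        return agg

    def predict(
        self, sequences: list[str], add_composition_back: bool = True
    ) -> np.ndarray:
        """Log10 binding, peptides x concentrations (batch, vectorized)."""
        tokens, group = encoding.encode_batch(sequences, shifted=self.config.shifting)
        out = self.forward_tokens(tokens, group).astype(float)
        if self.config.composition and add_composition_back and self.composition_model:
            out = out + predict_composition(self.composition_model, sequences)
        return out

    # ---------------------------------------------------------------- io

    def save(self, path) -> None:
        path = Path(path)
        arrays = {f"w{i}": w for i, w in enumerate(self.net.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.net.biases)})
        if self.output_offset is not None:
            arrays["output_offset"] = self.output_offset
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {
            "config": _config_dict(self.config),
            "token_order": encoding.TOKENS,
            "concentrations": list(self.concentrations),
            "final_loss": self.final_loss,
            "composition_model": None
            if self.composition_model is None
            else json.loads(self.composition_model.to_json()),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "BindingModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfgd = meta["config"]
        cfgd["weighting_config"] = WeightingConfig(**cfgd["weighting_config"])
        cfg = ModelConfig(**cfgd)
        arrs = np.load(path.with_suffix(".npz"))
        n_layers = cfg.hidden_layers + 1
        net = _MLP.__new__(_MLP)
        net.weights = [arrs[f"w{i}"] for i in range(n_layers)]
        net.biases = [arrs[f"b{i}"] for i in range(n_layers)]
        comp = meta["composition_model"]
        return cls(
            config=cfg,
            net=net,
            composition_model=None
            if comp is None
            else CompositionModel.from_json(json.dumps(comp)),
            concentrations=tuple(meta["concentrations"]),
            final_loss=meta["final_loss"],
            output_offset=arrs["output_offset"] if "output_offset" in arrs else None,
        )


def _config_dict(cfg: ModelConfig) -> dict:
    d = asdict(cfg)
    return d


def _forward_chunked(net: _MLP, tokens: np.ndarray, chunk: int = 8192) -> np.ndarray:
    width = tokens.shape[1] * encoding.N_TOKENS
    outs = []
    for start in range(0, len(tokens), chunk):
        block = tokens[start : start + chunk]
        x = np.zeros((len(block), width), dtype=np.float32)
        cols = block.astype(np.int64) + np.arange(block.shape[1]) * encoding.N_TOKENS
        x[np.arange(len(block))[:, None], cols] = 1.0
        outs.append(net.forward(x))
    return np.vstack(outs) if outs else np.empty((0, net.biases[-1].shape[0]), np.float32)


def train(table: BindingTable, cfg: ModelConfig) -> BindingModel:
    """Fit one network on a prepared binding table.

    The table must already be averaged, saturation-corrected,
    length-filtered and cognate-excluded.  Weighting multiplicities are
    computed from the reference (highest) concentration column; when
    composition is on, the network is trained on residual targets.
    """
    rng = np.random.default_rng(cfg.seed)
    targets = table.values.astype(np.float32)
    comp_model = None
    if cfg.composition:
        comp_model = fit_composition(
            table.sequences, table.values, pooled=cfg.composition_pooled
        )
        targets = (table.values - predict_composition(comp_model, table.sequences)).astype(
            np.float32
        )

    if cfg.weighting:
        ref_col = int(
            np.argmin(
                np.abs(
                    np.asarray(table.concentrations)
                    - cfg.weighting_config.reference_concentration
                )
            )
        )
        mult = weight_expand(table.values[:, ref_col], cfg.weighting_config).astype(
            np.float32
        )
    else:
        mult = np.ones(len(table), dtype=np.float32)

    tokens, group = encoding.encode_batch(table.sequences, shifted=cfg.shifting)
    y = targets[group]
    w = mult[group]
    offset = (w @ y) / w.sum()
    y = y - offset

    sizes = [cfg.input_width] + [cfg.nodes_per_layer] * cfg.hidden_layers + [cfg.output_dim]
    net = _MLP(sizes, rng)
    adam = net.init_adam()
    n = len(tokens)
    width = tokens.shape[1] * encoding.N_TOKENS
    col_offsets = np.arange(tokens.shape[1]) * encoding.N_TOKENS
    t = 0
    loss = float("nan")
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            block = tokens[sel]
            x = np.zeros((len(sel), width), dtype=np.float32)
            x[np.arange(len(sel))[:, None], block.astype(np.int64) + col_offsets] = 1.0
            t += 1
            with np.errstate(over="ignore", invalid="ignore"):
                loss = net.train_step(x, y[sel], w[sel], adam, cfg.learning_rate, t)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training loss became non-finite at step {t} (lr={cfg.learning_rate})"
                )
    return BindingModel(
        config=cfg,
        net=net,
        composition_model=comp_model,
        concentrations=table.concentrations,
        final_loss=loss,
        output_offset=offset.astype(np.float64),
    )


class Ensemble:
    """Mean-of-members prediction over independently seeded trainings."""

    def __init__(self, models: list[BindingModel]):
        if not models:
            raise ValueError("empty ensemble")
        self.models = models

    @property
    def config(self) -> ModelConfig:
        return self.models[0].config

    def predict(self, sequences: list[str], add_composition_back: bool = True) -> np.ndarray:
        tokens, group = encoding.encode_batch(
            sequences, shifted=self.config.shifting
        )
        out = np.mean(
            [m.forward_tokens(tokens, group) for m in self.models], axis=0
        ).astype(float)
        if self.config.composition and add_composition_back:
            out = out + predict_composition(
                self.models[0].composition_model, sequences
            )
        return out

    def predict_tokens(self, tokens, group, sequences=None, add_composition_back=True):
        """Prediction path for pre-encoded queries (ranking reuses encodings)."""
        out = np.mean(
            [m.forward_tokens(tokens, group) for m in self.models], axis=0
        ).astype(float)
        if self.config.composition and add_composition_back and sequences is not None:
            out = out + predict_composition(self.models[0].composition_model, sequences)
        return out


def train_ensemble(
    table: BindingTable,
    cfg: ModelConfig,
    n_models: int = 12,
    seeds: list[int] | None = None,
) -> Ensemble:
    """Train ``n_models`` networks differing only in seed."""
    from dataclasses import replace

    if seeds is None:
        seeds = [cfg.seed + 1000 * i for i in range(n_models)]
    if len(seeds) != n_models:
        raise ValueError("need one seed per model")
    return Ensemble([train(table, replace(cfg, seed=s)) for s in seeds])


def cross_validate(
    table: BindingTable, cfg: ModelConfig, k: int = 10, seed: int = 0
) -> np.ndarray:
    """k-fold CV Pearson r per (fold, concentration), measured vs predicted.

    Weighting/shifting/composition are applied inside each training fold
    only, so no duplicated copies leak across the fold boundary.
    """
    rng = np.random.default_rng(seed)
    n = len(table)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    out = np.zeros((k, len(table.concentrations)))
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, test_idx, assume_unique=True)
        model = train(table.take(train_idx), cfg)
        pred = model.predict([table.sequences[i] for i in test_idx])
        truth = table.values[test_idx]
        for j in range(truth.shape[1]):
            out[f, j] = _pearson(truth[:, j], pred[:, j])
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    return float(a @ b / denom) if denom > 0 else 0.0
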