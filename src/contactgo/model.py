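"""The edge-supervised graph-attention network.

Architecture (three stages): a stack of graph-attention layers updates the
residue features

    h_i^{l+1} = act( Σ_{j ∈ N_i ∪ {i}}  α_ij  W^l h_j^l ),

where the aggregation weights α_ij come from the shared pairwise
coefficients (see :mod:`contactgo.attention_core`); global max pooling
collapses the final node embeddings into one protein vector; a two-layer
MLP with a sigmoid head emits one score per GO term.

The network is pure numpy. The backward pass is derived analytically layer
by layer and is validated against finite differences in the test suite;
everything runs in float64, which at desk-scale graph sizes is both fast
and free of precision surprises.

Ablation switches: ``use_unsupervised_attention=False`` replaces α by the
uniform GCN-style weight 1/|N_i ∪ {i}|; ``use_edge_supervision=False``
drops the auxiliary edge loss (handled in :mod:`contactgo.training`). With
both off the model degenerates into a plain GCN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import attention_core as ac
from .graph_io import ConfigurationError, DataError, ProteinGraph, ShapeMismatchError

CHECKPOINT_FORMAT = "contactgo-checkpoint-1"

_ACTIVATIONS = ("sigmoid", "relu", "elu", "identity")


@dataclass
class ModelConfig:
    """Hyperparameters of the network.

    ``layer_dims`` lists the feature width at every level, input included,
    so it has ``n_layers + 1`` entries. The default pyramid
    ``[Dp, 512, 256, 128]`` targets ESM-2-sized inputs; desk-scale runs use
    a narrower pyramid. The aggregation activation defaults to sigmoid;
    ``relu``/``elu`` are available as the more conventional escape hatch.
    """

    n_terms: int
    layer_dims: list[int] = field(default_factory=lambda: [1280, 512, 256, 128])
    attention_strategy: str = "MX"
    dropout_rate: float = 0.2
    use_unsupervised_attention: bool = True
    use_edge_supervision: bool = True
    aggregation_activation: str = "sigmoid"
    classifier_hidden: int = 256
    n_heads: int = 1
    leaky_relu_slope: float = ac.LEAKY_RELU_SLOPE

    def __post_init__(self) -> None:
        if self.n_terms < 1:
            raise ConfigurationError("n_terms must be >= 1")
        if len(self.layer_dims) < 2:
            raise ConfigurationError("layer_dims needs at least input and one output width")
        if any(d < 1 for d in self.layer_dims):
            raise ConfigurationError("layer widths must be positive")
        if self.attention_strategy not in ac.STRATEGIES:
            raise ConfigurationError(f"unknown attention strategy {self.attention_strategy!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must lie in [0, 1)")
        if self.aggregation_activation not in _ACTIVATIONS:
            raise ConfigurationError(
                f"aggregation_activation must be one of {_ACTIVATIONS}"
            )
        if self.n_heads != 1:
            raise ConfigurationError("only single-head attention is supported")

    @property
    def n_layers(self) -> int:
        return len(self.layer_dims) - 1


def _activation(name: str, x: np.ndarray) -> np.ndarray:
    if name == "sigmoid":
        return ac.sigmoid(x)
    if name == "relu":
        return np.maximum(x, 0.0)
    if name == "elu":
        return np.where(x > 0, x, np.expm1(x))
    return x


def _activation_grad(name: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Derivative of the activation, given pre-activation x and output y."""
    if name == "sigmoid":
        return y * (1.0 - y)
    if name == "relu":
        return (x > 0).astype(np.float64)
    if name == "elu":
        return np.where(x > 0, 1.0, y + 1.0)
    return np.ones_like(x)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape: tuple) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class EdgeSupervisedGAT:
    """The full network: GAT stack + max pool + MLP classifier.

    Parameters are plain float64 numpy arrays exposed through
    :meth:`parameters` as a flat name→array mapping (views, not copies),
    which is what the optimizer updates in place.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.layers: list[ac.LayerParams] = []
        needs_ws = config.attention_strategy in ("DP", "SD", "MX")
        for fin, fout in zip(config.layer_dims[:-1], config.layer_dims[1:]):
            W = _glorot(rng, fin, fout, (fin, fout))
            a = _glorot(rng, 2 * fout, 1, (2 * fout,))
            Ws = _glorot(rng, fin, fin, (fin, fin)) if needs_ws else None
            self.layers.append(
                ac.LayerParams(W=W, a=a, strategy=config.attention_strategy, Ws=Ws)
            )
        hid, nt = config.classifier_hidden, config.n_terms
        fin = config.layer_dims[-1]
        self.W1 = _glorot(rng, fin, hid, (fin, hid))
        self.b1 = np.zeros(hid)
        self.W2 = _glorot(rng, hid, nt, (hid, nt))
        self.b2 = np.zeros(nt)

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for l, p in enumerate(self.layers):
            out[f"layer{l}.W"] = p.W
            out[f"layer{l}.a"] = p.a
            if p.Ws is not None:
                out[f"layer{l}.Ws"] = p.Ws
        out.update({"mlp.W1": self.W1, "mlp.b1": self.b1, "mlp.W2": self.W2, "mlp.b2": self.b2})
        return out

    def set_parameters(self, values: dict[str, np.ndarray]) -> None:
        own = self.parameters()
        for name, arr in values.items():
            if name not in own:
                raise ConfigurationError(f"unknown parameter {name!r}")
            own[name][...] = arr

    def copy_parameters(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    # -- forward ------------------------------------------------------------

    def forward(
        self,
        graph: ProteinGraph,
        training: bool = False,
        rng: np.random.Generator | None = None,
        return_cache: bool = False,
    ):
        """Run the network on one protein graph.

        Returns ``(scores, states)`` — the per-term sigmoid scores and one
        :class:`~contactgo.attention_core.AttentionState` per layer — plus
        the backprop cache when ``return_cache`` is set. Dropout is active
        only with ``training=True`` (requires ``rng``).
        """
        cfg = self.config
        n = graph.n_residues
        if n == 0:
            raise DataError(f"protein {graph.protein_id!r} has an empty graph")
        X = graph.features
        if X.shape[1] != cfg.layer_dims[0]:
            raise ShapeMismatchError(
                f"feature dim {X.shape[1]} != configured input width {cfg.layer_dims[0]}"
            )
        mask = graph.adjacency.astype(bool) | np.eye(n, dtype=bool)

        states: list[ac.AttentionState] = []
        layer_caches: list[dict] = []
        H = X
        for params in self.layers:
            E, ccache = ac.coefficient_matrix(H, params)
            if cfg.use_unsupervised_attention:
                P = ac.masked_attention_weights(E, mask, cfg.leaky_relu_slope)
            else:
                P = mask / mask.sum(axis=1, keepdims=True)
            Hpre = P @ ccache["Z"]
            H_out = _activation(cfg.aggregation_activation, Hpre)
            states.append(ac.AttentionState(E, P, mask))
            layer_caches.append(
                {"ccache": ccache, "P": P, "Hpre": Hpre, "H_out": H_out, "E": E}
            )
            H = H_out

        pooled = H.max(axis=0)
        argmax = H.argmax(axis=0)
        h1pre = pooled @ self.W1 + self.b1
        h1 = np.maximum(h1pre, 0.0)
        if training and cfg.dropout_rate > 0.0:
            if rng is None:
                raise ConfigurationError("training-mode forward with dropout needs an rng")
            keep = 1.0 - cfg.dropout_rate
            drop_mask = (rng.random(h1.shape) < keep) / keep
        else:
            drop_mask = np.ones_like(h1)
        h1d = h1 * drop_mask
        logits = h1d @ self.W2 + self.b2
        scores = ac.sigmoid(logits)

        if not return_cache:
            return scores, states
        cache = {
            "mask": mask,
            "layers": layer_caches,
            "H_final": H,
            "pooled": pooled,
            "argmax": argmax,
            "h1pre": h1pre,
            "h1": h1,
            "drop_mask": drop_mask,
            "h1d": h1d,
            "logits": logits,
            "scores": scores,
        }
        return scores, states, cache

    # -- backward -----------------------------------------------------------

    def backward(
        self,
        cache: dict,
        dlogits: np.ndarray,
        dE_layers: list[np.ndarray] | None = None,
    ) -> dict[str, np.ndarray]:
        """Analytic gradients of the loss w.r.t. every parameter.

        ``dlogits`` is ∂L/∂(classifier pre-sigmoid logits); ``dE_layers``
        optionally adds the supervised-branch contribution ∂L/∂E per layer
        (already scaled by λ_E and the per-pair normalisation).
        """
        cfg = self.config
        grads: dict[str, np.ndarray] = {}

        h1d, pooled = cache["h1d"], cache["pooled"]
        grads["mlp.W2"] = np.outer(h1d, dlogits)
        grads["mlp.b2"] = dlogits.copy()
        dh1d = self.W2 @ dlogits
        dh1 = dh1d * cache["drop_mask"]
        dh1pre = dh1 * (cache["h1pre"] > 0)
        grads["mlp.W1"] = np.outer(pooled, dh1pre)
        grads["mlp.b1"] = dh1pre
        dpooled = self.W1 @ dh1pre

        H_final = cache["H_final"]
        dH = np.zeros_like(H_final)
        dH[cache["argmax"], np.arange(H_final.shape[1])] = dpooled

        for l in range(len(self.layers) - 1, -1, -1):
            params = self.layers[l]
            lc = cache["layers"][l]
            ccache, P = lc["ccache"], lc["P"]
            dHpre = dH * _activation_grad(
                cfg.aggregation_activation, lc["Hpre"], lc["H_out"]
            )
            dP = dHpre @ ccache["Z"].T
            dZ_agg = P.T @ dHpre

            if cfg.use_unsupervised_attention:
                # masked softmax backward; P vanishes off-mask so the dense
                # form already restricts to the neighbourhood
                dact = P * (dP - (dP * P).sum(axis=1, keepdims=True))
                dE = dact * ac.leaky_relu_grad(lc["E"], cfg.leaky_relu_slope)
            else:
                dE = np.zeros_like(lc["E"])
            if dE_layers is not None and dE_layers[l] is not None:
                dE = dE + dE_layers[l]

            cgrads = ac.coefficient_matrix_backward(dE, params, ccache)
            X_in = ccache["X"]
            grads[f"layer{l}.W"] = cgrads["W"] + X_in.T @ dZ_agg
            grads[f"layer{l}.a"] = cgrads["a"]
            if params.Ws is not None:
                grads[f"layer{l}.Ws"] = cgrads.get("Ws", np.zeros_like(params.Ws))
            dH = cgrads["X"] + dZ_agg @ params.W.T
        return grads

    # -- checkpointing ------------------------------------------------------

    def save(self, path) -> None:
        """Serialise parameters + config into a single ``.npz`` container."""
        payload = {f"param::{k}": v for k, v in self.parameters().items()}
        meta = {"format": CHECKPOINT_FORMAT, "config": asdict(self.config)}
        payload["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "EdgeSupervisedGAT":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(bytes(data["meta_json"]).decode())
            if meta.get("format") != CHECKPOINT_FORMAT:
                raise DataError(f"unsupported checkpoint format {meta.get('format')!r}")
            config = ModelConfig(**meta["config"])
            model = cls(config, seed=0)
            model.set_parameters(
                {k[len("param::"):]: data[k] for k in data.files if k.startswith("param::")}
            )
        return model


def predict_terms(scores: np.ndarray, threshold: float) -> set[int]:
    """Indices of terms whose score reaches the threshold (ties positive)."""
    if not 0.0 <= threshold <= 1.0:
        raise ConfigurationError(f"threshold must lie in [0, 1], got {threshold}")
    return {int(k) for k in np.nonzero(np.asarray(scores) >= threshold)[0]}
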