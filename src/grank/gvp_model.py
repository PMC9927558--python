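"""The scoring network: a rotation/translation/reflection-invariant GVP-GNN.

Node and edge embeddings are tuples ``(s, V)`` of a scalar feature vector and
a stack of geometric 3-vectors. A geometric vector perceptron (GVP) mixes the
two channels while preserving equivariance of the vector channel: vectors are
transformed only by channel mixing and per-channel gating, and they reach the
scalar channel only through their norms. The network is

    one-hot atoms --GVP--> h_V        RBF + unit vec --GVP--> h_E
    [ graph propagation + feed-forward ] x n_blocks (default 5)
    output GVP reducing to scalars -> mean pool over nodes -> 2 dense layers
    -> one scalar score per graph

The graph propagation layer computes a message for every directed edge j->i
from ``concat(h_Vj, h_Ej->i)`` through a chain of 3 GVPs, averages incoming
messages (1/k' with k' the in-degree; isolated nodes skip the term), and
applies a residual update with dropout and tuple layer norm. The
feed-forward layer is a point-wise chain of 2 GVPs with the same residual
norm. Since every learned map touches coordinates only through edge lengths,
edge directions and vector norms, the final scalar score is exactly invariant
under any rigid motion or reflection of the input coordinates.

All math runs on the NumPy autodiff core in :mod:`grank._autodiff`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .interface_graph import InterfaceGraph

_LN_EPS = 1e-5
_VN_EPS = 1e-8


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``n_blocks=5`` with message/feed-forward GVP counts (3, 2) is the
    reference architecture; hidden widths and dropout are config choices.
    """

    node_dims: tuple[int, int] = (100, 16)
    edge_dims: tuple[int, int] = (32, 1)
    n_blocks: int = 5
    n_message_gvps: int = 3
    n_ff_gvps: int = 2
    dropout_rate: float = 0.1
    n_rbf: int = 16
    dense_hidden: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_blocks", "n_message_gvps", "n_ff_gvps",
                     "n_rbf", "dense_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if min(self.node_dims) < 0 or min(self.edge_dims) < 0 or \
                self.node_dims[0] < 1 or self.edge_dims[0] < 1:
            raise ValueError("feature dims must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class GVPSpec:
    """Dims and activation flag of one GVP layer inside the network."""

    prefix: str
    in_dims: tuple[int, int]
    out_dims: tuple[int, int]
    activate: bool = True  # ReLU on scalars; vector gating is always on

    @property
    def hidden_v(self) -> int:
        return max(self.in_dims[1], self.out_dims[1])


def init_gvp_params(spec: GVPSpec, rng: np.random.Generator,
                    ) -> dict[str, Tensor]:
    """Glorot-uniform initialization of one GVP's parameters."""
    (si, vi), (so, vo) = spec.in_dims, spec.out_dims
    h = spec.hidden_v
    params: dict[str, Tensor] = {}

    def linear(name, fan_in, fan_out, bias):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        params[f"{spec.prefix}.{name}"] = Tensor(
            rng.uniform(-limit, limit, size=(fan_in, fan_out)),
            requires_grad=True)
        if bias:
            params[f"{spec.prefix}.{name}_b"] = Tensor(
                np.zeros(fan_out), requires_grad=True)

    if vi > 0:
        linear("Wh", vi, h, bias=False)
    linear("Wm", si + (h if vi > 0 else 0), so, bias=True)
    if vo > 0 and vi > 0:
        linear("Wmu", h, vo, bias=False)
        linear("Wg", so, vo, bias=True)
    return params


def gvp_forward(params: dict[str, Tensor], spec: GVPSpec,
                s: Tensor, V: Tensor) -> tuple[Tensor, Tensor]:
    """Apply one vector-gated GVP to a tuple embedding.

    V_h = W_h V; s_m = W_m concat(s, rownorm(V_h)) + b; scalars = ReLU(s_m)
    (identity when ``spec.activate`` is False); vectors = (W_mu V_h) gated
    per channel by sigmoid of a linear map of s_m. With no input vectors the
    output vector channel is zero (there is no equivariant way to create
    vectors from scalars alone).
    """
    p = spec.prefix
    (si, vi), (so, vo) = spec.in_dims, spec.out_dims
    if s.shape[-1] != si or V.shape[-2] != vi:
        raise ValueError(
            f"GVP {p!r}: input dims {(s.shape[-1], V.shape[-2])} "
            f"do not match spec {spec.in_dims}")
    if vi > 0:
        Vh = ad.vecmat(V, params[f"{p}.Wh"])
        s_in = ad.concat([s, ad.safe_norm(Vh, axis=2, eps=_VN_EPS)], axis=1)
    else:
        s_in = s
    sm = ad.add(ad.matmul(s_in, params[f"{p}.Wm"]), params[f"{p}.Wm_b"])
    s_out = ad.relu(sm) if spec.activate else sm
    if vo == 0:
        V_out = Tensor(np.zeros((s.shape[0], 0, 3)))
    elif vi == 0:
        V_out = Tensor(np.zeros((s.shape[0], vo, 3)))
    else:
        Vmu = ad.vecmat(Vh, params[f"{p}.Wmu"])
        gate = ad.sigmoid(ad.add(ad.matmul(sm, params[f"{p}.Wg"]),
                                 params[f"{p}.Wg_b"]))
        V_out = ad.mul(Vmu, ad.reshape(gate, (gate.shape[0], vo, 1)))
    return s_out, V_out


def init_layer_norm_params(prefix: str, n_scalar: int) -> dict[str, Tensor]:
    return {
        f"{prefix}.gamma": Tensor(np.ones(n_scalar), requires_grad=True),
        f"{prefix}.beta": Tensor(np.zeros(n_scalar), requires_grad=True),
    }


def layer_norm_tuple(params: dict[str, Tensor], prefix: str,
                     s: Tensor, V: Tensor) -> tuple[Tensor, Tensor]:
    """Tuple layer norm: affine norm on scalars; vector channel divided by
    the root-mean-square of its channel norms (no centering, so vector
    equivariance is preserved)."""
    mu = ad.tmean(s, axis=1, keepdims=True)
    xc = ad.sub(s, mu)
    var = ad.tmean(ad.mul(xc, xc), axis=1, keepdims=True)
    s_hat = ad.div(xc, ad.sqrt(ad.add(var, Tensor(_LN_EPS))))
    s_out = ad.add(ad.mul(s_hat, params[f"{prefix}.gamma"]),
                   params[f"{prefix}.beta"])
    nv = V.shape[1]
    if nv == 0:
        return s_out, V
    norms2 = ad.tsum(ad.mul(V, V), axis=2)             # (n, nv)
    rms = ad.sqrt(ad.add(ad.tmean(norms2, axis=1, keepdims=True),
                         Tensor(_VN_EPS)))             # (n, 1)
    V_out = ad.div(V, ad.reshape(rms, (rms.shape[0], 1, 1)))
    return s_out, V_out


def _dropout_tuple(s: Tensor, V: Tensor, rate: float,
                   rng: np.random.Generator) -> tuple[Tensor, Tensor]:
    """Train-mode dropout: elementwise on scalars, whole-3-vector on vectors."""
    if rate <= 0.0:
        return s, V
    keep = 1.0 - rate
    s_mask = (rng.random(s.shape) < keep) / keep
    s = ad.mul(s, Tensor(s_mask))
    if V.shape[1] > 0:
        v_mask = (rng.random(V.shape[:2]) < keep) / keep
        V = ad.mul(V, Tensor(v_mask[:, :, None]))
    return s, V


@dataclass
class GraphBatch:
    """Disjoint union of interface graphs for one forward pass."""

    node_scalar: np.ndarray
    node_vector: np.ndarray
    edges: np.ndarray
    edge_scalar: np.ndarray
    edge_vector: np.ndarray
    graph_index: np.ndarray  # (n_nodes,) graph id per node
    n_graphs: int

    @classmethod
    def from_graphs(cls, graphs: list[InterfaceGraph]) -> "GraphBatch":
        if not graphs:
            raise ValueError("empty batch")
        for g in graphs:
            if g.n_nodes == 0:
                raise ValueError("cannot score an empty graph")
        offsets = np.cumsum([0] + [g.n_nodes for g in graphs])
        edges = [g.edges + off for g, off in zip(graphs, offsets)
                 if g.n_edges > 0]
        n_rbf = graphs[0].edge_scalar.shape[1] if graphs else 0
        return cls(
            node_scalar=np.concatenate([g.node_scalar for g in graphs]),
            node_vector=np.concatenate([g.node_vector for g in graphs]),
            edges=(np.concatenate(edges) if edges
                   else np.zeros((0, 2), dtype=np.intp)),
            edge_scalar=np.concatenate([g.edge_scalar for g in graphs])
            if graphs else np.zeros((0, n_rbf)),
            edge_vector=np.concatenate([g.edge_vector for g in graphs]),
            graph_index=np.repeat(np.arange(len(graphs)),
                                  [g.n_nodes for g in graphs]),
            n_graphs=len(graphs),
        )


@dataclass
class ModelState:
    """Serializable snapshot of every learned parameter plus the config."""

    config: ModelConfig
    params: dict[str, np.ndarray] = field(default_factory=dict)

    def save(self, path) -> None:
        arrays = {k: v for k, v in self.params.items()}
        arrays["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ModelState":
        with np.load(path, allow_pickle=False) as data:
            cfg_raw = json.loads(bytes(data["__config__"]).decode())
            cfg_raw["node_dims"] = tuple(cfg_raw["node_dims"])
            cfg_raw["edge_dims"] = tuple(cfg_raw["edge_dims"])
            config = ModelConfig(**cfg_raw)
            params = {k: data[k].copy() for k in data.files
                      if k != "__config__"}
        return cls(config=config, params=params)


class GVPModel:
    """The full scoring network with its parameters."""

    def __init__(self, config: ModelConfig, params: dict[str, Tensor] | None = None):
        self.config = config
        self.specs = self._build_specs(config)
        if params is None:
            rng = np.random.default_rng(config.seed)
            params = {}
            for spec in self.specs.values():
                params.update(init_gvp_params(spec, rng))
            for b in range(config.n_blocks):
                params.update(init_layer_norm_params(
                    f"block{b}.norm0", config.node_dims[0]))
                params.update(init_layer_norm_params(
                    f"block{b}.norm1", config.node_dims[0]))
            ns, dh = config.node_dims[0], config.dense_hidden
            for name, (fi, fo) in (("dense0", (ns, dh)), ("dense1", (dh, 1))):
                limit = np.sqrt(6.0 / (fi + fo))
                params[f"{name}.W"] = Tensor(
                    rng.uniform(-limit, limit, size=(fi, fo)),
                    requires_grad=True)
                params[f"{name}.b"] = Tensor(np.zeros(fo), requires_grad=True)
        self.params = params

    # -- architecture ------------------------------------------------------

    @staticmethod
    def _build_specs(cfg: ModelConfig) -> dict[str, GVPSpec]:
        ns, nv = cfg.node_dims
        es, ev = cfg.edge_dims
        specs: dict[str, GVPSpec] = {
            "node_embed": GVPSpec("node_embed", (5, 0), (ns, nv),
                                  activate=False),
            "edge_embed": GVPSpec("edge_embed", (cfg.n_rbf, 1), (es, ev),
                                  activate=False),
        }
        for b in range(cfg.n_blocks):
            for k in range(cfg.n_message_gvps):
                in_dims = (ns + es, nv + ev) if k == 0 else (ns, nv)
                last = k == cfg.n_message_gvps - 1
                specs[f"block{b}.msg{k}"] = GVPSpec(
                    f"block{b}.msg{k}", in_dims, (ns, nv), activate=not last)
            hidden = (2 * ns, nv)
            for k in range(cfg.n_ff_gvps):
                first = k == 0
                last = k == cfg.n_ff_gvps - 1
                in_dims = (ns, nv) if first else hidden
                out_dims = (ns, nv) if last else hidden
                specs[f"block{b}.ff{k}"] = GVPSpec(
                    f"block{b}.ff{k}", in_dims, out_dims, activate=not last)
        specs["out_gvp"] = GVPSpec("out_gvp", (ns, nv), (ns, 0),
                                   activate=False)
        return specs

    # -- layers ------------------------------------------------------------

    def _gvp_chain(self, prefixes: list[str], s: Tensor, V: Tensor):
        for p in prefixes:
            s, V = gvp_forward(self.params, self.specs[p], s, V)
        return s, V

    def propagate(self, block: int, s: Tensor, V: Tensor,
                  edge_s: Tensor, edge_V: Tensor, edges: np.ndarray,
                  n_nodes: int, train: bool = False,
                  rng: np.random.Generator | None = None):
        """One graph-propagation layer: messages, mean aggregation, residual."""
        cfg = self.config
        prefixes = [f"block{block}.msg{k}" for k in range(cfg.n_message_gvps)]
        if len(edges):
            src, dst = edges[:, 0], edges[:, 1]
            ms = ad.concat([ad.take(s, src), edge_s], axis=1)
            mV = ad.concat([ad.take(V, src), edge_V], axis=1)
            ms, mV = self._gvp_chain(prefixes, ms, mV)
            agg_s = ad.segment_sum(ms, dst, n_nodes)
            agg_V = ad.segment_sum(mV, dst, n_nodes)
            if train:
                agg_s, agg_V = _dropout_tuple(agg_s, agg_V,
                                              cfg.dropout_rate, rng)
            deg = np.bincount(dst, minlength=n_nodes).astype(float)
            inv = 1.0 / np.maximum(deg, 1.0)  # k'=0 nodes get a zero term
            agg_s = ad.mul(agg_s, Tensor(inv[:, None]))
            agg_V = ad.mul(agg_V, Tensor(inv[:, None, None]))
            s, V = ad.add(s, agg_s), ad.add(V, agg_V)
        return layer_norm_tuple(self.params, f"block{block}.norm0", s, V)

    def feed_forward(self, block: int, s: Tensor, V: Tensor,
                     train: bool = False,
                     rng: np.random.Generator | None = None):
        """One point-wise feed-forward layer with residual tuple norm."""
        cfg = self.config
        prefixes = [f"block{block}.ff{k}" for k in range(cfg.n_ff_gvps)]
        fs, fV = self._gvp_chain(prefixes, s, V)
        if train:
            fs, fV = _dropout_tuple(fs, fV, cfg.dropout_rate, rng)
        return layer_norm_tuple(self.params, f"block{block}.norm1",
                                ad.add(s, fs), ad.add(V, fV))

    # -- full forward ------------------------------------------------------

    def forward_batch(self, batch: GraphBatch, train: bool = False,
                      rng: np.random.Generator | None = None) -> Tensor:
        """Scores for every graph in the batch, shape (n_graphs,).

        Graphs never interact: all updates are per-node and pooling is
        per-graph, so a graph's score is independent of its batch-mates.
        """
        if train and rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        n = batch.node_scalar.shape[0]
        s, V = gvp_forward(self.params, self.specs["node_embed"],
                           Tensor(batch.node_scalar),
                           Tensor(batch.node_vector))
        e_s, e_V = gvp_forward(self.params, self.specs["edge_embed"],
                               Tensor(batch.edge_scalar),
                               Tensor(batch.edge_vector))
        for b in range(self.config.n_blocks):
            s, V = self.propagate(b, s, V, e_s, e_V, batch.edges, n,
                                  train=train, rng=rng)
            s, V = self.feed_forward(b, s, V, train=train, rng=rng)
        s, _ = gvp_forward(self.params, self.specs["out_gvp"], s, V)

        counts = np.bincount(batch.graph_index,
                             minlength=batch.n_graphs).astype(float)
        pooled = ad.mul(ad.segment_sum(s, batch.graph_index, batch.n_graphs),
                        Tensor(1.0 / counts[:, None]))
        h = ad.relu(ad.add(ad.matmul(pooled, self.params["dense0.W"]),
                           self.params["dense0.b"]))
        out = ad.add(ad.matmul(h, self.params["dense1.W"]),
                     self.params["dense1.b"])
        return ad.reshape(out, (batch.n_graphs,))

    def trainable_params(self) -> dict[str, Tensor]:
        return {k: v for k, v in self.params.items() if v.requires_grad}

    # -- persistence -------------------------------------------------------

    def state(self) -> ModelState:
        return ModelState(self.config,
                          {k: v.data.copy() for k, v in self.params.items()})

    @classmethod
    def from_state(cls, state: ModelState) -> "GVPModel":
        model = cls(state.config)
        for k, v in state.params.items():
            if k not in model.params:
                raise ValueError(f"unexpected parameter {k!r} in state")
            if model.params[k].data.shape != v.shape:
                raise ValueError(f"shape mismatch for parameter {k!r}")
            model.params[k].data = v.astype(np.float64).copy()
        return model


def score_graph(graph: InterfaceGraph, state: ModelState | GVPModel,
                mode: str = "eval") -> float:
    """Score one interface graph. Eval mode is deterministic and invariant
    under any rigid motion, reflection, or node reordering of the input."""
    model = state if isinstance(state, GVPModel) else GVPModel.from_state(state)
    batch = GraphBatch.from_graphs([graph])
    if mode == "eval":
        with ad.no_grad():
            return float(model.forward_batch(batch, train=False).data[0])
    rng = np.random.default_rng(model.config.seed)
    return float(model.forward_batch(batch, train=True, rng=rng).data[0])
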