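"""Training the scorer to regress f-nat, and fold ensembling.

The network is trained with mean squared error against f-nat using Adam
(batch size 64, learning rate 1e-4, 50 epochs by default). The model saved
for evaluation is the one from the epoch with the lowest validation loss.
Cross-validation splits are made *by complex*: every docking model of a
complex lands in the same split, so a test complex is never seen in
training. The final predictor averages the eval-mode scores of the models
trained on each fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .gvp_model import GraphBatch, GVPModel, ModelConfig, ModelState
from .interface_graph import InterfaceGraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 64
    learning_rate: float = 1e-4
    n_epochs: int = 50
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.n_epochs < 1:
            raise ValueError("batch_size and n_epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class FoldSplit:
    fold_id: int
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str] = field(default_factory=list)


@dataclass
class TrainHistory:
    """Per-epoch losses; ``selected_epoch`` is the 1-based argmin of the
    validation loss (the retained checkpoint)."""

    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)

    @property
    def selected_epoch(self) -> int:
        if not self.val_losses:
            raise ValueError("no epochs recorded")
        return int(np.argmin(self.val_losses)) + 1


def make_splits(complex_ids: list[str], n_folds: int, seed: int,
                test_ids: list[str] | None = None) -> list[FoldSplit]:
    """Deterministic per-complex cross-validation splits.

    ``test_ids`` (if given) are held out of every fold; the remaining
    complexes are shuffled once and partitioned into ``n_folds`` validation
    chunks, each fold training on the rest.
    """
    test_ids = list(test_ids or [])
    pool = [c for c in complex_ids if c not in set(test_ids)]
    if len(set(pool)) != len(pool):
        raise ValueError("duplicate complex ids")
    if len(pool) < n_folds:
        raise ValueError(
            f"need at least {n_folds} non-test complexes, got {len(pool)}")
    rng = np.random.default_rng(seed)
    order = [pool[i] for i in rng.permutation(len(pool))]
    chunks = [list(c) for c in np.array_split(np.array(order, dtype=object),
                                              n_folds)]
    return [
        FoldSplit(
            fold_id=f,
            train_ids=[c for g, chunk in enumerate(chunks) if g != f
                       for c in chunk],
            val_ids=list(chunks[f]),
            test_ids=list(test_ids),
        )
        for f in range(n_folds)
    ]


class Adam:
    """Adam optimizer with canonical moment defaults and no weight decay."""

    def __init__(self, params: dict[str, Tensor], cfg: TrainConfig):
        self.params = params
        self.cfg = cfg
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def step(self) -> None:
        cfg = self.cfg
        self.t += 1
        bc1 = 1.0 - cfg.beta1 ** self.t
        bc2 = 1.0 - cfg.beta2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = cfg.beta1 * self.m[k] + (1 - cfg.beta1) * g
            self.v[k] = cfg.beta2 * self.v[k] + (1 - cfg.beta2) * g * g
            p.data -= cfg.learning_rate * (self.m[k] / bc1) / (
                np.sqrt(self.v[k] / bc2) + cfg.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()


LabeledGraphs = list[tuple[InterfaceGraph, float]]


def _eval_mse(model: GVPModel, data: LabeledGraphs,
              batch_size: int) -> float:
    """Mean squared error over a dataset in eval mode (dropout off)."""
    errors = []
    with ad.no_grad():
        for lo in range(0, len(data), batch_size):
            chunk = data[lo:lo + batch_size]
            batch = GraphBatch.from_graphs([g for g, _ in chunk])
            preds = model.forward_batch(batch, train=False).data
            y = np.array([t for _, t in chunk])
            errors.append((preds - y) ** 2)
    return float(np.concatenate(errors).mean())


def train_fold(train_data: LabeledGraphs, val_data: LabeledGraphs,
               model_cfg: ModelConfig, train_cfg: TrainConfig,
               fold_id: int = 0) -> tuple[ModelState, TrainHistory]:
    """Train one fold and return the lowest-validation-loss checkpoint.

    Fully seeded: parameter init comes from ``model_cfg.seed``, while
    shuffling and dropout derive from ``train_cfg.seed`` combined with the
    fold id and epoch, so two runs with the same configs are identical.
    """
    if not train_data or not val_data:
        raise ValueError("train and validation sets must be non-empty")
    model = GVPModel(model_cfg)
    opt = Adam(model.trainable_params(), train_cfg)
    history = TrainHistory()
    best_state: ModelState | None = None
    best_val = np.inf

    for epoch in range(train_cfg.n_epochs):
        epoch_rng = np.random.default_rng(
            (train_cfg.seed * 100_003 + fold_id * 1_009 + epoch) % (2**31))
        order = epoch_rng.permutation(len(train_data))
        epoch_losses = []
        for lo in range(0, len(order), train_cfg.batch_size):
            chunk = [train_data[i] for i in order[lo:lo + train_cfg.batch_size]]
            batch = GraphBatch.from_graphs([g for g, _ in chunk])
            y = np.array([t for _, t in chunk])
            preds = model.forward_batch(batch, train=True, rng=epoch_rng)
            diff = ad.sub(preds, Tensor(y))
            loss = ad.tmean(ad.mul(diff, diff))
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch + 1} "
                    f"(fold {fold_id}); last batch size {len(chunk)}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        val_loss = _eval_mse(model, val_data, train_cfg.batch_size)
        history.train_losses.append(float(np.mean(epoch_losses)))
        history.val_losses.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state()
        logger.debug("fold %d epoch %d: train %.4f val %.4f",
                     fold_id, epoch + 1, history.train_losses[-1], val_loss)

    assert best_state is not None
    return best_state, history


def ensemble_predict(states: list[ModelState | GVPModel],
                     graph: InterfaceGraph) -> float:
    """Arithmetic mean of the member models' eval-mode scores."""
    return float(np.mean(ensemble_predict_batch(states, [graph])))


def ensemble_predict_batch(states: list[ModelState | GVPModel],
                           graphs: list[InterfaceGraph],
                           batch_size: int = 64) -> np.ndarray:
    """Ensemble scores for many graphs, shape (len(graphs),)."""
    if not states:
        raise ValueError("ensemble needs at least one model state")
    models = [s if isinstance(s, GVPModel) else GVPModel.from_state(s)
              for s in states]
    totals = np.zeros(len(graphs))
    with ad.no_grad():
        for lo in range(0, len(graphs), batch_size):
            batch = GraphBatch.from_graphs(graphs[lo:lo + batch_size])
            for model in models:
                totals[lo:lo + batch_size] += model.forward_batch(
                    batch, train=False).data
    return totals / len(models)
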