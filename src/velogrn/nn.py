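"""Per-gene velocity regression networks with soft multi-task sharing.

Each gene (task) owns a small network: a TF aggregation layer in which
neuron ``k`` combines TF ``k``'s three inputs as
``g(w1_k * a_sum_k + w2_k * a_mean_k + w3_k * x_k)``, followed by fully
connected layers FC1 (64), FC2 (32), FC3 (16) and a linear scalar output.
Tasks within a cluster are trained jointly: besides the mean-squared error
and an L1 penalty on all weights, the loss carries a trace-norm (nuclear
norm) penalty on the matrix obtained by stacking each task's flattened FC1
(resp. FC2) weights as columns.  Minimizing the sum of singular values
pushes the stacked matrix toward low rank, i.e. makes tasks share structure
without hard weight tying.

All parameters live in stacked arrays with a leading task axis, so the
whole cluster trains in vectorized NumPy; the optimizer is Adam with the
trace-norm term's gradient supplied by the subgradient U V^T of the thin
SVD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocess import TaskDataset

__all__ = [
    "TrainingConfig",
    "MultiTaskModel",
    "BatchPlan",
    "init_model",
    "forward",
    "forward_single",
    "trace_norm",
    "trace_norm_subgradient",
    "multitask_loss",
    "multitask_loss_and_grads",
    "sample_epoch_batches",
    "train_cluster",
]

HIDDEN = (64, 32, 16)
SHAREABLE = ("FC1", "FC2")  # lower layers share; FC3/output stay task-specific
WEIGHT_KEYS = ("agg", "W1", "W2", "W3", "W4")
_SHARED_KEY = {"FC1": "W1", "FC2": "W2"}


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters for joint training of one gene cluster.

    ``lambda_l1`` is the L1 strength on all weight matrices (biases
    excluded); ``gamma_trace`` the trace-norm strength on the shared layer
    stacks.  ``sharing_enabled=False`` drops the trace-norm term entirely,
    giving the independent per-gene baseline with an otherwise identical
    architecture.  ``repeats`` re-runs training with derived seeds and
    averages the per-gene test R²; ``rounds`` and ``top_k`` govern the
    downstream consensus-network construction.
    """

    lambda_l1: float = 0.01
    gamma_trace: float = 0.01
    batch_size: int = 128
    epochs: int = 30
    learning_rate: float = 1e-3
    seed: int = 0
    share_layers: tuple[str, ...] = SHAREABLE
    sharing_enabled: bool = True
    activation: str = "relu"
    repeats: int = 3
    rounds: int = 5
    top_k: int = 50
    normalize_mse: bool = True

    def __post_init__(self) -> None:
        if self.lambda_l1 < 0 or self.gamma_trace < 0:
            raise ValueError("regularization strengths must be nonnegative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        bad = set(self.share_layers) - set(SHAREABLE)
        if bad:
            raise ValueError(f"unshareable layers requested: {sorted(bad)}")
        if self.activation not in {"relu", "tanh"}:
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class MultiTaskModel:
    """Stacked parameters for all tasks of one cluster.

    ``params['agg']`` has shape (T, 3, n_tfs); ``params['W<l>']`` /
    ``params['b<l>']`` are (T, in, out) / (T, out).  Flattening order for the
    shared stacks is row-major over (in, out); biases are excluded from both
    the L1 and trace-norm terms.
    """

    gene_ids: list[str]
    n_tfs: int
    params: dict[str, np.ndarray]
    activation: str = "relu"
    hidden: tuple[int, ...] = HIDDEN

    @property
    def n_tasks(self) -> int:
        return len(self.gene_ids)

    def task_params(self, t: int) -> dict[str, np.ndarray]:
        return {k: v[t] for k, v in self.params.items()}


@dataclass
class BatchPlan:
    """Per-epoch mini-batch schedule for one cluster.

    ``streams`` has shape (T, batches_per_epoch, b): for each ensemble batch
    one size-``b`` index batch per task.  Tasks with fewer examples than an
    epoch consumes are resampled by cycling reshuffled permutations, so every
    training example of every task appears at least once per epoch.
    """

    batches_per_epoch: int
    c_max: int
    batch_size: int
    streams: np.ndarray


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    return np.maximum(z, 0.0) if kind == "relu" else np.tanh(z)


def _act_grad(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (z > 0).astype(z.dtype)
    t = np.tanh(z)
    return 1.0 - t * t


def init_model(
    n_tfs: int,
    gene_ids: list[str],
    config: TrainingConfig,
    seed: int | None = None,
) -> MultiTaskModel:
    """Glorot-uniform initialization of all task networks, deterministic in
    the seed.  Aggregation neurons have fan-in 3 / fan-out 1; biases start
    at zero."""
    if n_tfs < 1:
        raise ValueError("n_tfs must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    t = len(gene_ids)
    widths = (n_tfs,) + HIDDEN + (1,)
    params: dict[str, np.ndarray] = {
        "agg": rng.uniform(-math.sqrt(6 / 4), math.sqrt(6 / 4), size=(t, 3, n_tfs))
    }
    for layer, (fan_in, fan_out) in enumerate(zip(widths[:-1], widths[1:]), start=1):
        lim = math.sqrt(6.0 / (fan_in + fan_out))
        params[f"W{layer}"] = rng.uniform(-lim, lim, size=(t, fan_in, fan_out))
        params[f"b{layer}"] = np.zeros((t, fan_out))
    return MultiTaskModel(list(gene_ids), n_tfs, params, config.activation)


def _forward_cache(
    model: MultiTaskModel, x: np.ndarray
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Vectorized forward for stacked input x of shape (T, n, 3*n_tfs)."""
    f = model.n_tfs
    if x.shape[-1] != 3 * f:
        raise ValueError(
            f"input rows must have length 3*n_tfs = {3 * f}, got {x.shape[-1]}"
        )
    p = model.params
    a_sum, a_mean, expr = x[..., :f], x[..., f : 2 * f], x[..., 2 * f :]
    z0 = (
        p["agg"][:, 0][:, None, :] * a_sum
        + p["agg"][:, 1][:, None, :] * a_mean
        + p["agg"][:, 2][:, None, :] * expr
    )
    h0 = _act(z0, model.activation)
    cache = {"a_sum": a_sum, "a_mean": a_mean, "expr": expr, "z0": z0, "h0": h0}
    h = h0
    for layer in (1, 2, 3):
        z = h @ p[f"W{layer}"] + p[f"b{layer}"][:, None, :]
        cache[f"z{layer}"] = z
        h = _act(z, model.activation)
        cache[f"h{layer}"] = h
    out = h @ p["W4"] + p["b4"][:, None, :]
    return out[..., 0], cache


def forward(model: MultiTaskModel, x: np.ndarray) -> np.ndarray:
    """Predicted velocities, shape (T, n), for stacked inputs (T, n, 3F)."""
    out, _ = _forward_cache(model, x)
    return out


def forward_single(model: MultiTaskModel, task: int, x: np.ndarray) -> np.ndarray:
    """Predictions of one task's network for rows x of shape (n, 3F)."""
    out = forward(
        MultiTaskModel(
            [model.gene_ids[task]],
            model.n_tfs,
            {k: v[task : task + 1] for k, v in model.params.items()},
            model.activation,
        ),
        x[None],
    )
    return out[0]


def trace_norm(w: np.ndarray) -> float:
    """Nuclear norm: sum of singular values."""
    w = np.asarray(w, dtype=float)
    if w.size == 0:
        raise ValueError("empty matrix")
    return float(np.linalg.svd(w, compute_uv=False).sum())


def trace_norm_subgradient(w: np.ndarray) -> np.ndarray:
    """The numerically stable subgradient U V^T of the nuclear norm, from
    the thin SVD W = U S V^T.  Its spectral norm is <= 1."""
    u, _, vt = np.linalg.svd(np.asarray(w, dtype=float), full_matrices=False)
    return u @ vt


def _shared_stack(model: MultiTaskModel, layer: str) -> np.ndarray:
    """Columns = per-task row-major flattened weights of the named layer."""
    key = _SHARED_KEY[layer]
    w = model.params[key]
    return w.reshape(w.shape[0], -1).T


def multitask_loss(
    model: MultiTaskModel,
    batches: np.ndarray,
    targets: np.ndarray,
    config: TrainingConfig,
) -> float:
    loss, _ = multitask_loss_and_grads(model, batches, targets, config, grads=False)
    return loss


def multitask_loss_and_grads(
    model: MultiTaskModel,
    batches: np.ndarray,
    targets: np.ndarray,
    config: TrainingConfig,
    grads: bool = True,
) -> tuple[float, dict[str, np.ndarray] | None]:
    """Joint loss over one ensemble batch (inputs (T, b, 3F), targets
    (T, b)) and, optionally, its gradients w.r.t. every parameter.

    loss = sum_i MSE_i + lambda * sum_i sum_layers ||W||_1
         + gamma * sum_{shared layers} ||W'||_*         (if sharing enabled)

    With ``normalize_mse`` the squared-error term is the per-task batch mean
    (keeps lambda/gamma scales batch-size independent); otherwise the raw
    sum, matching the loss as written with unnormalized sums.
    """
    p = model.params
    kind = model.activation
    pred, cache = _forward_cache(model, batches)
    resid = pred - targets  # (T, b)
    n_per_task = batches.shape[1]
    scale = 1.0 / n_per_task if config.normalize_mse else 1.0
    mse = float((resid**2).sum() * scale)

    l1 = 0.0
    if config.lambda_l1 > 0:
        l1 = config.lambda_l1 * sum(
            float(np.abs(p[k]).sum()) for k in WEIGHT_KEYS
        )

    trace = 0.0
    stacks: dict[str, np.ndarray] = {}
    if config.sharing_enabled and config.gamma_trace > 0:
        for layer in config.share_layers:
            stacks[layer] = _shared_stack(model, layer)
            trace += trace_norm(stacks[layer])
        trace *= config.gamma_trace

    loss = mse + l1 + trace
    if not grads:
        return loss, None

    g: dict[str, np.ndarray] = {}
    d_out = (2.0 * scale) * resid[..., None]  # (T, b, 1)
    h3 = cache["h3"]
    g["W4"] = np.matmul(h3.transpose(0, 2, 1), d_out)
    g["b4"] = d_out.sum(axis=1)
    d_h = np.matmul(d_out, p["W4"].transpose(0, 2, 1))
    for layer in (3, 2, 1):
        d_z = d_h * _act_grad(cache[f"z{layer}"], kind)
        h_prev = cache[f"h{layer - 1}"] if layer > 1 else cache["h0"]
        g[f"W{layer}"] = np.matmul(h_prev.transpose(0, 2, 1), d_z)
        g[f"b{layer}"] = d_z.sum(axis=1)
        d_h = np.matmul(d_z, p[f"W{layer}"].transpose(0, 2, 1))
    d_z0 = d_h * _act_grad(cache["z0"], kind)  # (T, b, F)
    g["agg"] = np.stack(
        [
            (d_z0 * cache["a_sum"]).sum(axis=1),
            (d_z0 * cache["a_mean"]).sum(axis=1),
            (d_z0 * cache["expr"]).sum(axis=1),
        ],
        axis=1,
    )

    if config.lambda_l1 > 0:
        for k in WEIGHT_KEYS:
            g[k] = g[k] + config.lambda_l1 * np.sign(p[k])

    if stacks:
        for layer, stack in stacks.items():
            key = _SHARED_KEY[layer]
            sub = trace_norm_subgradient(stack)  # (flat, T)
            g[key] = g[key] + config.gamma_trace * sub.T.reshape(p[key].shape)

    return loss, g


def sample_epoch_batches(
    task_sizes: list[int], b: int, seed: int
) -> BatchPlan:
    """Index schedule for one epoch.

    ``batches_per_epoch = ceil(C_max / b)`` where C_max is the largest
    training count among the cluster's tasks.  Smaller tasks cycle through
    reshuffled permutations of their indices (bootstrapping by permutation
    cycling), so every example of every task is used at least once per
    epoch.
    """
    if any(n < 1 for n in task_sizes):
        raise ValueError("every task needs at least one training example")
    if b < 1:
        raise ValueError("batch size must be >= 1")
    c_max = max(task_sizes)
    n_batches = math.ceil(c_max / b)
    need = n_batches * b
    rng = np.random.default_rng(seed)
    streams = np.empty((len(task_sizes), n_batches, b), dtype=np.int64)
    for t, n in enumerate(task_sizes):
        chunks = []
        got = 0
        while got < need:
            chunks.append(rng.permutation(n))
            got += n
        streams[t] = np.concatenate(chunks)[:need].reshape(n_batches, b)
    return BatchPlan(n_batches, c_max, b, streams)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float) -> None:
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for k, gr in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * gr
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * gr**2
            params[k] -= self.lr * (self.m[k] / b1c) / (
                np.sqrt(self.v[k] / b2c) + self.eps
            )


def _r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot <= 0:
        return float("nan")
    return 1.0 - float(((y_true - y_pred) ** 2).sum()) / ss_tot


def _train_once(
    train: list[TaskDataset],
    test: list[TaskDataset] | None,
    config: TrainingConfig,
    seed: int,
) -> tuple[MultiTaskModel, dict[str, float]]:
    gene_ids = [d.gene_id for d in train]
    n_tfs = train[0].inputs.shape[1] // 3
    model = init_model(n_tfs, gene_ids, config, seed=seed)
    opt = _Adam(model.params, config.learning_rate)
    sizes = [d.n_examples for d in train]
    b = config.batch_size
    t_n = len(train)
    for epoch in range(config.epochs):
        plan = sample_epoch_batches(sizes, b, seed + 10007 * (epoch + 1))
        for batch_i in range(plan.batches_per_epoch):
            xb = np.empty((t_n, b, 3 * n_tfs))
            yb = np.empty((t_n, b))
            for t, d in enumerate(train):
                idx = plan.streams[t, batch_i]
                xb[t] = d.inputs[idx]
                yb[t] = d.targets[idx]
            loss, grads = multitask_loss_and_grads(model, xb, yb, config)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {batch_i}"
                )
            opt.step(model.params, grads)
    r2: dict[str, float] = {}
    if test is not None:
        for t, d in enumerate(test):
            pred = forward_single(model, t, d.inputs)
            r2[d.gene_id] = _r2(d.targets, pred)
    return model, r2


def train_cluster(
    train: list[TaskDataset],
    test: list[TaskDataset] | None,
    config: TrainingConfig,
) -> tuple[MultiTaskModel, dict[str, float]]:
    """Train one cluster's tasks jointly and evaluate per-gene test R².

    With ``repeats > 1`` the whole procedure re-runs with derived seeds and
    the returned per-gene score is the mean R² across repeats (the model
    from the last repeat is returned).  With ``sharing_enabled=False`` the
    trace-norm term is absent and training reduces to independent per-gene
    fits that merely share the batch schedule.
    """
    if not train:
        raise ValueError("empty cluster")
    if test is not None and [d.gene_id for d in test] != [d.gene_id for d in train]:
        raise ValueError("train/test task lists must align by gene")
    repeats = max(1, config.repeats)
    all_r2: list[dict[str, float]] = []
    model = None
    for rep in range(repeats):
        seed = (config.seed + 7919 * rep) % (2**31 - 1)
        model, r2 = _train_once(train, test, config, seed)
        all_r2.append(r2)
    mean_r2 = {}
    if test is not None:
        for g in all_r2[0]:
            vals = [r[g] for r in all_r2]
            mean_r2[g] = float(np.mean(vals))
    assert model is not None
    return model, mean_r2
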