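"""Conditional Wasserstein GAN with gradient penalty for tabular records.

Generator: (128-d standard-normal noise ++ one-hot class label) projected to
a 256-wide hidden layer, two residual blocks, tanh output matched to the
(-1, 1) robust-tanh feature space.  Critic: three spectrally-normalized
affine layers with LeakyReLU(0.2), conditioned on the same one-hot label.
Training follows the WGAN-GP loop: per generator step, ``n_critic`` critic
updates minimizing ``-mean(D(x,y)) + mean(D(x~,y)) + gp``, then one
generator update minimizing ``-mean(D(x~,y))``; RMSprop updates with a
step learning-rate decay.

Built on the package's own reverse-mode engine (:mod:`idhgan.autodiff`);
the gradient penalty differentiates the norm of the critic's input
gradient with respect to the critic weights (double backprop).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import autodiff as ad
from .synthetic_data import OUTCOME_COLUMN

__all__ = [
    "GanConfig",
    "GanState",
    "init_networks",
    "gradient_penalty",
    "train_cwgan_gp",
    "sample_synthetic",
    "assemble_dataset",
]

_N_CLASSES = 2  # binary IDH label


@dataclass(frozen=True)
class GanConfig:
    noise_dim: int = 128
    hidden_dim: int = 256
    n_residual_blocks: int = 2
    critic_layers: int = 3
    spectral_norm: bool = True
    n_critic: int = 5
    gp_weight: float = 5.0
    lr_g: float = 1e-3
    lr_d: float = 2e-3
    scheduler_step: int = 30
    scheduler_gamma: float = 0.9
    batch_size: int = 1024
    epochs: int = 200
    leaky_slope: float = 0.2
    #: decay of the exponential moving average of generator weights used
    #: for sampling; averaging late iterates smooths the adversarial
    #: oscillation of the generator and stabilizes sample quality
    ema_decay: float = 0.995
    #: fraction of the training schedule before the average starts
    #: (averaging early, still-drifting iterates hurts quality)
    ema_start_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.gp_weight < 0:
            raise ValueError("gradient-penalty weight must be >= 0")
        if self.n_critic < 1:
            raise ValueError("n_critic must be >= 1")
        for f in ("noise_dim", "hidden_dim", "batch_size", "epochs"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be positive")


@dataclass
class GanState:
    gen_params: dict
    critic_params: dict
    sn_vectors: dict
    config: GanConfig
    feature_names: list
    binary_mask: np.ndarray
    loss_history: list = field(default_factory=list)  # (step, kind, value)
    #: EMA of generator weights; preferred for sampling when present
    gen_params_ema: dict | None = None

    def save(self, path) -> None:
        path = Path(path)
        arrays = {f"g__{k}": v for k, v in self.gen_params.items()}
        arrays.update({f"d__{k}": v for k, v in self.critic_params.items()})
        arrays.update({f"u__{k}": v for k, v in self.sn_vectors.items()})
        if self.gen_params_ema is not None:
            arrays.update({f"e__{k}": v
                           for k, v in self.gen_params_ema.items()})
        arrays["binary_mask"] = self.binary_mask.astype(np.int8)
        np.savez(path, **arrays)
        sidecar = {
            "config": asdict(self.config),
            "feature_names": list(self.feature_names),
            "loss_history": [[int(s), k, float(v)]
                             for s, k, v in self.loss_history],
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path) -> "GanState":
        path = Path(path)
        data = np.load(path if path.suffix == ".npz"
                       else path.with_suffix(".npz"))
        side = json.loads(path.with_suffix(".json").read_text())
        gen = {k[3:]: data[k] for k in data.files if k.startswith("g__")}
        crit = {k[3:]: data[k] for k in data.files if k.startswith("d__")}
        sn = {k[3:]: data[k] for k in data.files if k.startswith("u__")}
        ema = {k[3:]: data[k] for k in data.files if k.startswith("e__")}
        return cls(gen_params=gen, critic_params=crit, sn_vectors=sn,
                   gen_params_ema=ema or None,
                   config=GanConfig(**side["config"]),
                   feature_names=side["feature_names"],
                   binary_mask=data["binary_mask"].astype(bool),
                   loss_history=[tuple(t) for t in side["loss_history"]])


def _kaiming(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))


def init_networks(feature_count: int, config: GanConfig,
                  seed: int | None = None,
                  feature_names: list | None = None,
                  binary_mask: np.ndarray | None = None) -> GanState:
    """Kaiming-initialized generator and critic; deterministic given seed."""
    if feature_count < 1:
        raise ValueError("feature_count must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    h = config.hidden_dim
    gen: dict[str, np.ndarray] = {
        "W_in": _kaiming(rng, config.noise_dim + _N_CLASSES, h),
        "b_in": np.zeros(h),
    }
    for i in range(config.n_residual_blocks):
        gen[f"W_res{i}a"] = _kaiming(rng, h, h)
        gen[f"b_res{i}a"] = np.zeros(h)
        gen[f"W_res{i}b"] = _kaiming(rng, h, h)
        gen[f"b_res{i}b"] = np.zeros(h)
    # Reduced-gain output init keeps the tanh pre-activation well inside
    # its linear range at the start of training (Kaiming gain here would
    # saturate the output and stall the generator's gradients).
    gen["W_out"] = rng.normal(0.0, 0.25 / np.sqrt(h), size=(h, feature_count))
    gen["b_out"] = np.zeros(feature_count)

    dims = [feature_count + _N_CLASSES] + [h] * (config.critic_layers - 1) + [1]
    crit: dict[str, np.ndarray] = {}
    sn: dict[str, np.ndarray] = {}
    for i in range(config.critic_layers):
        crit[f"W{i}"] = _kaiming(rng, dims[i], dims[i + 1])
        crit[f"b{i}"] = np.zeros(dims[i + 1])
        if config.spectral_norm:
            # Learnable scalar gain on the normalized weight: spectral
            # normalization conditions the matrix while the gradient
            # penalty governs the overall Lipschitz scale.  Without the
            # gain the critic stays near-linear and cannot bend its
            # score down beyond the data support.
            crit[f"g{i}"] = np.ones(1)
        u = rng.normal(size=dims[i])
        sn[f"W{i}"] = u / np.linalg.norm(u)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(feature_count)]
    if binary_mask is None:
        binary_mask = np.zeros(feature_count, dtype=bool)
    return GanState(gen_params=gen, critic_params=crit, sn_vectors=sn,
                    config=config, feature_names=list(feature_names),
                    binary_mask=np.asarray(binary_mask, dtype=bool))


def _one_hot(labels: np.ndarray) -> np.ndarray:
    y = np.zeros((len(labels), _N_CLASSES))
    y[np.arange(len(labels)), labels.astype(int)] = 1.0
    return y


def _spectral_vectors(W: np.ndarray, u: np.ndarray,
                      n_iter: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """One power-iteration step for the leading singular pair of W.

    The returned u, v are treated as constants in the backward pass while
    sigma = u^T W v itself is differentiated, matching the standard
    spectral-normalization formulation.
    """
    for _ in range(n_iter):
        v = W.T @ u
        v = v / (np.linalg.norm(v) + 1e-12)
        u = W @ v
        u = u / (np.linalg.norm(u) + 1e-12)
    return u, v


def generator_forward(params: dict, z, y_onehot, config: GanConfig):
    """Graph forward pass; ``params`` values are autodiff Tensors."""
    slope = config.leaky_slope
    h = ad.leaky_relu(
        ad.concat([ad.astensor(z), ad.astensor(y_onehot)], axis=1)
        @ params["W_in"] + params["b_in"], slope)
    for i in range(config.n_residual_blocks):
        t = ad.leaky_relu(h @ params[f"W_res{i}a"] + params[f"b_res{i}a"],
                          slope)
        t = t @ params[f"W_res{i}b"] + params[f"b_res{i}b"]
        h = ad.leaky_relu(h + t, slope)
    return ad.tanh(h @ params["W_out"] + params["b_out"])


def critic_forward(params: dict, x, y_onehot, config: GanConfig,
                   sn_vectors: dict | None = None,
                   update_sn: bool = False):
    """Critic score; spectral normalization rescales each affine map by
    its estimated largest singular value."""
    slope = config.leaky_slope
    h = ad.concat([ad.astensor(x), ad.astensor(y_onehot)], axis=1)
    for i in range(config.critic_layers):
        W = params[f"W{i}"]
        if config.spectral_norm and sn_vectors is not None:
            Wdata = W.data if isinstance(W, ad.Tensor) else np.asarray(W)
            u, v = _spectral_vectors(Wdata, sn_vectors[f"W{i}"])
            if update_sn:
                sn_vectors[f"W{i}"] = u
            # sigma = u^T W v as a graph scalar (u, v detached).
            sigma = ad.sum_(ad.astensor(W) * ad.Tensor(np.outer(u, v)))
            W = ad.astensor(W) * (sigma ** -1.0)
            if f"g{i}" in params:
                W = W * ad.astensor(params[f"g{i}"])
        h = h @ W + params[f"b{i}"]
        if i < config.critic_layers - 1:
            h = ad.leaky_relu(h, slope)
    return h


def gradient_penalty(critic_fn, x_real: np.ndarray, x_fake: np.ndarray,
                     y_onehot: np.ndarray, gp_weight: float,
                     rng: np.random.Generator):
    """lambda * mean((||grad_xhat D(xhat, y)||_2 - 1)^2).

    ``critic_fn(x_tensor, y_array) -> Tensor`` lets callers supply either
    the full spectrally-normalized critic or a bare linear map (used by
    the closed-form unit tests).  Interpolation draws eps ~ U[0,1] per
    sample: xhat = eps * x + (1 - eps) * x~.
    """
    if x_real.shape != x_fake.shape:
        raise ValueError("real and fake batches must share a shape")
    eps = rng.uniform(size=(x_real.shape[0], 1))
    xhat = ad.Tensor(eps * x_real + (1.0 - eps) * x_fake, requires_grad=True)
    d = critic_fn(xhat, y_onehot)
    (gx,) = ad.grad(ad.sum_(d), [xhat])
    sq = ad.sum_(gx * gx, axis=1)
    norm = (sq + 1e-12) ** 0.5
    return ad.mean_((norm - 1.0) ** 2.0) * gp_weight


class _RMSprop:
    """RMSprop (alpha 0.99, eps 1e-8).

    The second-moment accumulator starts at 1 rather than 0, damping the
    first few hundred updates to roughly ``lr * g``; it decays to the
    standard scale-free behavior as the accumulator fills.  Without the
    damping the generator's tanh output saturates irrecoverably before
    the critic becomes informative.
    """

    def __init__(self, params: dict, lr: float, alpha: float = 0.99,
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self.sq = {k: np.ones_like(v.data) for k, v in params.items()}

    def step(self, grads: dict) -> None:
        for k, g in grads.items():
            s = self.sq[k]
            s *= self.alpha
            s += (1 - self.alpha) * g * g
            self.params[k].data -= self.lr * g / (np.sqrt(s) + self.eps)


def _as_live(params: dict) -> dict:
    return {k: ad.Tensor(v, requires_grad=True) for k, v in params.items()}


def _as_const(params: dict) -> dict:
    return {k: ad.astensor(v.data if isinstance(v, ad.Tensor) else v)
            for k, v in params.items()}


def train_cwgan_gp(train: pd.DataFrame, config: GanConfig,
                   feature_names: list | None = None,
                   label_column: str = OUTCOME_COLUMN,
                   binary_mask: np.ndarray | None = None) -> GanState:
    """Run the cWGAN-GP training loop on a scaled training table.

    Expects continuous features inside (-1, 1) (robust-tanh space) and a
    binary label column.  Returns the trained state with the full
    per-step loss history; deterministic given ``config.seed``.
    """
    if feature_names is None:
        feature_names = [c for c in train.columns if c != label_column]
    X = train[feature_names].to_numpy(dtype=np.float64)
    yv = train[label_column].to_numpy(dtype=np.float64)
    labels = np.unique(yv)
    if len(labels) < 2:
        raise ValueError("training table must contain both classes")
    if binary_mask is None:
        binary_mask = np.array([set(np.unique(X[:, j])) <= {0.0, 1.0}
                                for j in range(X.shape[1])])
    state = init_networks(X.shape[1], config, seed=config.seed,
                          feature_names=feature_names,
                          binary_mask=binary_mask)
    rng = np.random.default_rng(config.seed + 1)

    gen_live = _as_live(state.gen_params)
    crit_live = _as_live(state.critic_params)
    opt_g = _RMSprop(gen_live, config.lr_g)
    opt_d = _RMSprop(crit_live, config.lr_d)
    n = len(X)
    m = min(config.batch_size, n)
    step = 0
    gen_iters_per_epoch = max(1, max(1, n // m) // config.n_critic)
    total_gen_iters = config.epochs * gen_iters_per_epoch
    ema_start = int(config.ema_start_fraction * total_gen_iters)
    ema: dict | None = None
    gen_iter_count = 0

    def check_finite(value: float, kind: str) -> None:
        if not np.isfinite(value):
            raise RuntimeError(
                f"non-finite {kind} loss at step {step}; last history: "
                f"{state.loss_history[-5:]}")

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        n_batches = max(1, n // m)
        # Each generator iteration consumes exactly n_critic critic
        # batches (cyclically when an epoch is shorter than n_critic).
        n_gen_iters = max(1, n_batches // config.n_critic)
        for g_iter in range(n_gen_iters):
            for t in range(config.n_critic):
                b = (g_iter * config.n_critic + t) % n_batches
                idx = order[b * m:(b + 1) * m]
                x_real = X[idx]
                y = _one_hot(yv[idx])
                z = rng.standard_normal((len(idx), config.noise_dim))
                x_fake = generator_forward(_as_const(gen_live), z, y,
                                           config).data
                d_real = critic_forward(crit_live, x_real, y, config,
                                        state.sn_vectors, update_sn=True)
                d_fake = critic_forward(crit_live, x_fake, y, config,
                                        state.sn_vectors)
                pen = gradient_penalty(
                    lambda xh, yh: critic_forward(crit_live, xh, yh, config,
                                                  state.sn_vectors),
                    x_real, x_fake, y, config.gp_weight, rng)
                loss_d = ad.mean_(d_fake) - ad.mean_(d_real) + pen
                check_finite(float(loss_d.data), "critic")
                names = list(crit_live)
                grads = ad.grad(loss_d, [crit_live[k] for k in names])
                opt_d.step({k: g.data for k, g in zip(names, grads)})
                state.loss_history.append((step, "critic", float(loss_d.data)))
                step += 1

            z = rng.standard_normal((len(idx), config.noise_dim))
            x_fake_t = generator_forward(gen_live, z, y, config)
            d_gen = critic_forward(_as_const(crit_live), x_fake_t, y,
                                   config, state.sn_vectors)
            loss_g = -ad.mean_(d_gen)
            check_finite(float(loss_g.data), "generator")
            names = list(gen_live)
            grads = ad.grad(loss_g, [gen_live[k] for k in names])
            opt_g.step({k: g.data for k, g in zip(names, grads)})
            gen_iter_count += 1
            if gen_iter_count >= ema_start:
                if ema is None:
                    ema = {k: v.data.copy() for k, v in gen_live.items()}
                else:
                    d = config.ema_decay
                    for k in ema:
                        ema[k] = d * ema[k] + (1.0 - d) * gen_live[k].data
            state.loss_history.append(
                (step, "generator", float(loss_g.data)))
            step += 1
        if (epoch + 1) % config.scheduler_step == 0:
            opt_g.lr *= config.scheduler_gamma
            opt_d.lr *= config.scheduler_gamma

    state.gen_params = {k: v.data for k, v in gen_live.items()}
    state.critic_params = {k: v.data for k, v in crit_live.items()}
    state.gen_params_ema = ema
    return state


def sample_synthetic(state: GanState, n: int, label: int,
                     seed: int = 0) -> pd.DataFrame:
    """Draw ``n`` synthetic rows conditioned on ``label``.

    Continuous outputs lie strictly inside (-1, 1); binary columns are
    snapped to the nearest of {0, 1}.  Deterministic given the seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    cols = list(state.feature_names) + [OUTCOME_COLUMN]
    if n == 0:
        return pd.DataFrame(columns=cols)
    rng = np.random.default_rng(seed)
    config = state.config
    z = rng.standard_normal((n, config.noise_dim))
    y = _one_hot(np.full(n, label))
    params = state.gen_params_ema or state.gen_params
    out = generator_forward(_as_const(params), z, y, config).data
    out = out.copy()
    if state.binary_mask.any():
        bm = state.binary_mask
        out[:, bm] = (out[:, bm] >= 0.5).astype(float)
    df = pd.DataFrame(out, columns=state.feature_names)
    df[OUTCOME_COLUMN] = float(label)
    return df


def assemble_dataset(train: pd.DataFrame, state: GanState,
                     mode: str = "balance",
                     n_synthetic_minority: int | None = None,
                     n_synthetic_majority: int | None = None,
                     label_column: str = OUTCOME_COLUMN,
                     seed: int = 0) -> pd.DataFrame:
    """Append synthetic rows to the training table.

    ``balance``: exactly (N_majority - N_minority) synthetic minority
    rows, yielding a 50.00% positive rate.  ``augment``: a synthetic
    block of both classes; default doubles the dataset with a 50/50
    synthetic block.  Appended rows carry ``synthetic=True``; original
    rows are preserved verbatim.
    """
    y = train[label_column].to_numpy()
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training table must contain both classes")
    minority, majority = (1, 0) if n_pos < n_neg else (0, 1)
    n_min, n_maj = min(n_pos, n_neg), max(n_pos, n_neg)
    base = train.copy()
    base["synthetic"] = False
    if mode == "balance":
        if n_min >= n_maj:
            raise ValueError("balance mode requires minority < majority")
        synth = sample_synthetic(state, n_maj - n_min, minority, seed=seed)
        synth["synthetic"] = True
        blocks = [base, synth]
    elif mode == "augment":
        if n_synthetic_minority is None and n_synthetic_majority is None:
            total = len(train)
            n_synthetic_minority = total // 2
            n_synthetic_majority = total - n_synthetic_minority
        n_synthetic_minority = n_synthetic_minority or 0
        n_synthetic_majority = n_synthetic_majority or 0
        s_min = sample_synthetic(state, n_synthetic_minority, minority,
                                 seed=seed)
        s_maj = sample_synthetic(state, n_synthetic_majority, majority,
                                 seed=seed + 1)
        for s in (s_min, s_maj):
            s["synthetic"] = True
        blocks = [base, s_min, s_maj]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = pd.concat(blocks, ignore_index=True)
    return out
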