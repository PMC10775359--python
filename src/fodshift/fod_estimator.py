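"""Trainable FOD regressor: six-direction input preparation, training,
fine-tuning, and inference.

The estimator maps the order-2 SH representation of six diffusion
measurements (normalized by the voxelwise mean b=0 signal) to the order-8
SH coefficients of the fiber orientation distribution.  The regressor is a
compact multilayer perceptron over a configurable spatial-context window:
each voxel's input stacks the six order-2 coefficients of every voxel in
its ``(2*context_radius+1)^3`` neighborhood, so the receptive field is
local and translation-invariant, and inference over sliding patches with
overlap averaging is exactly consistent.  Optimization is Adam with
decoupled weight decay, dropout on hidden activations, and model selection
at the epoch with the lowest validation MSE.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from itertools import combinations

import numpy as np

from .sh_core import SHCoefficientField, build_sh_basis, n_coeffs_for_lmax
from .synthetic_cohort import GradientScheme, SubjectPhantom

__all__ = [
    "EstimatorConfig",
    "TrainedEstimator",
    "select_six_directions",
    "prepare_input",
    "patch_offsets",
    "merge_patches",
    "train",
    "finetune",
    "predict",
]

SIX_SHELL_B = 1000.0  # shell shared by both site protocols
_B0_EPS = 1e-8
_EXHAUSTIVE_LIMIT = 50_000


@dataclass(frozen=True)
class EstimatorConfig:
    """Hyperparameters; training defaults follow the backbone recipe
    (lr 5e-5, weight decay 1e-3, dropout 0.1), fine-tuning the adaptation
    recipe (lr 5e-6, batch 10, 100 epochs).  ``epochs_train`` defaults to a
    desk-scale 150 (the full-scale recipe of 1000 remains configurable)."""

    patch_size: int = 16
    input_lmax: int = 2
    output_lmax: int = 8
    context_radius: int = 1
    hidden_channels: tuple[int, ...] = (64, 64)
    dropout: float = 0.1
    lr_train: float = 5e-5
    weight_decay: float = 1e-3
    batch_train: int = 35
    epochs_train: int = 150
    lr_finetune: float = 5e-6
    batch_finetune: int = 10
    epochs_finetune: int = 100
    wm_patch_min_frac: float = 0.3
    max_voxels_per_subject: int | None = None  # deterministic subsample cap
    seed: int = 0

    def __post_init__(self):
        if self.lr_finetune >= self.lr_train:
            raise ValueError("fine-tuning must use a reduced learning rate")
        if self.patch_size < 8 or self.patch_size % 2 != 0:
            raise ValueError("patch_size must be an even integer >= 8")

    @property
    def n_in(self) -> int:
        k = 2 * self.context_radius + 1
        return n_coeffs_for_lmax(self.input_lmax) * k**3

    @property
    def n_out(self) -> int:
        return n_coeffs_for_lmax(self.output_lmax)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# six-direction selection


def _design_cond(bvecs: np.ndarray, idx) -> float:
    B = build_sh_basis(bvecs[list(idx)], 2)
    return float(np.linalg.cond(B))


def select_six_directions(scheme: GradientScheme, shell_b: float = SIX_SHELL_B, seed: int = 0) -> np.ndarray:
    """Pick the six measurements of one shell whose order-2 SH design matrix
    has the smallest condition number.

    Exhaustive over all C(n, 6) subsets when that count is at most 50,000;
    otherwise greedy farthest-point seeding followed by best-improvement
    exchange (deterministic; the seed only perturbs tie-breaking order).
    """
    shell_idx = scheme.shell_indices(shell_b)
    shell_idx = shell_idx[scheme.bvals[shell_idx] > scheme.shell_tol]
    n = len(shell_idx)
    if n < 6:
        raise ValueError(f"shell b={shell_b} has only {n} directions")
    if n == 6:
        return np.array(shell_idx)
    bvecs = scheme.bvecs
    from math import comb

    if comb(n, 6) <= _EXHAUSTIVE_LIMIT:
        best = min(combinations(shell_idx, 6), key=lambda s: (_design_cond(bvecs, s), s))
        return np.array(best)
    rng = np.random.default_rng(seed)
    # farthest-point (antipodally symmetric metric) seeding
    order = list(rng.permutation(shell_idx))
    chosen = [order[0]]
    while len(chosen) < 6:
        best_i, best_d = None, -1.0
        for i in order:
            if i in chosen:
                continue
            d = min(1.0 - abs(bvecs[i] @ bvecs[j]) for j in chosen)
            if d > best_d:
                best_i, best_d = i, d
        chosen.append(best_i)
    current = sorted(chosen)
    current_cond = _design_cond(bvecs, current)
    improved = True
    while improved:
        improved = False
        for k in range(6):
            for cand in shell_idx:
                if cand in current:
                    continue
                trial = sorted(current[:k] + current[k + 1 :] + [cand])
                c = _design_cond(bvecs, trial)
                if c < current_cond - 1e-12:
                    current, current_cond = trial, c
                    improved = True
    return np.array(current)


# ---------------------------------------------------------------------------
# input preparation and patch bookkeeping


def prepare_input(
    dwi: np.ndarray,
    scheme: GradientScheme,
    six_indices,
    input_lmax: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize the six selected signals by the voxelwise mean b=0 signal
    and project them onto the order-``input_lmax`` SH basis (an exact 6x6
    solve at the default order 2).

    Returns ``(sh_field, valid_mask)``; voxels with a non-positive b0 are
    flagged invalid and excluded from losses downstream.
    """
    dwi = np.asarray(dwi, dtype=float)
    six_indices = np.asarray(list(six_indices), dtype=int)
    b0 = dwi[..., scheme.b0_mask].mean(axis=-1)
    valid = b0 > _B0_EPS
    six = dwi[..., six_indices] / np.maximum(b0, _B0_EPS)[..., None]
    B = build_sh_basis(scheme.bvecs[six_indices], input_lmax)
    # exact solve when square, least squares otherwise
    if B.shape[0] == B.shape[1]:
        coeffs = np.linalg.solve(B, six[..., None])[..., 0]
    else:
        coeffs = np.linalg.lstsq(B, six.reshape(-1, B.shape[0]).T, rcond=None)[0].T.reshape(
            six.shape[:-1] + (B.shape[1],)
        )
    coeffs[~valid] = 0.0
    return coeffs, valid


def patch_offsets(vol_shape, patch_size: int, stride: int) -> list[tuple[int, int, int]]:
    """Corner offsets of a sliding patch grid covering the volume.

    Offsets step by ``stride`` and the final offset per axis is clamped so
    the last patch touches the volume boundary.
    """
    out = []
    per_axis = []
    for s in vol_shape[:3]:
        if patch_size > s:
            raise ValueError(f"patch size {patch_size} exceeds volume extent {s}")
        ax = list(range(0, s - patch_size + 1, stride))
        if ax[-1] != s - patch_size:
            ax.append(s - patch_size)
        per_axis.append(ax)
    for x in per_axis[0]:
        for y in per_axis[1]:
            for z in per_axis[2]:
                out.append((x, y, z))
    return out


def merge_patches(patches: dict[tuple[int, int, int], np.ndarray], vol_shape, patch_size: int) -> np.ndarray:
    """Uniform overlap averaging of per-patch outputs into a volume."""
    first = next(iter(patches.values()))
    acc = np.zeros(tuple(vol_shape[:3]) + first.shape[3:])
    cnt = np.zeros(tuple(vol_shape[:3]))
    for (x, y, z), p in patches.items():
        acc[x : x + patch_size, y : y + patch_size, z : z + patch_size] += p
        cnt[x : x + patch_size, y : y + patch_size, z : z + patch_size] += 1
    if np.any(cnt == 0):
        raise ValueError("patch grid does not cover the volume")
    return acc / cnt[(...,) + (None,) * (acc.ndim - 3)]


def _context_features(sh_field: np.ndarray, coords: np.ndarray, radius: int) -> np.ndarray:
    """Gather flattened neighborhood inputs for given voxel coordinates."""
    pad = np.pad(sh_field, [(radius, radius)] * 3 + [(0, 0)], mode="reflect")
    offs = range(-radius, radius + 1)
    feats = []
    for dx in offs:
        for dy in offs:
            for dz in offs:
                feats.append(
                    pad[
                        coords[:, 0] + radius + dx,
                        coords[:, 1] + radius + dy,
                        coords[:, 2] + radius + dz,
                    ]
                )
    return np.concatenate(feats, axis=-1).astype(np.float32)


def _training_voxels(subject: SubjectPhantom, config: EstimatorConfig) -> np.ndarray:
    """Unique WM voxel coordinates covered by patches with sufficient WM."""
    stride = config.patch_size // 2
    wm = subject.wm_mask
    keep = np.zeros_like(wm)
    for (x, y, z) in patch_offsets(wm.shape, config.patch_size, stride):
        sl = (slice(x, x + config.patch_size), slice(y, y + config.patch_size), slice(z, z + config.patch_size))
        if wm[sl].mean() >= config.wm_patch_min_frac:
            keep[sl] |= wm[sl]
    return np.array(np.nonzero(keep)).T


def _subject_samples(subject: SubjectPhantom, six_indices, config: EstimatorConfig):
    sh_field, valid = prepare_input(subject.dwi, subject.scheme, six_indices, config.input_lmax)
    coords = _training_voxels(subject, config)
    coords = coords[valid[tuple(coords.T)]]
    cap = config.max_voxels_per_subject
    if cap is not None and len(coords) > cap:
        digest = int(hashlib.sha256(subject.subject_id.encode()).hexdigest()[:8], 16)
        rng = np.random.default_rng((config.seed, digest))
        coords = coords[rng.choice(len(coords), size=cap, replace=False)]
    X = _context_features(sh_field, coords, config.context_radius)
    Y = subject.gt_fod.coefficients[tuple(coords.T)].astype(np.float32)
    return X, Y


# ---------------------------------------------------------------------------
# the MLP and its optimizer


def _init_params(config: EstimatorConfig, rng) -> list[dict]:
    sizes = [config.n_in, *config.hidden_channels, config.n_out]
    params = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)).astype(np.float32)
        params.append({"w": w, "b": np.zeros(fan_out, dtype=np.float32)})
    return params


def _forward(params, X, dropout: float = 0.0, rng=None):
    """Forward pass; returns output and the cache needed for backprop."""
    cache = []
    h = X
    for i, layer in enumerate(params):
        z = h @ layer["w"] + layer["b"]
        last = i == len(params) - 1
        if not last:
            a = np.maximum(z, 0.0)
            if dropout > 0.0 and rng is not None:
                mask = (rng.random(a.shape) >= dropout).astype(np.float32) / (1.0 - dropout)
                a = a * mask
            else:
                mask = None
            cache.append((h, z, mask))
            h = a
        else:
            cache.append((h, z, None))
            h = z
    return h, cache


def _backward(params, cache, grad_out):
    grads = [None] * len(params)
    g = grad_out
    for i in reversed(range(len(params))):
        h, z, mask = cache[i]
        if i != len(params) - 1:
            if mask is not None:
                g = g * mask
            g = g * (z > 0)
        grads[i] = {"w": h.T @ g, "b": g.sum(axis=0)}
        if i > 0:
            g = g @ params[i]["w"].T
    return grads


class _Adam:
    """Adam with decoupled weight decay on the weight matrices."""

    def __init__(self, params, lr, weight_decay, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in p.items()} for p in params]
        self.v = [{k: np.zeros_like(v) for k, v in p.items()} for p in params]

    def step(self, params, grads):
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            for k in p:
                m[k] = self.b1 * m[k] + (1 - self.b1) * g[k]
                v[k] = self.b2 * v[k] + (1 - self.b2) * g[k] ** 2
                update = (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)
                if k == "w" and self.wd > 0:
                    update = update + self.wd * p[k]
                p[k] = (p[k] - self.lr * update).astype(np.float32)


@dataclass
class TrainedEstimator:
    """Parameters plus config, per-epoch history, and the selected epoch.

    ``feat_mean``/``feat_std`` standardize input features.  They are
    estimated on the training set and travel with the model, so a site
    shift reaches the network as a mis-standardized distribution;
    fine-tuning re-estimates them on the target subjects (as one updates
    batch-normalization statistics during domain adaptation) before
    continuing optimization.
    """

    params: list[dict]
    config: EstimatorConfig
    six_indices: np.ndarray
    history: list[dict]  # {"phase", "epoch", "train_mse", "val_mse"}
    selected_epoch: int
    feat_mean: np.ndarray | None = None
    feat_std: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        if self.feat_mean is None:
            return X
        return ((X - self.feat_mean) / self.feat_std).astype(np.float32)

    def mse(self, X: np.ndarray, Y: np.ndarray) -> float:
        pred, _ = _forward(self.params, self.standardize(X))
        return float(np.mean((pred - Y) ** 2))


def _run_epochs(
    params,
    X_train,
    Y_train,
    X_val,
    Y_val,
    config: EstimatorConfig,
    lr: float,
    batch: int,
    epochs: int,
    rng,
    phase: str,
    history: list[dict],
    select_on_val: bool = True,
):
    opt = _Adam(params, lr, config.weight_decay)
    n = X_train.shape[0]
    best = (np.inf, None, -1)
    warned_divergence = False
    loss_avg = None
    for epoch in range(epochs):
        order = rng.permutation(n)
        run_loss, n_batches = 0.0, 0
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            out, cache = _forward(params, X_train[idx], dropout=config.dropout, rng=rng)
            diff = out - Y_train[idx]
            run_loss += float(np.mean(diff**2))
            n_batches += 1
            grads = _backward(params, cache, (2.0 / diff.size) * diff)
            opt.step(params, grads)
        train_mse = run_loss / max(n_batches, 1)
        if loss_avg is None:
            loss_avg = train_mse
        else:
            if train_mse > 4.0 * loss_avg and not warned_divergence:
                import warnings

                warnings.warn(f"training loss diverging at epoch {epoch}", stacklevel=2)
                warned_divergence = True
            loss_avg = 0.9 * loss_avg + 0.1 * train_mse
        val_out, _ = _forward(params, X_val)
        val_mse = float(np.mean((val_out - Y_val) ** 2))
        history.append({"phase": phase, "epoch": epoch, "train_mse": train_mse, "val_mse": val_mse})
        if select_on_val and val_mse < best[0]:
            best = (val_mse, [{k: v.copy() for k, v in p.items()} for p in params], len(history) - 1)
    if select_on_val and best[1] is not None:
        return best[1], best[2]
    return params, len(history) - 1


def _stack_samples(subjects, six_indices, config):
    Xs, Ys = zip(*(_subject_samples(s, six_indices, config) for s in subjects))
    return np.concatenate(Xs), np.concatenate(Ys)


def train(
    config: EstimatorConfig,
    train_subjects: list[SubjectPhantom],
    val_subjects: list[SubjectPhantom],
    six_indices=None,
) -> TrainedEstimator:
    """Train from random initialization; returns the estimator at the epoch
    of lowest validation MSE.  Deterministic for a fixed config seed."""
    if not train_subjects or not val_subjects:
        raise ValueError("train and validation subject lists must be non-empty")
    if {s.subject_id for s in train_subjects} & {s.subject_id for s in val_subjects}:
        raise ValueError("train and validation subjects overlap")
    scheme = train_subjects[0].scheme
    if six_indices is None:
        six_indices = select_six_directions(scheme)
    ss = np.random.SeedSequence(config.seed)
    rng_init, rng_epochs = (np.random.default_rng(s) for s in ss.spawn(2))
    params = _init_params(config, rng_init)
    X_train, Y_train = _stack_samples(train_subjects, six_indices, config)
    X_val, Y_val = _stack_samples(val_subjects, six_indices, config)
    feat_mean = X_train.mean(axis=0)
    feat_std = X_train.std(axis=0) + 1e-6
    X_train = ((X_train - feat_mean) / feat_std).astype(np.float32)
    X_val = ((X_val - feat_mean) / feat_std).astype(np.float32)
    history: list[dict] = []
    params, sel = _run_epochs(
        params,
        X_train,
        Y_train,
        X_val,
        Y_val,
        config,
        config.lr_train,
        config.batch_train,
        config.epochs_train,
        rng_epochs,
        "train",
        history,
    )
    return TrainedEstimator(
        params=params,
        config=config,
        six_indices=np.asarray(six_indices),
        history=history,
        selected_epoch=sel,
        feat_mean=feat_mean,
        feat_std=feat_std,
        provenance={
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "train_subjects": [s.subject_id for s in train_subjects],
            "val_subjects": [s.subject_id for s in val_subjects],
        },
    )


def finetune(
    model: TrainedEstimator,
    target_subjects: list[SubjectPhantom],
    config: EstimatorConfig | None = None,
    six_indices=None,
) -> TrainedEstimator:
    """Adapt a trained model to target-domain subjects: re-estimate the
    input standardization statistics on the target data, then continue
    optimization at the reduced fine-tuning learning rate and batch size.

    With two or more subjects the last one is held out for validation-based
    epoch selection; with a single subject the final-epoch parameters are
    kept.  The input six-direction indices may differ from the source
    site's (the target scheme differs), but SH orders must match.
    """
    if not target_subjects:
        raise ValueError("need at least one target subject")
    config = model.config if config is None else config
    if (config.input_lmax, config.output_lmax) != (model.config.input_lmax, model.config.output_lmax):
        raise ValueError("fine-tuning config changes SH orders; incompatible with the model")
    if six_indices is None:
        six_indices = select_six_directions(target_subjects[0].scheme)
    params = [{k: v.copy() for k, v in p.items()} for p in model.params]
    ss = np.random.SeedSequence((config.seed, len(target_subjects), 0x5EED))
    rng = np.random.default_rng(ss)
    if len(target_subjects) >= 2:
        fit_subjects, val_subjects = target_subjects[:-1], target_subjects[-1:]
        select = True
    else:
        fit_subjects, val_subjects = target_subjects, target_subjects
        select = False
    X_all, _ = _stack_samples(target_subjects, six_indices, config)
    X_train, Y_train = _stack_samples(fit_subjects, six_indices, config)
    X_val, Y_val = _stack_samples(val_subjects, six_indices, config)
    # re-estimate the input standardization on the target domain (the
    # analogue of updating batch-normalization statistics when adapting a
    # model), using every available target subject
    feat_mean = X_all.mean(axis=0)
    feat_std = X_all.std(axis=0) + 1e-6
    X_train = ((X_train - feat_mean) / feat_std).astype(np.float32)
    X_val = ((X_val - feat_mean) / feat_std).astype(np.float32)
    history = list(model.history)
    params, sel = _run_epochs(
        params,
        X_train,
        Y_train,
        X_val,
        Y_val,
        config,
        config.lr_finetune,
        config.batch_finetune,
        config.epochs_finetune,
        rng,
        "finetune",
        history,
        select_on_val=select,
    )
    prov = dict(model.provenance)
    prov.update(
        {
            "finetune_subjects": [s.subject_id for s in target_subjects],
            "n_target_subjects": len(target_subjects),
        }
    )
    return TrainedEstimator(
        params=params,
        config=config,
        six_indices=np.asarray(six_indices),
        history=history,
        selected_epoch=sel,
        feat_mean=feat_mean if model.feat_mean is not None else None,
        feat_std=feat_std if model.feat_std is not None else None,
        provenance=prov,
    )


def predict(
    model: TrainedEstimator,
    subject: SubjectPhantom | None = None,
    dwi: np.ndarray | None = None,
    scheme: GradientScheme | None = None,
    six_indices=None,
) -> SHCoefficientField:
    """Estimate the FOD field of a full volume.

    The regressor is voxelwise over its context window, so sliding-window
    inference with uniform overlap averaging reduces exactly to one pass
    over all voxels; invalid (zero-b0) voxels yield zero coefficients.
    """
    if subject is not None:
        dwi, scheme = subject.dwi, subject.scheme
    if dwi is None or scheme is None:
        raise ValueError("provide a subject or (dwi, scheme)")
    if min(dwi.shape[:3]) < model.config.patch_size:
        raise ValueError(
            f"volume {dwi.shape[:3]} is smaller than patch size {model.config.patch_size}; pad the input"
        )
    idx = model.six_indices if six_indices is None else np.asarray(list(six_indices))
    sh_field, valid = prepare_input(dwi, scheme, idx, model.config.input_lmax)
    coords = np.array(np.nonzero(np.ones(dwi.shape[:3], dtype=bool))).T
    X = model.standardize(_context_features(sh_field, coords, model.config.context_radius))
    out, _ = _forward(model.params, X)
    vol = out.reshape(dwi.shape[:3] + (model.config.n_out,)).astype(float)
    vol[~valid] = 0.0
    return SHCoefficientField(lmax=model.config.output_lmax, coefficients=vol)
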