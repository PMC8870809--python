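"""Training loop, augmentation and dataset split for the V-NET.

Training follows the published TMTV setup: stochastic gradient descent
with learning rate 0.001 and momentum 0.9 on the soft dice loss, the
continuous TMTVprob map as the target, and one additional augmented copy
of each case (random translation, rotation about the axial axis, and
isotropic scaling, applied identically to CT, PET and target).  The
60/20/20 train/test/validation split is reproduced by a seeded shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .autograd import soft_dice
from .model import VNet, VnetConfig, build_model

__all__ = [
    "TrainingCase",
    "DatasetSplit",
    "AugmentParams",
    "soft_dice_loss",
    "augment",
    "split_dataset",
    "train",
    "save_weights",
    "load_weights",
]


def soft_dice_loss(pred: np.ndarray, truth: np.ndarray, eps: float = 1e-6) -> float:
    """Soft dice loss ``1 - (2*sum(p*t)+eps) / (sum(p)+sum(t)+eps)``.

    Accepts continuous maps in [0, 1]; on binary inputs with eps -> 0 this
    is exactly one minus the dice coefficient.
    """
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(truth, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    if p.min() < 0 or p.max() > 1 or t.min() < 0 or t.max() > 1:
        raise ValueError("inputs must lie in [0, 1]")
    return float(1.0 - (2.0 * (p * t).sum() + eps) / (p.sum() + t.sum() + eps))


@dataclass
class TrainingCase:
    """One preprocessed case: scaled (CT, PET) channels plus TMTVprob."""

    case_id: str
    inputs: np.ndarray  # (2, D, H, W) in [0, 1]
    target: np.ndarray  # (D, H, W) in [0, 1]

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=np.float32)
        self.target = np.asarray(self.target, dtype=np.float32)
        if self.inputs.ndim != 4 or self.inputs.shape[1:] != self.target.shape:
            raise ValueError(
                f"inputs {self.inputs.shape} and target {self.target.shape} disagree"
            )


@dataclass
class DatasetSplit:
    """Reproducible 60/20/20 partition of case ids."""

    train: list
    val: list
    test: list
    split_seed: int

    def all_ids(self) -> list:
        return list(self.train) + list(self.val) + list(self.test)


def split_dataset(case_ids: Sequence, seed: int) -> DatasetSplit:
    """Shuffle case ids with ``seed`` and split 60% train / 20% val /
    20% test (rounded; partition is disjoint and exhaustive)."""
    ids = list(case_ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n = len(ids)
    n_train = int(round(0.6 * n))
    n_val = int(round(0.2 * n))
    shuffled = [ids[i] for i in order]
    return DatasetSplit(
        train=shuffled[:n_train],
        val=shuffled[n_train : n_train + n_val],
        test=shuffled[n_train + n_val :],
        split_seed=seed,
    )


# ---------------------------------------------------------------------------
# augmentation

@dataclass
class AugmentParams:
    """One sampled rigid+scale transform (world-space parameters)."""

    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: float = 0.0  # about the axial (z) axis
    scale: float = 1.0


def sample_augment_params(cfg: VnetConfig, rng: np.random.Generator) -> AugmentParams:
    return AugmentParams(
        translation_mm=tuple(rng.uniform(-cfg.translation_mm, cfg.translation_mm, 3)),
        rotation_deg=float(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)),
        scale=float(rng.uniform(*cfg.scale_range)),
    )


def augment(
    pet: np.ndarray,
    ct: np.ndarray,
    truth: np.ndarray,
    seed: int | None = None,
    params: AugmentParams | None = None,
    spacing_mm: Sequence[float] = (4.0, 4.0, 4.0),
    cfg: VnetConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply one random translation+rotation+scaling to PET, CT and truth.

    The same transform is applied to all three volumes (trilinear
    interpolation; the truth TMTVprob is continuous-valued, so it is
    interpolated rather than re-binarized).  Either pass explicit
    ``params`` or a ``seed`` from which they are sampled.  Identity
    parameters return the inputs unchanged.
    """
    if params is None:
        if seed is None:
            raise ValueError("provide either params or a seed")
        params = sample_augment_params(cfg or VnetConfig(), np.random.default_rng(seed))

    shape = np.asarray(pet.shape, dtype=float)
    center = (shape - 1) / 2.0
    s = params.scale
    th = np.deg2rad(params.rotation_deg)
    # output voxel x maps to input voxel A @ (x - center - t_vox) + center;
    # A = Rz(-theta)/s so features rotate by +theta and dilate by s
    rot = np.array(
        [[np.cos(th), np.sin(th), 0.0], [-np.sin(th), np.cos(th), 0.0], [0.0, 0.0, 1.0]]
    )
    a = rot / s
    t_vox = np.asarray(params.translation_mm) / np.asarray(spacing_mm, dtype=float)
    offset = center - a @ (center + t_vox)

    def apply(vol: np.ndarray) -> np.ndarray:
        out = ndimage.affine_transform(
            np.asarray(vol, dtype=np.float32), a, offset=offset, order=1,
            mode="constant", cval=0.0,
        )
        return np.clip(out, 0.0, 1.0).astype(np.float32)

    return apply(pet), apply(ct), apply(truth)


def augment_case(case: TrainingCase, params: AugmentParams,
                 spacing_mm=(4.0, 4.0, 4.0)) -> TrainingCase:
    ct, pet = case.inputs[0], case.inputs[1]
    pet_a, ct_a, tr_a = augment(pet, ct, case.target, params=params, spacing_mm=spacing_mm)
    return TrainingCase(
        case_id=f"{case.case_id}+aug",
        inputs=np.stack([ct_a, pet_a], axis=0),
        target=tr_a,
    )


# ---------------------------------------------------------------------------
# training

def train(
    train_cases: Sequence[TrainingCase],
    cfg: VnetConfig,
    val_cases: Sequence[TrainingCase] = (),
    model: VNet | None = None,
    spacing_mm: Sequence[float] = (4.0, 4.0, 4.0),
    verbose: bool = False,
) -> tuple[dict[str, np.ndarray], dict]:
    """SGD training on the soft dice loss.

    Each case contributes itself plus ``cfg.augment_per_case`` augmented
    copies (generated once, up front).  Gradients are averaged over
    mini-batches of ``cfg.batch_size``; momentum ``cfg.momentum`` and
    learning rate ``cfg.learning_rate`` update the weights.  Per-epoch
    mean train and validation losses are logged; the weights of the best
    validation epoch (best train epoch when no validation cases are
    given) are returned together with the history.

    A non-finite loss aborts with the offending epoch index.
    """
    if len(train_cases) < 2:
        raise ValueError("need at least 2 training cases")
    rng = np.random.default_rng(cfg.seed)
    model = model or build_model(cfg)

    pool: list[TrainingCase] = list(train_cases)
    for case in train_cases:
        for _ in range(cfg.augment_per_case):
            pool.append(augment_case(case, sample_augment_params(cfg, rng), spacing_mm))

    velocity = {k: np.zeros_like(p.data) for k, p in model.parameters().items()}
    history: dict = {"train_loss": [], "val_loss": []}
    best_loss, best_state = np.inf, model.state_dict()

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(pool))
        losses = []
        for start in range(0, len(pool), cfg.batch_size):
            batch = [pool[i] for i in order[start : start + cfg.batch_size]]
            model.zero_grad()
            for case in batch:
                pred = model.forward(case.inputs)
                loss = soft_dice(pred, case.target[None], eps=cfg.dice_eps)
                loss.backward()
                losses.append(float(loss.data))
            for k, p in model.parameters().items():
                g = p.grad / len(batch)
                velocity[k] = cfg.momentum * velocity[k] - cfg.learning_rate * g
                p.data += velocity[k]
        train_loss = float(np.mean(losses))
        if not np.isfinite(train_loss):
            raise RuntimeError(f"non-finite training loss at epoch {epoch}")
        val_loss = evaluate_loss(model, val_cases, cfg.dice_eps) if val_cases else None
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        monitor = val_loss if val_loss is not None else train_loss
        if monitor < best_loss:
            best_loss, best_state = monitor, model.state_dict()
        if verbose:
            msg = f"epoch {epoch + 1}/{cfg.epochs}  train {train_loss:.4f}"
            if val_loss is not None:
                msg += f"  val {val_loss:.4f}"
            print(msg)

    history["best_loss"] = float(best_loss)
    model.load_state_dict(best_state)
    return best_state, history


def evaluate_loss(model: VNet, cases: Sequence[TrainingCase], eps: float = 1e-6) -> float:
    """Mean soft dice loss over cases (no gradient bookkeeping needed)."""
    losses = [
        soft_dice_loss(model.predict(c.inputs), c.target, eps=eps) for c in cases
    ]
    return float(np.mean(losses))


# ---------------------------------------------------------------------------
# weight persistence (native .npz plus JSON metadata sidecar)

def save_weights(path: str | Path, state: dict[str, np.ndarray],
                 cfg: VnetConfig, history: dict | None = None) -> None:
    import json
    from dataclasses import asdict

    path = Path(path)
    np.savez(path, **state)
    meta = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "epochs": cfg.epochs,
        "n_parameters": int(sum(v.size for v in state.values())),
    }
    if history is not None:
        meta["final_train_loss"] = history["train_loss"][-1]
        meta["best_loss"] = history.get("best_loss")
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=list))


def load_weights(path: str | Path) -> tuple[dict[str, np.ndarray], VnetConfig]:
    import json

    path = Path(path)
    state = dict(np.load(path))
    meta = json.loads(path.with_suffix(".json").read_text())
    raw_cfg = meta["config"]
    raw_cfg["scale_range"] = tuple(raw_cfg["scale_range"])
    return state, VnetConfig(**raw_cfg)
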