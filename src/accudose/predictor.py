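"""Voxel-wise accumulated-dose prediction from anatomy.

A slice-wise residual encoder–decoder maps three normalized axial channels —
planning CT, structure label map, distance-to-target map — to the
accumulated EQD2 dose of the combined EBRT+BT treatment.  Two presets share
one I/O contract: ``full`` (three resolution levels, for real cohorts) and
``reduced`` (two levels, small enough to train on a CPU).  Training uses
patient-level k-fold cross-validation, mean-squared error on normalized
dose, and Adam; every source of randomness (fold assignment, weight init,
shuffling) derives from the single seed in :class:`TrainingConfig`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .anatomy import DTTMap, LabelMap
from .errors import ConfigurationError, GeometryError, InvalidParameterError, ShapeError
from .grid import DoseGrid
from .nnet import Adam, ResEncDec, mse_loss

__all__ = [
    "Normalization",
    "PredictionSample",
    "TrainingConfig",
    "MODEL_PRESETS",
    "assemble_samples",
    "build_model",
    "train_kfold",
    "KFoldResult",
    "predict_dose",
    "mean_dose_baseline",
    "save_checkpoint",
    "load_checkpoint",
]

#: channel widths per resolution level
MODEL_PRESETS: dict[str, tuple[int, ...]] = {
    "full": (32, 64, 128),
    "reduced": (8, 16),
}


@dataclass(frozen=True)
class Normalization:
    """Channel scaling factors, recorded so predictions can be inverted.

    CT is windowed to ``[ct_low, ct_high]`` HU and mapped to [0, 1]; labels
    are divided by the largest label value, DTT by the cohort maximum
    distance, and dose by the summed prescription.
    """

    ct_low: float = -1000.0
    ct_high: float = 1000.0
    label_scale: float = 1.0
    dtt_scale: float = 1.0
    dose_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.ct_high <= self.ct_low:
            raise InvalidParameterError("CT window must have ct_high > ct_low")
        for name in ("label_scale", "dtt_scale", "dose_scale"):
            if getattr(self, name) <= 0 or not np.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite and > 0")

    def normalize_ct(self, ct: np.ndarray) -> np.ndarray:
        clipped = np.clip(ct, self.ct_low, self.ct_high)
        return (clipped - self.ct_low) / (self.ct_high - self.ct_low)

    def normalize_dose(self, dose: np.ndarray) -> np.ndarray:
        return np.asarray(dose, dtype=np.float64) / self.dose_scale

    def denormalize_dose(self, normalized: np.ndarray) -> np.ndarray:
        return np.asarray(normalized, dtype=np.float64) * self.dose_scale

    def to_dict(self) -> dict:
        return {
            "ct_low": self.ct_low,
            "ct_high": self.ct_high,
            "label_scale": self.label_scale,
            "dtt_scale": self.dtt_scale,
            "dose_scale": self.dose_scale,
        }


@dataclass(frozen=True)
class PredictionSample:
    """One axial training slice: 3 input channels and an optional dose target."""

    channels: np.ndarray  # (3, nx, ny), normalized
    target: np.ndarray | None  # (1, nx, ny), normalized dose
    patient_id: str
    slice_index: int

    def __post_init__(self) -> None:
        ch = np.asarray(self.channels, dtype=np.float64)
        if ch.ndim != 3 or ch.shape[0] != 3:
            raise ShapeError(f"channels must be (3, nx, ny), got {ch.shape}")
        if not np.all(np.isfinite(ch)):
            raise InvalidParameterError("channel values must be finite")
        object.__setattr__(self, "channels", ch)
        if self.target is not None:
            t = np.asarray(self.target, dtype=np.float64)
            if t.shape != (1, *ch.shape[1:]):
                raise ShapeError(f"target shape {t.shape} != (1, {ch.shape[1]}, {ch.shape[2]})")
            if not np.all(np.isfinite(t)):
                raise InvalidParameterError("target values must be finite")
            object.__setattr__(self, "target", t)


@dataclass(frozen=True)
class TrainingConfig:
    """Cross-validation and optimisation settings; ``seed`` feeds everything."""

    folds: int = 5
    epochs: int = 45
    learning_rate: float = 5e-3
    lr_decay: float = 0.5
    lr_decay_every: int = 15
    batch_size: int = 8
    seed: int = 0
    preset: str = "reduced"
    # left-right mirror augmentation; valid because pelvic anatomy and the
    # analytic dose are statistically symmetric about the sagittal plane
    augment_flips: bool = True
    # optional central (H, W) crop applied to training/validation slices;
    # the network is fully convolutional, so inference still runs full-size
    crop_hw: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ConfigurationError(f"folds must be >= 2, got {self.folds}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if not 0 < self.lr_decay <= 1 or self.lr_decay_every < 1:
            raise ConfigurationError("lr_decay must be in (0, 1] with lr_decay_every >= 1")
        if self.preset not in MODEL_PRESETS:
            raise ConfigurationError(f"unknown preset '{self.preset}'")


def assemble_samples(
    ct: np.ndarray,
    labels: LabelMap,
    dtt: DTTMap,
    dose: DoseGrid | None,
    normalization: Normalization,
    patient_id: str = "",
) -> list[PredictionSample]:
    """Stack normalized axial slices into (3, nx, ny) channel triples.

    One sample per z-slice; the target is the normalized accumulated dose
    when provided (training) or absent (inference).
    """
    geom = labels.geometry
    ct = np.asarray(ct, dtype=np.float64)
    if ct.shape != geom.shape:
        raise GeometryError(f"CT shape {ct.shape} != grid shape {geom.shape}")
    geom.require_same_grid(dtt.geometry)
    if dose is not None:
        geom.require_same_grid(dose.geometry)

    ct_n = normalization.normalize_ct(ct)
    lab_n = labels.values / normalization.label_scale
    dtt_n = dtt.values / normalization.dtt_scale
    dose_n = normalization.normalize_dose(dose.values) if dose is not None else None

    samples = []
    for k in range(geom.shape[2]):
        channels = np.stack([ct_n[:, :, k], lab_n[:, :, k], dtt_n[:, :, k]])
        target = dose_n[None, :, :, k] if dose_n is not None else None
        samples.append(
            PredictionSample(channels=channels, target=target, patient_id=patient_id, slice_index=k)
        )
    return samples


def build_model(preset: str = "reduced", seed: int = 0) -> ResEncDec:
    """Instantiate a preset network; identical seeds give identical weights."""
    if preset not in MODEL_PRESETS:
        raise ConfigurationError(f"unknown preset '{preset}'; choose from {sorted(MODEL_PRESETS)}")
    return ResEncDec(MODEL_PRESETS[preset], seed=seed)


def assign_folds(patient_ids: list[str], folds: int, seed: int) -> dict[str, int]:
    """Seeded patient-level fold assignment; each patient validates exactly once."""
    if len(patient_ids) < folds:
        raise ConfigurationError(f"{len(patient_ids)} patients cannot fill {folds} folds")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF01D]))
    order = list(np.array(sorted(patient_ids))[rng.permutation(len(patient_ids))])
    return {pid: i % folds for i, pid in enumerate(order)}


@dataclass
class KFoldResult:
    """Per-fold models, their held-out MAE (Gy) and training-loss histories."""

    models: list[ResEncDec]
    fold_assignment: dict[str, int]
    validation_mae_gy: list[float]
    loss_history: list[list[float]] = field(default_factory=list)


def _stack(
    samples: list[PredictionSample], crop_hw: tuple[int, int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.channels for s in samples]).astype(np.float32)
    t = np.stack([s.target for s in samples]).astype(np.float32)
    if crop_hw is not None:
        ch, cw = crop_hw
        h, w = x.shape[2:]
        if not (0 < ch <= h and 0 < cw <= w):
            raise ConfigurationError(f"crop {crop_hw} exceeds slice size {(h, w)}")
        i0, j0 = (h - ch) // 2, (w - cw) // 2
        x = x[:, :, i0 : i0 + ch, j0 : j0 + cw]
        t = t[:, :, i0 : i0 + ch, j0 : j0 + cw]
    return np.ascontiguousarray(x), np.ascontiguousarray(t)


def _train_one(
    model: ResEncDec,
    x: np.ndarray,
    t: np.ndarray,
    config: TrainingConfig,
    rng: np.random.Generator,
) -> list[float]:
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history = []
    n = x.shape[0]
    for epoch in range(config.epochs):
        opt.lr = config.learning_rate * config.lr_decay ** (epoch // config.lr_decay_every)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, tb = x[idx], t[idx]
            if config.augment_flips:
                flip = rng.random(len(idx)) < 0.5
                xb, tb = xb.copy(), tb.copy()
                xb[flip] = xb[flip, :, ::-1]  # mirror the left-right axis
                tb[flip] = tb[flip, :, ::-1]
            pred = model.forward(xb)
            loss, dy = mse_loss(pred, tb)
            model.backward(dy)
            opt.step(model.gradients())
            epoch_loss += loss * len(idx)
        history.append(epoch_loss / n)
    return history


def train_kfold(
    cohort: dict[str, list[PredictionSample]],
    config: TrainingConfig,
    normalization: Normalization,
) -> KFoldResult:
    """Patient-level k-fold training of the dose-prediction network.

    Patients are partitioned into ``config.folds`` seeded folds; for each
    fold a fresh model is trained on the out-of-fold patients and scored on
    the held-out ones.  The reported per-fold MAE is the mean absolute dose
    error in Gy over all validation voxels (denormalized).
    """
    for pid, samples in cohort.items():
        if any(s.target is None for s in samples):
            raise ConfigurationError(f"patient '{pid}' has samples without dose targets")
    fold_of = assign_folds(list(cohort), config.folds, config.seed)
    seeds = np.random.SeedSequence([config.seed, 0x7EA1]).spawn(config.folds)

    models, maes, histories = [], [], []
    for fold in range(config.folds):
        train_samples = [s for pid, ss in cohort.items() if fold_of[pid] != fold for s in ss]
        val_samples = [s for pid, ss in cohort.items() if fold_of[pid] == fold for s in ss]
        x_tr, t_tr = _stack(train_samples, config.crop_hw)
        x_va, t_va = _stack(val_samples, config.crop_hw)

        model = build_model(config.preset, seed=config.seed * config.folds + fold)
        rng = np.random.default_rng(seeds[fold])
        history = _train_one(model, x_tr, t_tr, config, rng)

        pred_va = _forward_batched(model, x_va)
        mae = float(np.mean(np.abs(pred_va - t_va))) * normalization.dose_scale
        models.append(model)
        maes.append(mae)
        histories.append(history)
    return KFoldResult(
        models=models, fold_assignment=fold_of, validation_mae_gy=maes, loss_history=histories
    )


def _forward_batched(model: ResEncDec, x: np.ndarray, chunk: int = 16) -> np.ndarray:
    return np.concatenate([model.forward(x[i : i + chunk]) for i in range(0, len(x), chunk)])


def predict_dose(
    model: ResEncDec,
    ct: np.ndarray,
    labels: LabelMap,
    dtt: DTTMap,
    normalization: Normalization,
) -> DoseGrid:
    """Slice-wise inference assembled back onto the input geometry.

    Outputs are denormalized to Gy and negative values clamped to zero.
    """
    samples = assemble_samples(ct, labels, dtt, None, normalization)
    x = np.stack([s.channels for s in samples])
    pred = _forward_batched(model, x)[:, 0]  # (nz, nx, ny)
    values = normalization.denormalize_dose(np.moveaxis(pred, 0, 2))
    return DoseGrid(values=np.clip(values, 0.0, None), geometry=labels.geometry)


def mean_dose_baseline(doses: list[DoseGrid]) -> DoseGrid:
    """Cohort-mean dose map: the no-anatomy reference predictor."""
    if not doses:
        raise ConfigurationError("at least one dose grid is required")
    geom = doses[0].geometry
    for d in doses[1:]:
        geom.require_same_grid(d.geometry)
    return DoseGrid(values=np.mean([d.values for d in doses], axis=0), geometry=geom)


# ---------------------------------------------------------------------------
# Checkpointing: .npz weights plus a JSON sidecar
# ---------------------------------------------------------------------------

def save_checkpoint(
    model: ResEncDec,
    path: str | Path,
    normalization: Normalization,
    *,
    preset: str,
    seed: int,
    fold_assignment: dict[str, int] | None = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "preset": preset,
        "seed": seed,
        "widths": list(model.widths),
        "normalization": normalization.to_dict(),
        "fold_assignment": fold_assignment or {},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> tuple[ResEncDec, Normalization, dict]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    model = ResEncDec(tuple(sidecar["widths"]), seed=int(sidecar["seed"]))
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_arrays([data[f"param_{i}"] for i in range(len(data.files))])
    norm = Normalization(**sidecar["normalization"])
    return model, norm, sidecar
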