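"""Training regimes, per-complex aggregation and multi-model consensus.

Three regimes are supported, all minimising mean squared error on the pK
scale with Adam:

``crystal_only``
    one voxelized crystallographic pose per complex per epoch;
``md_augmented``
    the crystal pose plus every available trajectory frame, each treated as
    an independent sample labeled with the parent complex's affinity;
``spatio_temporal``
    exactly one whole-simulation grid sequence per complex per epoch, the
    replicate drawn uniformly at random with the epoch rng.

During training one random rotation is drawn per sample per epoch (no
rotation at evaluation).  Per-complex predictions are the arithmetic mean of
the entity-level predictions (frames for 3-D models, whole simulations for
4-D models), and the ensemble consensus is the mean of those per-complex
predictions over model replicates.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (ComplexFrame, Manifest, PredictionSet, Trajectory,
                        CRYSTAL_REPLICATE)
from .errors import GridbindError, LeakageError
from .featurize import (KEEP_MODES, CENTERINGS, Rotation, encode_frame,
                        random_rotation, voxelize_points)
from .models import ModelConfig, build_model
from .nn import Adam, Tensor, mse_loss

REGIMES = ("crystal_only", "md_augmented", "spatio_temporal")
ROTATION_POLICIES = ("none", "random24", "random_so3")


@dataclass
class TrainingConfig:
    regime: str = "md_augmented"
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    rotation: str = "random24"
    seed: int = 0
    n_model_replicates: int = 10
    patience: int = 10
    centering: str = "pocket"
    keep: str = "complex"
    edge_A: float = 25.0
    resolution_A: float = 1.0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise GridbindError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        if self.epochs < 1:
            raise GridbindError("epochs must be >= 1")
        if self.batch_size < 1:
            raise GridbindError("batch_size must be >= 1")
        if self.rotation not in ROTATION_POLICIES:
            raise GridbindError(f"rotation must be one of {ROTATION_POLICIES}")
        if self.keep not in KEEP_MODES:
            raise GridbindError(f"keep must be one of {KEEP_MODES}")
        if self.centering not in CENTERINGS:
            raise GridbindError(f"centering must be one of {CENTERINGS}")
        if self.n_model_replicates < 1:
            raise GridbindError("n_model_replicates must be >= 1")


@dataclass
class _Encoded:
    """Cached per-roster encoding: features and the ligand mask."""

    feats: np.ndarray
    lig_mask: np.ndarray


@dataclass
class ComplexEntry:
    """Everything the trainer needs about one complex."""

    crystal: ComplexFrame
    trajectories: list[Trajectory] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.center = self.crystal.ligand_center()
        self._crystal_enc: _Encoded | None = None
        self._traj_enc: _Encoded | None = None

    def crystal_encoding(self) -> _Encoded:
        if self._crystal_enc is None:
            _, feats = encode_frame(self.crystal)
            self._crystal_enc = _Encoded(feats, self.crystal.roles() == "ligand")
        return self._crystal_enc

    def traj_encoding(self) -> _Encoded:
        if self._traj_enc is None:
            t = self.trajectories[0]
            _, feats = encode_frame(t.frame(0))
            roles = np.array([a.role for a in t.topology])
            self._traj_enc = _Encoded(feats, roles == "ligand")
        return self._traj_enc


class AffinityData:
    """Complex entries plus the manifest, the unit the trainer consumes."""

    def __init__(self, entries: dict[str, ComplexEntry], manifest: Manifest):
        self.entries = entries
        self.manifest = manifest
        missing = [cid for cid in manifest.ids() if cid not in entries]
        if missing:
            raise GridbindError(f"manifest lists complexes with no data: {missing[:5]}...")

    @classmethod
    def from_synthetic(cls, dataset, frame_stride: int = 1,
                       replicates: int | None = None) -> "AffinityData":
        """Adapt a :class:`~gridbind.synthetic.SyntheticDataset`.

        ``frame_stride`` subsamples trajectory frames and ``replicates``
        limits how many replicate trajectories are exposed to training
        (desk-scale control of the augmentation factor).
        """
        entries = {}
        for cid, crystal in dataset.crystals.items():
            trajs = dataset.trajectories.get(cid, [])
            if replicates is not None:
                trajs = trajs[:replicates]
            if frame_stride > 1:
                trajs = [Trajectory(t.complex_id, t.replicate_id, t.topology,
                                    t.coords[::frame_stride],
                                    t.frame_indices[::frame_stride], t.label_pk)
                         for t in trajs]
            entries[cid] = ComplexEntry(crystal, trajs)
        return cls(entries, dataset.manifest)

    def labels(self) -> dict[str, float]:
        return self.manifest.labels()


#: sample descriptor: (complex_id, kind, replicate_position, frame_position)
Sample = tuple


def build_epoch_samples(data: AffinityData, regime: str,
                        rng: np.random.Generator, split: str = "train") -> list[Sample]:
    """The sample list for one epoch of the given regime."""
    if regime not in REGIMES:
        raise GridbindError(f"regime must be one of {REGIMES}")
    ids = sorted(data.manifest.ids(split))
    samples: list[Sample] = []
    if regime == "spatio_temporal":
        missing = [cid for cid in ids if not data.entries[cid].trajectories]
        if missing:
            raise GridbindError(f"spatio_temporal regime but no trajectory for: {missing}")
        for cid in ids:
            r = int(rng.integers(len(data.entries[cid].trajectories)))
            samples.append((cid, "sequence", r, -1))
        return samples
    for cid in ids:
        samples.append((cid, "crystal", -1, -1))
        if regime == "md_augmented":
            for r, traj in enumerate(data.entries[cid].trajectories):
                for t in range(traj.n_frames):
                    samples.append((cid, "frame", r, t))
    return samples


def _frame_grid(coords: np.ndarray, enc: _Encoded, all_lig_coords: np.ndarray,
                cfg: TrainingConfig, center: np.ndarray,
                rotation: Rotation | None) -> np.ndarray:
    keep_mask = {"complex": slice(None),
                 "protein_only": ~enc.lig_mask,
                 "ligand_only": enc.lig_mask}[cfg.keep]
    sel_coords = coords[keep_mask]
    sel_feats = enc.feats[keep_mask]
    lig_coords = all_lig_coords
    if rotation is not None:
        sel_coords = (sel_coords - center) @ rotation.matrix.T + center
        lig_coords = (lig_coords - center) @ rotation.matrix.T + center
    box_center = center if cfg.centering == "pocket" else lig_coords.mean(axis=0)
    grid = voxelize_points(sel_coords, sel_feats, box_center, cfg.edge_A,
                           cfg.resolution_A, cfg.centering, out_dtype=np.float32)
    return grid.values


def sample_to_input(data: AffinityData, sample: Sample, cfg: TrainingConfig,
                    rotation: Rotation | None) -> np.ndarray:
    """Voxelize one epoch sample (a grid, or a (T, C, D, D, D) sequence)."""
    cid, kind, r, t = sample
    entry = data.entries[cid]
    if kind == "crystal":
        enc = entry.crystal_encoding()
        coords = entry.crystal.coords()
        return _frame_grid(coords, enc, coords[enc.lig_mask], cfg, entry.center, rotation)
    traj = entry.trajectories[r]
    enc = entry.traj_encoding()
    if kind == "frame":
        coords = traj.coords[t]
        return _frame_grid(coords, enc, coords[enc.lig_mask], cfg, entry.center, rotation)
    if kind == "sequence":
        frames = [_frame_grid(traj.coords[i], enc, traj.coords[i][enc.lig_mask],
                              cfg, entry.center, rotation)
                  for i in range(traj.n_frames)]
        return np.stack(frames)
    raise GridbindError(f"unknown sample kind {kind!r}")


def _draw_rotation(cfg: TrainingConfig, rng: np.random.Generator) -> Rotation | None:
    if cfg.rotation == "none":
        return None
    return random_rotation(rng, "right_angle" if cfg.rotation == "random24" else "so3")


def _assert_no_leakage(manifest: Manifest) -> None:
    manifest.check()


@dataclass
class TrainedEnsemble:
    """One trained model per replicate, with seeds and per-epoch histories."""

    models: list
    histories: list[list[dict]]
    seeds: list[int]
    model_config: ModelConfig
    training_config: TrainingConfig


def predict_entities(model, data: AffinityData, ids, mode: str,
                     cfg: TrainingConfig, model_replicate: int = 0,
                     batch_size: int = 32) -> PredictionSet:
    """Eval-mode predictions for every entity of the listed complexes.

    ``mode`` selects the entity type: ``crystal`` poses, individual
    trajectory ``frames``, or whole-simulation ``sequences`` (one prediction
    per replicate, ``frame_index == -1``).  No rotation is applied.
    """
    rows, inputs = [], []
    for cid in sorted(ids):
        entry = data.entries[cid]
        if mode == "crystal":
            inputs.append(sample_to_input(data, (cid, "crystal", -1, -1), cfg, None))
            rows.append({"complex_id": cid, "replicate_id": CRYSTAL_REPLICATE, "frame_index": 0})
        elif mode == "frames":
            for r, traj in enumerate(entry.trajectories):
                for t in range(traj.n_frames):
                    inputs.append(sample_to_input(data, (cid, "frame", r, t), cfg, None))
                    rows.append({"complex_id": cid, "replicate_id": traj.replicate_id,
                                 "frame_index": int(traj.frame_indices[t])})
        elif mode == "sequences":
            for r, traj in enumerate(entry.trajectories):
                inputs.append(sample_to_input(data, (cid, "sequence", r, -1), cfg, None))
                rows.append({"complex_id": cid, "replicate_id": traj.replicate_id,
                             "frame_index": -1})
        else:
            raise GridbindError(f"unknown prediction mode {mode!r}")
    if not rows:
        raise GridbindError("no entities to predict")
    preds = model.predict(np.stack(inputs), batch_size=batch_size)
    for row, p in zip(rows, preds):
        row["model_replicate"] = model_replicate
        row["predicted_pk"] = float(p)
    return PredictionSet.from_rows(rows)


def predict_per_complex(predictions: PredictionSet) -> pd.Series:
    """Per-complex prediction: mean of the entity-level predictions."""
    return predictions.per_complex()


def consensus(per_model_predictions: list[PredictionSet]) -> pd.Series:
    """Consensus: mean over model replicates of the per-complex predictions."""
    if not per_model_predictions:
        raise GridbindError("consensus needs at least one model's predictions")
    series = [p.per_complex() for p in per_model_predictions]
    return pd.concat(series, axis=1).mean(axis=1)


def _entity_mode(regime: str) -> str:
    return {"crystal_only": "crystal", "md_augmented": "frames",
            "spatio_temporal": "sequences"}[regime]


def _val_predictions(model, data, ids, cfg) -> pd.Series:
    if cfg.regime == "md_augmented":
        parts = [predict_entities(model, data, ids, "crystal", cfg)]
        if any(data.entries[c].trajectories for c in ids):
            parts.append(predict_entities(model, data, ids, "frames", cfg))
        return PredictionSet.concat(parts).per_complex()
    return predict_entities(model, data, ids, _entity_mode(cfg.regime), cfg).per_complex()


def train(model_config: ModelConfig, training_config: TrainingConfig,
          data: AffinityData, callback=None) -> TrainedEnsemble:
    """Train ``n_model_replicates`` independently seeded models.

    Hard-fails before any optimization if a complex id crosses the
    train/validation boundary.  Per replicate, the checkpoint with the lowest
    per-complex validation RMSE is retained; histories record per-epoch
    train loss and validation RMSE / Pearson R.
    """
    cfg = training_config
    _assert_no_leakage(data.manifest)
    train_ids = data.manifest.ids("train")
    val_ids = data.manifest.ids("val")
    if not train_ids or not val_ids:
        raise GridbindError("both train and val splits must be non-empty")
    needs_sequence = model_config.family in ("lrcn", "convlstm")
    if needs_sequence != (cfg.regime == "spatio_temporal"):
        raise GridbindError(f"family {model_config.family!r} is incompatible with "
                            f"regime {cfg.regime!r}")
    labels = data.labels()
    models, histories, seeds = [], [], []
    for rep in range(cfg.n_model_replicates):
        seed_rep = int(cfg.seed + 10007 * rep)
        seeds.append(seed_rep)
        model = build_model(model_config, seed=seed_rep)
        train_labels = np.array([labels[c] for c in train_ids])
        model.set_output_transform(float(train_labels.mean()),
                                   float(max(train_labels.std(), 1e-6)))
        optim = Adam(model.parameters(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
        best_state, best_rmse, best_epoch = model.state_dict(), np.inf, -1
        history = []
        for epoch in range(cfg.epochs):
            _assert_no_leakage(data.manifest)
            rng = np.random.default_rng([seed_rep, epoch])
            samples = build_epoch_samples(data, cfg.regime, rng, "train")
            rng.shuffle(samples)
            model.train()
            losses = []
            bs = 1 if cfg.regime == "spatio_temporal" else cfg.batch_size
            for lo in range(0, len(samples), bs):
                batch = samples[lo:lo + bs]
                grids = np.stack([sample_to_input(data, s, cfg, _draw_rotation(cfg, rng))
                                  for s in batch])
                y = np.array([labels[s[0]] for s in batch], dtype=np.float32)
                pred = model(Tensor(grids.astype(model_config.np_dtype())))
                loss = mse_loss(pred, y)
                optim.zero_grad()
                loss.backward()
                optim.step()
                losses.append(float(loss.data) * len(batch))
            val_pred = _val_predictions(model, data, val_ids, cfg)
            val_truth = np.array([labels[c] for c in val_pred.index])
            val_rmse = float(np.sqrt(np.mean((val_pred.to_numpy() - val_truth) ** 2)))
            if np.std(val_pred.to_numpy()) > 0 and np.std(val_truth) > 0:
                val_r = float(np.corrcoef(val_pred.to_numpy(), val_truth)[0, 1])
            else:
                val_r = None  # undefined correlation, flagged missing
            record = {"replicate": rep, "epoch": epoch,
                      "train_loss": float(np.sum(losses) / len(samples)),
                      "val_rmse": val_rmse, "val_pearson_r": val_r}
            history.append(record)
            if callback is not None:
                callback(record)
            if val_rmse < best_rmse:
                best_rmse, best_state, best_epoch = val_rmse, model.state_dict(), epoch
            elif epoch - best_epoch >= cfg.patience:
                break
        model.load_state_dict(best_state)
        model.eval()
        models.append(model)
        histories.append(history)
    return TrainedEnsemble(models, histories, seeds, model_config, cfg)
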