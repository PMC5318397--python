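"""End-to-end experiment orchestration: generate -> train -> analyze -> predict.

Model variants are named with a compact label grammar, hyphen-joined tokens:

    Norm          per-sector unit-norm input (all-zero rows dropped)
    SP<k>         spatial sparsity, top-k per sample, at a hidden layer
    LT<p>%        lifetime sparsity, top p percent per unit across the batch
    DL            dense layer (no sparsifier)
    Mask          reconstruction error restricted to the visible sectors

One sparsity token means a 3-layer net (input-latent-output) with that
sparsifier at the latent layer; two tokens mean a 5-layer net where the first
token applies to the 2nd and 4th layers and the second to the latent layer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from placegrid import analysis, prediction
from placegrid.arena import (
    ArenaConfig,
    BagDataset,
    boxes_to_frame,
    build_bag_dataset,
    place_boxes,
    visibility_table,
)
from placegrid.autoencoder import (
    AEConfig,
    AEWeights,
    LifetimeSparsity,
    SpatialSparsity,
    train,
)

logger = logging.getLogger(__name__)

_SPARSITY_TOKEN = re.compile(r"^(SP(?P<k>\d+)|LT(?P<p>\d+(?:\.\d+)?)%|DL)$")


def parse_label(
    label: str,
    input_dim: int,
    latent_dim: int = 30,
    *,
    epochs: int = 100,
    batch_size: int = 1000,
    learning_rate: float = 0.015,
    optimizer: str = "adagrad",
    lr_schedule: str = "constant",
    seed: int = 0,
) -> AEConfig:
    """Build an :class:`AEConfig` from a hyphenated variant label."""
    tokens = label.split("-")
    normalize = False
    masked = False
    if tokens and tokens[0] == "Norm":
        normalize = True
        tokens = tokens[1:]
    if tokens and tokens[-1] == "Mask":
        masked = True
        tokens = tokens[:-1]
    specs = []
    for tok in tokens:
        m = _SPARSITY_TOKEN.match(tok)
        if not m:
            raise ValueError(f"unrecognized token {tok!r} in label {label!r}")
        if tok == "DL":
            specs.append(None)
        elif m.group("k") is not None:
            specs.append(SpatialSparsity(int(m.group("k"))))
        else:
            specs.append(LifetimeSparsity(float(m.group("p"))))
    if len(specs) == 1:
        dims = (input_dim, latent_dim, input_dim)
        sparsity = (specs[0],)
    elif len(specs) == 2:
        mid = int(round((input_dim - latent_dim) / 2))
        dims = (input_dim, mid, latent_dim, mid, input_dim)
        sparsity = (specs[0], specs[1], specs[0])
    else:
        raise ValueError(
            f"label {label!r} must contain one or two sparsity tokens, got {len(specs)}"
        )
    return AEConfig(
        layer_dims=dims,
        sparsity=sparsity,
        masked_loss=masked,
        normalize=normalize,
        epochs=epochs,
        batch_size=batch_size,
        learning_rate=learning_rate,
        optimizer=optimizer,
        lr_schedule=lr_schedule,
        seed=seed,
        label=label,
    )


@dataclass
class ExperimentSpec:
    """Everything needed to reproduce a full run from a single seed."""

    arena: ArenaConfig = field(default_factory=ArenaConfig)
    models: tuple[str, ...] = ("Norm-LT3.33%-LT3.33%-Mask",)
    mask_widths: tuple[int, ...] = (1, 3, 5, 7, 9, 11, 13, 15, 17, 18)
    latent_dim: int = 30
    epochs: int = 100
    batch_size: int = 1000
    learning_rate: float = 0.015
    optimizer: str = "adagrad"
    lr_schedule: str = "constant"
    pipeline_model: str = "Norm-LT6.66%-Mask"
    pipeline_mask_width: int = 11
    predict_resolution: int = 150
    predict_n: int = 60
    predict_steps: int = 200
    predict_directions: tuple[float, ...] = (0.0,)
    pls_components: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.models)) != len(self.models):
            raise ValueError("model labels must be unique")
        for label in set(self.models) | {self.pipeline_model}:
            parse_label(label, self.arena.input_dim, self.latent_dim)

    def ae_config(self, label: str, seed: int | None = None) -> AEConfig:
        return parse_label(
            label,
            self.arena.input_dim,
            self.latent_dim,
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            optimizer=self.optimizer,
            lr_schedule=self.lr_schedule,
            seed=self.seed if seed is None else seed,
        )

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["arena"] = dataclasses.asdict(self.arena)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExperimentSpec":
        d = dict(d)
        arena_d = dict(d.pop("arena", {}))
        for key in ("box_half_extent", "band"):
            if key in arena_d:
                arena_d[key] = tuple(arena_d[key])
        for key in ("models", "mask_widths", "predict_directions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(arena=ArenaConfig(**arena_d), **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def manifest(self) -> dict[str, Any]:
        payload = self.to_dict()
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()
        return {"spec": payload, "config_hash": digest, "version": 1}


def field_of_view_label(v: int, config: ArenaConfig) -> int:
    """Total viewing angle through a v-sector window, as a whole-degree label."""
    return int(round(config.field_of_view_deg(v)))


def train_variant(
    spec: ExperimentSpec,
    label: str,
    v: int,
    dataset: BagDataset | None = None,
    seed: int | None = None,
) -> tuple[AEWeights, BagDataset, list[float]]:
    """Train one model variant at one mask width; returns weights, data, loss."""
    cfg = spec.ae_config(label, seed=seed)
    if dataset is None:
        boxes = place_boxes(spec.arena)
        dataset = build_bag_dataset(spec.arena, boxes, v=v, normalize=cfg.normalize)
    active = ~dataset.dropped
    loss_mask = dataset.loss_mask()[active] if cfg.masked_loss else None
    weights, history = train(dataset.X[active], cfg, loss_mask=loss_mask)
    return weights, dataset, history


def run_table1_sweep(
    spec: ExperimentSpec, out_dir: str | Path | None = None
) -> pd.DataFrame:
    """Dead-unit census over (model variant x mask width).

    Trains one model per cell and counts latent units that never respond;
    a failed cell is recorded as NA and the sweep continues.  Columns are
    labelled by total viewing angle in degrees.
    """
    boxes = place_boxes(spec.arena)
    vis = visibility_table(spec.arena, boxes)
    datasets: dict[tuple[int, bool], BagDataset] = {}
    columns = [field_of_view_label(v, spec.arena) for v in spec.mask_widths]
    table = pd.DataFrame(index=list(spec.models), columns=columns, dtype="object")
    for label in spec.models:
        for v in spec.mask_widths:
            cfg = spec.ae_config(label)
            key = (v, cfg.normalize)
            if key not in datasets:
                datasets[key] = build_bag_dataset(
                    spec.arena, boxes, v=v, normalize=cfg.normalize, vis=vis
                )
            try:
                weights, dataset, _ = train_variant(
                    spec, label, v, dataset=datasets[key]
                )
                tensor = analysis.response_tensor(weights, dataset)
                dead = analysis.count_dead_units(tensor)
            except Exception:
                logger.exception("sweep cell (%s, v=%d) failed", label, v)
                dead = pd.NA
            table.loc[label, field_of_view_label(v, spec.arena)] = dead
            logger.info("sweep %s v=%d -> dead=%s", label, v, dead)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "dead_units.csv", index_label="model")
    return table


def run_full_pipeline(spec: ExperimentSpec, out_dir: str | Path) -> Path:
    """Generate, train, analyze, and predict; persist every stage.

    Stage failures abort with the stage name; artifacts of completed stages
    remain on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(spec.manifest(), indent=2))
    stage = "generate"
    try:
        boxes = place_boxes(spec.arena)
        boxes_to_frame(boxes).to_csv(out / "boxes.csv", index=False)
        cfg = spec.ae_config(spec.pipeline_model)
        dataset = build_bag_dataset(
            spec.arena, boxes, v=spec.pipeline_mask_width, normalize=cfg.normalize
        )
        dataset.save(out / "dataset")

        stage = "train"
        weights, dataset, history = train_variant(
            spec, spec.pipeline_model, spec.pipeline_mask_width, dataset=dataset
        )
        weights.save(out / "weights", config=cfg)
        pd.DataFrame(
            {"epoch": np.arange(1, len(history) + 1), "loss": history}
        ).to_csv(out / "weights" / "training_log.csv", index=False)

        stage = "analyze"
        tensor = analysis.response_tensor(weights, dataset)
        np.savez_compressed(out / "responses.npz", tensor=tensor.values)
        summary = {
            "dead_units": analysis.count_dead_units(tensor),
            "mean_winner_invariance": float(
                analysis.winner_invariance_map(tensor).mean()
            ),
        }
        try:
            lat = analysis.lattice_summary(tensor)
            summary["polygon_counts"] = lat.polygon_counts
            summary["mean_nn_distance"] = lat.mean_nn_distance
            summary["nn_distance_cv"] = lat.nn_distance_cv
        except ValueError as exc:
            summary["lattice_error"] = str(exc)
        (out / "analysis.json").write_text(json.dumps(summary, indent=2))

        stage = "predict"
        act = prediction.fine_grid_activities(
            weights,
            spec.arena,
            boxes,
            resolution=spec.predict_resolution,
            v=spec.pipeline_mask_width,
            normalize=cfg.normalize,
        )
        for direction in spec.predict_directions:
            windows = prediction.build_path_windows(act, direction, spec.predict_n)
            predictor = prediction.fit_pls(
                windows, n_components=min(spec.pls_components, windows.n_windows)
            )
            pfield = prediction.render_prediction_field(
                predictor, act, direction, spec.predict_n, steps=spec.predict_steps
            )
            np.savez_compressed(
                out / f"prediction_{int(direction):03d}.npz",
                leading=pfield.leading,
                starts=pfield.start_points,
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
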