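"""Count evaluation: per-image predictions, MAE/RMSE, and the
architecture x batch-size comparison harness.

Counts are reported as raw reals (no rounding): the error metrics operate
on the predicted density integrals directly. MAE is the mean absolute
difference between true and predicted counts over the test images; RMSE
the root of the mean squared difference, so RMSE >= MAE always, with
equality iff all absolute errors coincide.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .density import DensityMap, KernelSpec, count_from_density
from .models import NetworkHandle, build_network, forward
from .synthetic import AnnotatedImage
from .training import TrainConfig, normalize_patch, prepare_sample, split_dataset, train

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalReport:
    """Per-image (identifier, true, predicted) records with MAE/RMSE."""

    records: list[tuple[str, int, float]]
    mae: float
    rmse: float

    @property
    def n(self) -> int:
        return len(self.records)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.records, columns=["identifier", "true_count", "predicted_count"]
        ).to_csv(path, index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"mae": self.mae, "rmse": self.rmse, "n": self.n}, fh, indent=2)
            fh.write("\n")


def mae(pairs) -> float:
    """Mean absolute error over (true, predicted) pairs."""
    arr = np.asarray(list(pairs), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("mae of an empty list is undefined")
    return float(np.mean(np.abs(arr[:, 0] - arr[:, 1])))


def rmse(pairs) -> float:
    """Root mean squared error over (true, predicted) pairs."""
    arr = np.asarray(list(pairs), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("rmse of an empty list is undefined")
    return float(np.sqrt(np.mean((arr[:, 0] - arr[:, 1]) ** 2)))


def predict_density(
    network: NetworkHandle,
    sample: AnnotatedImage,
    kernel: KernelSpec,
    target_scale: float = 100.0,
    patch_size: int | None = None,
) -> DensityMap:
    """Network density prediction for one image, on the count scale.

    Applies the same preprocessing as training (grayscale, center patch,
    patch normalization), then divides the training target scale back out.
    """
    prepped = prepare_sample(sample, patch_size or max(sample.annotation.frame_shape))
    x = normalize_patch(prepped.pixels)[None].astype(np.float32)
    pred = forward(network, x)[0].astype(np.float64) / target_scale
    return DensityMap(values=np.maximum(pred, 0.0), kernel=kernel)


def evaluate(
    network: NetworkHandle,
    samples: list[AnnotatedImage],
    kernel: KernelSpec,
    target_scale: float = 100.0,
    patch_size: int | None = None,
    batch: int = 8,
) -> EvalReport:
    """Predicted-vs-true counts over a test set, aggregated into MAE/RMSE.

    Each image goes through the training-time preprocessing, a forward
    pass, and counting by integration of the predicted map.
    """
    if not samples:
        raise ValueError("test set is empty")
    prepped = [
        prepare_sample(s, patch_size or max(s.annotation.frame_shape)) for s in samples
    ]
    records: list[tuple[str, int, float]] = []
    for start in range(0, len(prepped), batch):
        chunk = prepped[start : start + batch]
        xb = np.stack([normalize_patch(s.pixels) for s in chunk])[..., None].astype(np.float32)
        preds = forward(network, xb).astype(np.float64) / target_scale
        for s, p in zip(chunk, preds):
            dmap = DensityMap(values=np.maximum(p, 0.0), kernel=kernel)
            records.append((s.identifier, s.count, count_from_density(dmap)))
    pairs = [(t, p) for _, t, p in records]
    return EvalReport(records=records, mae=mae(pairs), rmse=rmse(pairs))


def run_comparison(
    samples: list[AnnotatedImage],
    kernel: KernelSpec,
    base_config: TrainConfig,
    families: tuple[str, ...] = ("fcrn", "unet"),
    batch_sizes: tuple[int, ...] = (1, 8, 16),
    base_channels: int = 32,
    out_csv=None,
) -> pd.DataFrame:
    """Train and score every (family, batch size) cell on one shared split.

    All cells reuse the same train/test partition and the same
    initialization seed so the comparison isolates the architecture and
    batch-size effect. Returns a table with columns
    ``network, batch_size, mae, rmse`` (one row per cell, like the usual
    two-architectures-by-three-batch-sizes summary), optionally persisted
    as CSV.
    """
    from .models import ArchitectureSpec

    by_id = {s.identifier: s for s in samples}
    train_ids, test_ids = split_dataset(
        list(by_id), base_config.train_fraction, base_config.seed
    )
    train_set = [by_id[i] for i in train_ids]
    test_set = [by_id[i] for i in test_ids]
    rows = []
    for family in families:
        for bs in batch_sizes:
            spec = ArchitectureSpec(family=family, base_channels=base_channels)
            network = build_network(spec, seed=base_config.seed)
            cfg = replace(base_config, batch_size=bs)
            logger.info("training %s at batch size %d (%d train images)",
                        family, bs, len(train_set))
            train(network, train_set, kernel, cfg)
            report = evaluate(
                network, test_set, kernel,
                target_scale=cfg.target_scale, patch_size=cfg.patch_size,
            )
            rows.append(
                {"network": family, "batch_size": bs,
                 "mae": report.mae, "rmse": report.rmse}
            )
            logger.info("%s/bs=%d: MAE %.3f RMSE %.3f", family, bs,
                        report.mae, report.rmse)
    table = pd.DataFrame(rows, columns=["network", "batch_size", "mae", "rmse"])
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table


def zeros_baseline_mae(samples: list[AnnotatedImage]) -> float:
    """MAE of the trivial all-zeros predictor: the mean true count."""
    return mae([(s.count, 0.0) for s in samples])
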