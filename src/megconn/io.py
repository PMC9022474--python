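"""Plain-text on-disk interchange for epoched series and cohort tables.

All formats are delimited text: an epoched series is stored as a single
whitespace-delimited matrix of shape (n_epochs·n_regions, n_samples) with a
metadata header, so external users can supply their own region time series
without any binary container.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .preprocess import EpochedSeries

__all__ = ["write_epoched_series", "read_epoched_series"]


def write_epoched_series(series: EpochedSeries, path: str | Path) -> Path:
    path = Path(path)
    header = (
        f"subject_id: {series.subject_id}\n"
        f"sampling_rate: {series.sampling_rate}\n"
        f"epoch_length: {series.epoch_length}\n"
        f"n_epochs: {series.n_epochs}\n"
        f"n_regions: {series.n_regions}"
    )
    if series.motion is not None:
        header += "\nmotion: " + " ".join(f"{m:.17g}" for m in series.motion)
    flat = series.epochs.reshape(series.n_epochs * series.n_regions, series.n_samples)
    np.savetxt(path, flat, header=header, fmt="%.8g")
    return path


def read_epoched_series(path: str | Path) -> EpochedSeries:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line.lstrip("# ").partition(":")
            meta[key.strip()] = val.strip()
    flat = np.loadtxt(path)
    n_epochs = int(meta["n_epochs"])
    n_regions = int(meta["n_regions"])
    epochs = flat.reshape(n_epochs, n_regions, -1)
    motion = None
    if "motion" in meta:
        motion = np.array([float(v) for v in meta["motion"].split()])
    return EpochedSeries(
        subject_id=meta["subject_id"],
        epochs=epochs,
        sampling_rate=float(meta["sampling_rate"]),
        epoch_length=float(meta["epoch_length"]),
        motion=motion,
    )
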