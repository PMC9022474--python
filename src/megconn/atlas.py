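"""Region atlas handling (labels + 3-D centroid coordinates).

The packaged fixture carries the 90 cortical/subcortical region labels of the
Automated Anatomical Labeling (AAL) parcellation in standard order with
approximate MNI centroid coordinates (synthetic approximations adequate for
network export and hub labelling; users with their own parcellation supply a
CSV with the same ``label,x,y,z`` column contract).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["AtlasInfo", "load_aal90", "load_atlas"]


@dataclass
class AtlasInfo:
    """Region labels and centroid coordinates (mm, MNI convention)."""

    labels: list[str]
    coords: np.ndarray  # (n_regions, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.labels) != self.coords.shape[0] or self.coords.shape[1] != 3:
            raise ValueError("labels and (n, 3) coords must align")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("region labels must be unique")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_regions(self) -> int:
        return len(self.labels)


def load_atlas(path: str | Path) -> AtlasInfo:
    """Load an atlas from a CSV with columns label,x,y,z."""
    df = pd.read_csv(path)
    return AtlasInfo(
        labels=df["label"].astype(str).tolist(),
        coords=df[["x", "y", "z"]].to_numpy(dtype=float),
    )


def load_aal90() -> AtlasInfo:
    """The packaged 90-region AAL label set with approximate MNI centroids."""
    with resources.as_file(resources.files("megconn.data") / "aal90.csv") as p:
        atlas = load_atlas(p)
    if atlas.n_regions != 90:
        raise RuntimeError("packaged atlas fixture must have 90 regions")
    return atlas
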