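"""Weighted phase lag index (wPLI) connectivity.

For two analytic signals z_i, z_j the per-epoch cross-spectral samples are
X_t = z_i(t)·conj(z_j(t)) and

    wPLI = |Σ_t Im(X_t)| / Σ_t |Im(X_t)|

which weights phase differences by the magnitude of the imaginary part of the
cross-spectrum, is blind to zero-lag (volume-conduction / field-spread)
coupling, and ranges from 0 (no consistent lag) to 1 (perfectly consistent
lag).  wPLI is computed within each epoch over time samples and then averaged
across epochs; when the denominator is zero (pure zero-lag or silent input)
the value is defined as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .bands import BandDefinition
from .preprocess import AnalyticEpochs

__all__ = [
    "ConnectivityMatrix",
    "epoch_wpli",
    "wpli_matrix",
    "subject_connectivity",
    "write_connectivity",
    "read_connectivity",
]

logger = logging.getLogger(__name__)


@dataclass
class ConnectivityMatrix:
    """Symmetric region×region wPLI matrix for one subject and band."""

    subject_id: str
    band: BandDefinition
    values: np.ndarray
    n_epochs_used: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        validate_wpli_matrix(self.values)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def validate_wpli_matrix(values: np.ndarray, atol: float = 1e-9) -> None:
    """Check symmetry, [0, 1] range, zero diagonal and finiteness.

    Raises ValueError naming the first offending cell.
    """
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"connectivity matrix must be square, got {values.shape}")
    bad = ~np.isfinite(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"non-finite connectivity value at cell ({i}, {j})")
    out = (values < 0) | (values > 1)
    if out.any():
        i, j = np.argwhere(out)[0]
        raise ValueError(
            f"connectivity value {values[i, j]} at cell ({i}, {j}) outside [0, 1]"
        )
    asym = np.abs(values - values.T) > atol
    if asym.any():
        i, j = np.argwhere(asym)[0]
        raise ValueError(f"asymmetric connectivity at cell ({i}, {j})")
    if np.any(np.abs(np.diag(values)) > atol):
        i = int(np.argmax(np.abs(np.diag(values))))
        raise ValueError(f"non-zero diagonal at cell ({i}, {i})")


def epoch_wpli(z_i: np.ndarray, z_j: np.ndarray) -> float:
    """wPLI of two equal-length complex analytic sample sequences."""
    z_i = np.asarray(z_i)
    z_j = np.asarray(z_j)
    if z_i.shape != z_j.shape:
        raise ValueError(f"length mismatch: {z_i.shape} vs {z_j.shape}")
    if z_i.size < 2:
        raise ValueError("need at least 2 samples")
    if not (np.all(np.isfinite(z_i)) and np.all(np.isfinite(z_j))):
        raise ValueError("non-finite input")
    # Im(z_i conj(z_j)) via explicit real arithmetic: the two rounded products
    # and one subtraction make swapping the arguments an exact negation (a
    # fused complex multiply would break exact symmetry), and identical
    # signals give an exact zero.
    imx = z_i.imag * z_j.real - z_i.real * z_j.imag
    den = np.abs(imx).sum()
    # denominator-zero convention: pure zero-lag or silent input -> 0; the
    # cutoff is relative to the cross-spectrum magnitude |z_i||z_j|
    if den <= 1e-12 * (np.abs(z_i) * np.abs(z_j)).sum():
        logger.debug("wPLI denominator zero; returning 0 (no phase locking)")
        return 0.0
    return float(np.abs(imx.sum()) / den)


def wpli_matrix(Z: np.ndarray) -> np.ndarray:
    """Epoch-averaged wPLI over all region pairs.

    Parameters
    ----------
    Z : complex ndarray, shape (n_epochs, n_regions, n_samples)

    Returns
    -------
    (n_regions, n_regions) symmetric matrix with zero diagonal; wPLI is
    computed per epoch and averaged arithmetically across epochs.
    """
    if Z.ndim != 3:
        raise ValueError("Z must be (n_epochs, n_regions, n_samples)")
    n_epochs, n_regions, _ = Z.shape
    if n_epochs < 1:
        raise ValueError("need at least one epoch")
    W = np.zeros((n_regions, n_regions))
    Zc = np.conj(Z)
    for i in range(n_regions - 1):
        x = Z[:, i, None, :] * Zc[:, i + 1 :, :]  # (E, R-i-1, T)
        imx = x.imag
        num = np.abs(imx.sum(axis=-1))
        den = np.abs(imx).sum(axis=-1)
        floor = 1e-12 * np.abs(x).sum(axis=-1)  # zero-lag convention, see epoch_wpli
        ok = den > floor
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(ok, num / np.where(ok, den, 1.0), 0.0)
        W[i, i + 1 :] = w.mean(axis=0)
    W = W + W.T
    # ratio estimator can graze 1 + eps through float rounding
    return np.clip(W, 0.0, 1.0)


def subject_connectivity(analytic: AnalyticEpochs) -> ConnectivityMatrix:
    """Epoch-averaged wPLI connectivity matrix for one subject and band."""
    if analytic.n_epochs < 1:
        raise ValueError("zero epochs: cannot estimate connectivity")
    values = wpli_matrix(analytic.epochs)
    return ConnectivityMatrix(
        subject_id=analytic.subject_id,
        band=analytic.band,
        values=values,
        n_epochs_used=analytic.n_epochs,
    )


def write_connectivity(matrix: ConnectivityMatrix, path: str | Path) -> Path:
    """Write a connectivity matrix as delimited text with a metadata header."""
    path = Path(path)
    header = (
        f"subject_id: {matrix.subject_id}\n"
        f"band: {matrix.band.name} {matrix.band.low} {matrix.band.high}\n"
        f"n_epochs_used: {matrix.n_epochs_used}"
    )
    np.savetxt(path, matrix.values, delimiter=",", header=header, fmt="%.17g")
    return path


def read_connectivity(path: str | Path) -> ConnectivityMatrix:
    """Read a connectivity matrix written by :func:`write_connectivity`.

    Rejects files whose values violate the wPLI matrix invariants, naming the
    offending cell.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line.lstrip("# ").partition(":")
            meta[key.strip()] = val.strip()
    values = np.loadtxt(path, delimiter=",", comments="#")
    band_name, low, high = meta["band"].split()
    matrix = ConnectivityMatrix(  # __post_init__ validates
        subject_id=meta["subject_id"],
        band=BandDefinition(band_name, float(low), float(high)),
        values=np.atleast_2d(values),
        n_epochs_used=int(meta["n_epochs_used"]),
    )
    return matrix
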