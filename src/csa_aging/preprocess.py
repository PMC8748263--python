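"""Signal-level preprocessing of surface BOLD scans.

Three in-scope steps, applied in this fixed order by the pipeline:
drop initial volumes -> global-mean normalization to 10,000 -> removal of
per-vertex linear and quadratic temporal trends.  Volumetric stages
(despiking, slice timing, motion correction, ICA denoising) are out of scope
here: the pipeline consumes surface-sampled series directly, and real-data
users can insert externally preprocessed series via the same BoldScan
container.
"""

from __future__ import annotations

import numpy as np

from .synthetic import BoldScan

__all__ = [
    "drop_initial_volumes",
    "normalize_global_mean",
    "detrend_quadratic",
    "preprocess_scan",
]


def drop_initial_volumes(scan: BoldScan, n: int = 5) -> BoldScan:
    """Remove the first `n` time points (T1-equilibration volumes)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n >= scan.n_volumes:
        raise ValueError(f"cannot drop {n} of {scan.n_volumes} volumes")
    return scan.with_data(scan.data[:, n:].copy())


def normalize_global_mean(scan: BoldScan, target: float = 10000.0) -> BoldScan:
    """Scale the whole 4D series so its grand mean equals `target`."""
    grand = float(scan.data.mean())
    if grand <= 0:
        raise ValueError(f"grand mean must be positive, got {grand}")
    return scan.with_data(scan.data * (target / grand))


def detrend_quadratic(scan: BoldScan) -> BoldScan:
    """Remove per-vertex linear and quadratic temporal trends, keeping the mean.

    The least-squares projection of each vertex's series onto centered
    {t, t^2} is subtracted; the design columns are mean-centered so the
    temporal mean of every vertex is preserved (the subsequent analyses treat
    the 0 Hz component separately).
    """
    n_t = scan.n_volumes
    if n_t < 4:
        raise ValueError("need at least 4 volumes to fit a quadratic trend")
    t = np.arange(n_t, dtype=float)
    t = t - t.mean()
    X = np.column_stack([t, t**2 - (t**2).mean()])
    # orthonormalize for a stable projection
    Q, _ = np.linalg.qr(X)
    data = scan.data
    trend = (data @ Q) @ Q.T
    return scan.with_data(data - trend)


def preprocess_scan(scan: BoldScan, n_drop: int = 5, target: float = 10000.0) -> BoldScan:
    """Full in-scope preprocessing chain: drop -> normalize -> detrend."""
    return detrend_quadratic(normalize_global_mean(drop_initial_volumes(scan, n_drop), target))
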