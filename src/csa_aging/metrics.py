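"""Per-band cortical spontaneous-activity metrics and their global summaries.

Three vertex-wise metrics across three slow frequency bands:

* **ALFF** — amplitude of low-frequency fluctuations: the mean one-sided
  amplitude spectrum 2/T * |DFT| over the band's frequency bins.  Mean (not
  sum) over bins, so values are comparable across bands of unequal width; a
  sum variant is `alff(..., reduce="sum")`.
* **ReHo** — regional homogeneity: Kendall's coefficient of concordance (W)
  of a vertex's band-filtered series with its k-ring mesh neighborhood
  (default 4 steps, ~61 vertices on a regular 2 mm mesh); W in [0, 1].
* **VMHC** — homotopic connectivity: Fisher-z-transformed Pearson
  correlation between band-filtered series at mirrored left/right vertices.

Bands follow the slow-band partition slow-5 (0.02-0.03 Hz), slow-4
(0.03-0.08 Hz), slow-3 (0.08-0.22 Hz); band membership of a DFT bin is
half-open [f_low, f_high) so the bands never double-count the shared
printed edges.  Per scan, the global summary is the mean and the SD (ddof=1)
of each raw map within the group mask; the two scans of a visit are then
averaged to give the visit-level global measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import rankdata

from .surface import SymmetricSurfaceMesh, all_kring_neighborhoods

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "bandpass_ideal",
    "alff",
    "reho_kcc",
    "vmhc",
    "global_summary",
    "average_scans",
    "compute_csa_table",
]

R_CLIP = 1.0 - 1e-6  # |r| clip before Fisher z, keeps VMHC finite


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_low: float
    f_high: float

    def __post_init__(self):
        if not 0 < self.f_low < self.f_high:
            raise ValueError(f"need 0 < f_low < f_high, got {self}")

    def bin_mask(self, n_volumes: int, tr: float) -> np.ndarray:
        """Boolean mask over rfft bins with f_low <= f < f_high."""
        freqs = np.fft.rfftfreq(n_volumes, d=tr)
        return (freqs >= self.f_low) & (freqs < self.f_high)


DEFAULT_BANDS = (
    BandDefinition("slow-5", 0.02, 0.03),
    BandDefinition("slow-4", 0.03, 0.08),
    BandDefinition("slow-3", 0.08, 0.22),
)


def _check_band(band: BandDefinition, n_volumes: int, tr: float) -> np.ndarray:
    mask = band.bin_mask(n_volumes, tr)
    if mask.sum() < 2:
        min_len = int(np.ceil(2.0 / (tr * (band.f_high - band.f_low)))) + 1
        raise ValueError(
            f"band {band.name} ({band.f_low}-{band.f_high} Hz) spans "
            f"{int(mask.sum())} DFT bin(s) at {n_volumes} volumes, TR={tr}s; "
            f"need >= 2 (at least ~{min_len} volumes)"
        )
    return mask


def bandpass_ideal(series: np.ndarray, band: BandDefinition, tr: float) -> np.ndarray:
    """Ideal (brick-wall DFT) bandpass of each vertex's time series.

    Bins with f_low <= f < f_high are retained; all others, including 0 Hz,
    are zeroed, so the output has zero temporal mean.
    """
    series = np.atleast_2d(np.asarray(series, float))
    mask = _check_band(band, series.shape[1], tr)
    spec = np.fft.rfft(series, axis=1)
    spec[:, ~mask] = 0.0
    return np.fft.irfft(spec, n=series.shape[1], axis=1)


def alff(
    series: np.ndarray, band: BandDefinition, tr: float, reduce: str = "mean"
) -> np.ndarray:
    """Per-vertex ALFF: average one-sided spectral amplitude over band bins.

    Amplitudes are a_k = (2/T)|DFT_k| for 0 < k < T/2; ALFF is their mean
    (or sum, with reduce="sum") over bins inside the band.
    """
    series = np.atleast_2d(np.asarray(series, float))
    n_t = series.shape[1]
    mask = _check_band(band, n_t, tr)
    mask = mask.copy()
    mask[0] = False  # never the 0 Hz bin
    if n_t % 2 == 0:
        mask[-1] = False  # exclude the Nyquist bin (k = T/2)
    amp = (2.0 / n_t) * np.abs(np.fft.rfft(series, axis=1))
    band_amp = amp[:, mask]
    return band_amp.sum(axis=1) if reduce == "sum" else band_amp.mean(axis=1)


def reho_kcc(
    filtered: np.ndarray, neighborhoods: sparse.spmatrix | list
) -> np.ndarray:
    """Per-vertex ReHo: Kendall's W of each vertex's series with its neighbors.

    Each series is ranked over time (average ranks on ties); for a vertex
    with neighborhood of size K over n time points, with R_t the sum of the
    K ranks at time t:

        W = [sum_t R_t^2 - n * Rbar^2] / [K^2 (n^3 - n) / 12]

    clipped to [0, 1].  `neighborhoods` is either a boolean/0-1 sparse matrix
    (row v marks the members of v's neighborhood, v included) or a list of
    index arrays.
    """
    filtered = np.atleast_2d(np.asarray(filtered, float))
    n_v, n_t = filtered.shape
    if n_t < 3:
        raise ValueError("need at least 3 time points for ReHo")
    if np.any(filtered.std(axis=1) == 0):
        warnings.warn("constant series in ReHo input; ranks are all-tied there")
    ranks = rankdata(filtered, axis=1)
    if not sparse.issparse(neighborhoods):
        indptr = np.zeros(n_v + 1, dtype=np.intp)
        indices = []
        for v, neigh in enumerate(neighborhoods):
            neigh = np.asarray(neigh, dtype=np.intp)
            if neigh.size == 0:
                raise ValueError(f"empty neighborhood for vertex {v}")
            indices.append(neigh)
            indptr[v + 1] = indptr[v] + neigh.size
        indices = np.concatenate(indices)
        neighborhoods = sparse.csr_matrix(
            (np.ones(indices.size, dtype=np.int8), indices, indptr), shape=(n_v, n_v)
        )
    K = np.asarray(neighborhoods.sum(axis=1)).ravel().astype(float)
    if np.any(K == 0):
        raise ValueError("every neighborhood must be nonempty")
    R = neighborhoods @ ranks  # (n_v, n_t): rank sums per time point
    S = (R**2).sum(axis=1) - n_t * R.mean(axis=1) ** 2
    W = 12.0 * S / (K**2 * (n_t**3 - n_t))
    return np.clip(W, 0.0, 1.0)


def vmhc(
    filtered: np.ndarray, pairing: np.ndarray
) -> np.ndarray:
    """Per-vertex VMHC: Fisher z of the mirror-pair temporal correlation.

    Returns one value per vertex; the value at v equals the value at
    pairing[v].  Correlations are clipped to +/-(1 - 1e-6) before atanh.
    Zero-variance members give VMHC 0 with a warning (the group mask should
    have excluded them).
    """
    filtered = np.asarray(filtered, float)
    pairing = np.asarray(pairing)
    x = filtered - filtered.mean(axis=1, keepdims=True)
    ss = np.sqrt((x**2).sum(axis=1))
    y = x[pairing]
    ss_y = ss[pairing]
    denom = ss * ss_y
    degenerate = denom == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} vertices with zero-variance series; VMHC set to 0"
        )
    denom[degenerate] = 1.0
    r = (x * y).sum(axis=1) / denom
    r[degenerate] = 0.0
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def global_summary(values: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    """Mean and SD (ddof=1) of a metric map over masked vertices."""
    values = np.asarray(values, float)
    mask = np.asarray(mask, bool)
    if mask.sum() < 2:
        raise ValueError("global SD needs at least 2 masked vertices")
    v = values[mask]
    return float(v.mean()), float(v.std(ddof=1))


def average_scans(summary1, summary2, check_provenance: tuple | None = None):
    """Average the (mean, SD) summaries of a visit's two scans.

    If `check_provenance` is given as ((subject, visit, metric, band) pair of
    tuples), mismatches raise.
    """
    if check_provenance is not None:
        a, b = check_provenance
        if tuple(a) != tuple(b):
            raise ValueError(f"provenance mismatch: {a} vs {b}")
    m1, s1 = summary1
    m2, s2 = summary2
    return ((m1 + m2) / 2.0, (s1 + s2) / 2.0)


def compute_csa_table(
    scans,
    mesh: SymmetricSurfaceMesh,
    mask: np.ndarray,
    bands=DEFAULT_BANDS,
    neighborhoods: sparse.spmatrix | None = None,
    k_steps: int = 4,
    cohort: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Global CSA table: metric x band x statistic per subject-visit.

    For every (preprocessed) scan and band: ALFF from the detrended series'
    spectrum restricted to the band; ReHo and VMHC from the ideal
    band-filtered series; each map summarized as (mean, SD) within the group
    mask; the two scans of each visit averaged.  Output is a tidy frame with
    columns subject_id, visit, metric, band, statistic, value (plus
    demographics if `cohort` is supplied).
    """
    scans = list(scans)
    if not scans:
        raise ValueError("no scans supplied")
    if neighborhoods is None:
        neighborhoods = all_kring_neighborhoods(mesh, k_steps)
    pairing = mesh.homotopic_pair

    per_scan = []
    for scan in scans:
        tr = scan.tr
        for band in bands:
            filt = bandpass_ideal(scan.data, band, tr)
            maps = {
                "ALFF": alff(scan.data, band, tr),
                "ReHo": reho_kcc(filt, neighborhoods),
                "VMHC": vmhc(filt, pairing),
            }
            for metric, m in maps.items():
                mean, sd = global_summary(m, mask)
                per_scan.append(
                    {
                        "subject_id": scan.subject_id,
                        "visit": scan.visit_index,
                        "scan": scan.scan_index,
                        "metric": metric,
                        "band": band.name,
                        "mean": mean,
                        "SD": sd,
                    }
                )
    df = pd.DataFrame(per_scan)
    visit_level = (
        df.groupby(["subject_id", "visit", "metric", "band"], as_index=False)[
            ["mean", "SD"]
        ].mean()
    )
    long = visit_level.melt(
        id_vars=["subject_id", "visit", "metric", "band"],
        value_vars=["mean", "SD"],
        var_name="statistic",
        value_name="value",
    )
    if cohort is not None:
        long = long.merge(cohort, on=["subject_id", "visit"], how="left")
    order = ["subject_id", "visit", "metric", "band", "statistic"]
    return long.sort_values(order, kind="mergesort").reset_index(drop=True)
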