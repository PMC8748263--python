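"""Synthetic longitudinal surface-BOLD cohorts with known aging effects.

This generator emulates the statistical structure the downstream analysis
assumes in a longitudinal resting-state cohort: ~24 older adults, five annual
visits each, two scans per visit, BOLD sampled on a symmetric surface mesh.
Per scan, each frequency band's component is band-limited Gaussian noise
whose amplitude carries the injected aging trend and subject random
intercept; homotopic coupling ties right-hemisphere components to their left
mirror partners; local spatial averaging induces neighborhood correlation;
white measurement noise and a positive offset complete the BOLD-like series.

The three aging pathways are independently switchable so that amplitude
(ALFF), local-coupling (ReHo) and homotopic-coupling (VMHC) effects can be
injected separately:

* ``amp_slope_per_year[band]`` scales band amplitude multiplicatively per
  year of age past the baseline reference (58 y).
* ``smooth_weight_slope_per_year[band]`` drifts the local 1-ring averaging
  weight, raising neighborhood concordance with age.
* ``homotopic_slope_per_year[band]`` drifts the homotopic mixing weight
  ``w_h``, raising mirror-pair correlation with age.

Every injected effect is recorded in a ground-truth ledger for recovery
tests.  All randomness flows through a single seed via numpy SeedSequence,
so identical specs and seeds reproduce datasets exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .surface import SymmetricSurfaceMesh

__all__ = [
    "REFERENCE_AGE",
    "BoldScan",
    "CohortSpec",
    "SignalSpec",
    "generate_cohort",
    "simulate_scan",
    "generate_dataset",
    "null_signal_spec",
    "amplitude_aging_signal_spec",
    "full_aging_signal_spec",
]

#: Age (years) at which injected multiplicative trends equal their base value.
REFERENCE_AGE = 58.0

BAND_NAMES = ("slow-5", "slow-4", "slow-3")


@dataclass
class BoldScan:
    """One scan's vertex x time matrix with acquisition metadata."""

    data: np.ndarray  # (n_vertices, n_volumes)
    tr: float  # repetition time, seconds
    subject_id: str
    visit_index: int  # 1-based
    scan_index: int  # 1 or 2

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "BoldScan":
        return BoldScan(data, self.tr, self.subject_id, self.visit_index, self.scan_index)


@dataclass
class CohortSpec:
    """Design of the longitudinal cohort (defaults mirror the study design:
    24 cognitively unimpaired elders, baseline ages 58-77, 8 of 24 male,
    five annual visits, two scans per visit)."""

    n_subjects: int = 24
    visits_per_subject: int = 5
    scans_per_visit: int = 2
    baseline_age_range: tuple[float, float] = (58.0, 77.0)
    male_fraction: float = 8.0 / 24.0
    education_range: tuple[float, float] = (10.0, 20.0)
    baseline_calendar_range: tuple[float, float] = (2012.0, 2017.0)

    def __post_init__(self):
        if min(self.n_subjects, self.visits_per_subject, self.scans_per_visit) < 1:
            raise ValueError("all cohort counts must be positive")
        if self.baseline_age_range[1] < self.baseline_age_range[0]:
            raise ValueError("empty baseline age range")


@dataclass
class SignalSpec:
    """Generative parameters for one scan's BOLD series.

    Amplitudes are in arbitrary intensity units on the ~10,000 global-mean
    scale; slopes are fractional change per year of age past REFERENCE_AGE.
    """

    base_amplitude: dict = field(
        default_factory=lambda: {"slow-5": 40.0, "slow-4": 60.0, "slow-3": 30.0}
    )
    amp_slope_per_year: dict = field(
        default_factory=lambda: {b: 0.0 for b in BAND_NAMES}
    )
    homotopic_weight: float = 0.3
    homotopic_slope_per_year: dict = field(
        default_factory=lambda: {b: 0.0 for b in BAND_NAMES}
    )
    smooth_weight: float = 0.5
    smooth_weight_slope_per_year: dict = field(
        default_factory=lambda: {b: 0.0 for b in BAND_NAMES}
    )
    smooth_steps: int = 1
    subject_intercept_sd: float = 0.1  # on log-amplitude
    noise_sd: float = 10.0
    n_volumes: int = 150
    n_equilibration: int = 5
    tr: float = 2.0
    offset: float = 10000.0
    sex_log_amplitude: float = 0.0  # additive shift on log-amplitude for males
    cohort_log_amplitude_per_year: float = 0.0

    def __post_init__(self):
        if any(v < 0 for v in self.base_amplitude.values()):
            raise ValueError("band amplitudes must be >= 0")
        if not 0.0 <= self.homotopic_weight <= 1.0:
            raise ValueError("homotopic_weight must lie in [0, 1]")
        if self.n_volumes <= 10:
            raise ValueError("need more than 10 volumes per scan")


def null_signal_spec(**overrides) -> SignalSpec:
    """Signal spec with no injected aging effect (type-I error studies)."""
    return SignalSpec(**overrides)


def amplitude_aging_signal_spec(slope: float = 0.02, **overrides) -> SignalSpec:
    """Multiplicative per-year amplitude increase in every band."""
    return SignalSpec(
        amp_slope_per_year={b: slope for b in BAND_NAMES}, **overrides
    )


def full_aging_signal_spec(
    amp_slope: float = 0.02,
    coupling_slope: float = 0.02,
    coupling_band: str = "slow-4",
    **overrides,
) -> SignalSpec:
    """Amplitude aging in all bands plus homotopic- and local-coupling drift
    confined to one band (default slow-4) — the full qualitative aging pattern
    the analysis is meant to recover.

    Measurement noise is off in this preset: broadband noise dilutes the
    band-filtered correlations, so an amplitude trend would otherwise leak an
    SNR-mediated connectivity trend into every band and the three aging
    pathways would no longer be separately emulable.
    """
    overrides.setdefault("noise_sd", 0.0)
    return SignalSpec(
        amp_slope_per_year={b: amp_slope for b in BAND_NAMES},
        homotopic_slope_per_year={
            b: (coupling_slope if b == coupling_band else 0.0) for b in BAND_NAMES
        },
        smooth_weight_slope_per_year={
            b: (coupling_slope if b == coupling_band else 0.0) for b in BAND_NAMES
        },
        **overrides,
    )


def generate_cohort(spec: CohortSpec, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Generate the longitudinal demographics table.

    One row per subject-visit with columns subject_id, visit, age, sex,
    education, cohort.  Baseline ages are uniform over the configured range;
    follow-ups are annual.  `cohort` is the decimal number of years between
    the subject's birth date and 1970-01-01 (negative for pre-1970 births),
    derived consistently from baseline calendar time minus baseline age.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = spec.n_subjects
    lo, hi = spec.baseline_age_range
    baseline_age = rng.uniform(lo, hi, size=n)
    baseline_year = rng.uniform(*spec.baseline_calendar_range, size=n)
    n_male = int(round(spec.male_fraction * n))
    sex = np.array(["male"] * n_male + ["female"] * (n - n_male))
    rng.shuffle(sex)
    education = np.round(rng.uniform(*spec.education_range, size=n))
    cohort = (baseline_year - 1970.0) - baseline_age

    rows = []
    for i in range(n):
        sid = f"sub-{i + 1:03d}"
        for j in range(spec.visits_per_subject):
            rows.append(
                {
                    "subject_id": sid,
                    "visit": j + 1,
                    "age": baseline_age[i] + float(j),
                    "sex": sex[i],
                    "education": education[i],
                    "cohort": cohort[i],
                }
            )
    return pd.DataFrame(rows)


def simulate_outcome_table(
    cohort: pd.DataFrame,
    truth_fn,
    sigma_b: float,
    sigma_e: float,
    seed: int | np.random.Generator = 0,
    value_col: str = "value",
) -> pd.DataFrame:
    """Simulate a global-outcome table directly at the model level.

    y_ij = truth_fn(age_ij) + b_i + eps_ij with b_i ~ N(0, sigma_b^2) and
    eps_ij ~ N(0, sigma_e^2).  Used for parameter-recovery and calibration
    studies of the aging-curve model without the imaging pipeline.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = cohort.copy().reset_index(drop=True)
    subjects = df["subject_id"].unique()
    b = dict(zip(subjects, sigma_b * rng.standard_normal(len(subjects))))
    ages = df["age"].to_numpy(float)
    df[value_col] = (
        np.asarray(truth_fn(ages), float)
        + df["subject_id"].map(b).to_numpy(float)
        + sigma_e * rng.standard_normal(len(df))
    )
    return df


def _band_bin_mask(n_volumes: int, tr: float, band: tuple[float, float]) -> np.ndarray:
    freqs = np.fft.rfftfreq(n_volumes, d=tr)
    lo, hi = band
    return (freqs >= lo) & (freqs < hi)


DEFAULT_BAND_EDGES = {
    "slow-5": (0.02, 0.03),
    "slow-4": (0.03, 0.08),
    "slow-3": (0.08, 0.22),
}


def _bandlimited_noise(
    rng: np.random.Generator, n_vertices: int, n_volumes: int, tr: float,
    band: tuple[float, float],
) -> np.ndarray:
    """White Gaussian noise ideal-filtered to `band`, unit temporal variance."""
    mask = _band_bin_mask(n_volumes, tr, band)
    if mask.sum() < 1:
        raise ValueError(f"no DFT bin falls inside band {band} at T={n_volumes}")
    white = rng.standard_normal((n_vertices, n_volumes))
    spec = np.fft.rfft(white, axis=1)
    spec[:, ~mask] = 0.0
    out = np.fft.irfft(spec, n=n_volumes, axis=1)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def simulate_scan(
    mesh: SymmetricSurfaceMesh,
    visit: pd.Series | dict,
    signal: SignalSpec,
    seed: int | np.random.Generator,
    subject_intercept: float = 0.0,
    scan_index: int = 1,
) -> BoldScan:
    """Simulate one scan's vertex x time BOLD matrix for a subject-visit.

    Construction, per band: (a) band-limited unit-variance Gaussian noise
    scaled to amplitude base*(1 + slope*(age-58))*exp(subject intercept
    + covariate shifts); (b) homotopic coupling of the right hemisphere to
    its left mirror component with weight w_h (right = w_h*left +
    sqrt(1-w_h^2)*independent, preserving variance); (c) local correlation by
    relaxed 1-ring averaging; then (d) additive white measurement noise and
    (e) a constant positive offset.

    The band structure is built on the retained time grid (n_volumes minus
    n_equilibration samples); the first n_equilibration volumes are its
    cyclic continuation, standing in for the T1-equilibration volumes the
    preprocessing discards, so the series that survives volume dropping has
    its spectrum exactly confined to the requested bands.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    visit = dict(visit)
    age = float(visit["age"])
    dt_age = age - REFERENCE_AGE
    if signal.n_volumes * signal.tr < 2 / 0.02:
        warnings.warn("scan shorter than two cycles of the lowest band (0.02 Hz)")

    n = mesh.n_vertices
    n_hemi = mesh.n_vertices_per_hemi
    left = np.flatnonzero(mesh.hemisphere == "L")
    pair = mesh.homotopic_pair

    cov_shift = 0.0
    if signal.sex_log_amplitude:
        cov_shift += signal.sex_log_amplitude * (visit.get("sex") == "male")
    if signal.cohort_log_amplitude_per_year:
        cov_shift += signal.cohort_log_amplitude_per_year * float(visit.get("cohort", 0.0))
    gain = float(np.exp(subject_intercept + cov_shift))

    # Band structure lives on the retained grid (after the equilibration
    # volumes are dropped downstream); the leading volumes are its cyclic
    # continuation.  Truncating an ideal-filtered full-length series instead
    # would smear each band's age-trending content into neighboring bands.
    n_equil = min(signal.n_equilibration, signal.n_volumes // 2)
    n_ret = signal.n_volumes - n_equil
    data = np.zeros((n, n_ret))
    # neighbor-averaging operator built lazily once per call
    adj = mesh.adjacency
    deg = np.asarray(adj.sum(axis=1)).ravel().astype(float)
    deg[deg == 0] = 1.0

    for band in BAND_NAMES:
        amp = signal.base_amplitude.get(band, 0.0)
        amp *= max(0.0, 1.0 + signal.amp_slope_per_year.get(band, 0.0) * dt_age)
        amp *= gain
        if amp == 0:
            continue
        w_h = signal.homotopic_weight * (
            1.0 + signal.homotopic_slope_per_year.get(band, 0.0) * dt_age
        )
        w_h = float(np.clip(w_h, 0.0, 1.0))
        w_s = signal.smooth_weight * (
            1.0 + signal.smooth_weight_slope_per_year.get(band, 0.0) * dt_age
        )
        w_s = float(np.clip(w_s, 0.0, 1.0))

        edges = DEFAULT_BAND_EDGES[band]
        comp = np.empty((n, n_ret))
        comp_left = _bandlimited_noise(rng, n_hemi, n_ret, signal.tr, edges)
        comp_ind = _bandlimited_noise(rng, n_hemi, n_ret, signal.tr, edges)
        comp[left] = comp_left
        comp[pair[left]] = w_h * comp_left + np.sqrt(1.0 - w_h**2) * comp_ind

        for _ in range(signal.smooth_steps):
            neigh_mean = (adj @ comp) / deg[:, None]
            comp = (1.0 - w_s) * comp + w_s * neigh_mean
        sd = comp.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        data += amp * comp / sd

    if n_equil:
        data = np.concatenate([data[:, n_ret - n_equil :], data], axis=1)
    if signal.noise_sd > 0:
        data += signal.noise_sd * rng.standard_normal(data.shape)
    data += signal.offset
    return BoldScan(
        data=data,
        tr=signal.tr,
        subject_id=str(visit.get("subject_id", "sub-000")),
        visit_index=int(visit.get("visit", 1)),
        scan_index=scan_index,
    )


def generate_dataset(
    cohort_spec: CohortSpec,
    signal_spec: SignalSpec,
    mesh: SymmetricSurfaceMesh,
    seed: int = 0,
    n_dead_vertices_per_hemi: int = 0,
):
    """Generate the full longitudinal dataset: scans, demographics, ledger.

    Returns
    -------
    scans : list of BoldScan
        n_subjects * visits_per_subject * scans_per_visit scans.
    cohort : DataFrame
        The demographics table from :func:`generate_cohort`.
    ledger : dict
        Ground truth of every injected effect: the signal spec, per-subject
        random intercepts, and indices of vertices zeroed in all scans
        (for group-mask recovery tests).
    """
    ss = np.random.SeedSequence(seed)
    rng_cohort, rng_subj, rng_dead, rng_scans = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    cohort = generate_cohort(cohort_spec, rng_cohort)
    subjects = cohort["subject_id"].unique()
    intercepts = dict(
        zip(
            subjects,
            signal_spec.subject_intercept_sd * rng_subj.standard_normal(len(subjects)),
        )
    )
    n_hemi = mesh.n_vertices_per_hemi
    dead = np.array([], dtype=int)
    if n_dead_vertices_per_hemi:
        dead_l = rng_dead.choice(n_hemi, n_dead_vertices_per_hemi, replace=False)
        dead_r = rng_dead.choice(
            np.arange(n_hemi, 2 * n_hemi), n_dead_vertices_per_hemi, replace=False
        )
        dead = np.sort(np.concatenate([dead_l, dead_r]))

    scan_seeds = ss.spawn(len(cohort) * cohort_spec.scans_per_visit)
    scans = []
    k = 0
    for _, row in cohort.iterrows():
        for s in range(1, cohort_spec.scans_per_visit + 1):
            scan = simulate_scan(
                mesh,
                row,
                signal_spec,
                np.random.default_rng(scan_seeds[k]),
                subject_intercept=intercepts[row["subject_id"]],
                scan_index=s,
            )
            if dead.size:
                scan.data[dead] = 0.0
            scans.append(scan)
            k += 1

    ledger = {
        "seed": seed,
        "signal_spec": asdict(signal_spec),
        "cohort_spec": asdict(cohort_spec),
        "subject_intercepts": {k: float(v) for k, v in intercepts.items()},
        "dead_vertices": dead.tolist(),
        "reference_age": REFERENCE_AGE,
    }
    return scans, cohort, ledger
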