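"""ALFF / ReHo / VMHC against independent oracles, plus global summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from csa_aging.metrics import (
    DEFAULT_BANDS,
    BandDefinition,
    alff,
    average_scans,
    bandpass_ideal,
    compute_csa_table,
    global_summary,
    reho_kcc,
    vmhc,
)
from csa_aging.surface import all_kring_neighborhoods, kring_neighbors
from csa_aging.synthetic import CohortSpec, SignalSpec, generate_dataset
from csa_aging.preprocess import preprocess_scan

SLOW5, SLOW4, SLOW3 = DEFAULT_BANDS
TR = 2.0


# ----------------------------------------------------------------- oracles
def alff_oracle(series, band, tr):
    """Direct trigonometric periodogram: a_k = 2/T sqrt(C_k^2 + S_k^2)."""
    series = np.atleast_2d(series)
    n_t = series.shape[1]
    t = np.arange(n_t)
    out = []
    for x in series:
        amps = []
        for k in range(1, (n_t - 1) // 2 + 1):
            f = k / (n_t * tr)
            if band.f_low <= f < band.f_high:
                c = np.sum(x * np.cos(2 * np.pi * k * t / n_t))
                s = np.sum(x * np.sin(2 * np.pi * k * t / n_t))
                amps.append(2.0 / n_t * np.hypot(c, s))
        out.append(np.mean(amps))
    return np.array(out)


def _avg_ranks(x):
    """Average ranks of a 1-D array, ties averaged (independent of scipy)."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def kcc_oracle(series_block):
    """Kendall's W of K series over n time points, by the rank-sum formula."""
    K, n = series_block.shape
    R = np.zeros(n)
    for x in series_block:
        R += _avg_ranks(x)
    S = np.sum((R - R.mean()) ** 2)
    return 12.0 * S / (K**2 * (n**3 - n))


# ----------------------------------------------------------------- bandpass
class TestBandpass:
    def test_in_band_bin_cosine_passes(self):
        n_t = 145
        k = 10  # f = 10/290 ~ 0.0345 Hz, inside slow-4
        t = np.arange(n_t)
        y = 3.0 + np.cos(2 * np.pi * k * t / n_t)
        out = bandpass_ideal(y, SLOW4, TR)
        assert np.abs(out[0] - (y - y.mean())).max() < 1e-8

    def test_out_of_band_bin_cosine_blocked(self):
        n_t = 145
        k = 3  # f ~ 0.0103 Hz, below slow-5
        y = np.cos(2 * np.pi * k * np.arange(n_t) / n_t)
        for band in DEFAULT_BANDS:
            assert np.abs(bandpass_ideal(y, band, TR)).max() < 1e-8

    def test_white_noise_band_variances_bounded_by_total(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal((20, 145))
        total = np.var(y, axis=1)
        band_sum = sum(np.var(bandpass_ideal(y, b, TR), axis=1) for b in DEFAULT_BANDS)
        assert np.all(band_sum <= total + 1e-12)

    def test_empty_band_raises_with_minimum_length(self):
        with pytest.raises(ValueError, match="volumes"):
            bandpass_ideal(np.ones(20), SLOW5, TR)

    def test_band_validation(self):
        with pytest.raises(ValueError):
            BandDefinition("bad", 0.05, 0.02)


# --------------------------------------------------------------------- ALFF
class TestALFF:
    def test_zero_series(self):
        assert alff(np.zeros((3, 145)), SLOW4, TR)[0] == 0.0

    def test_single_bin_cosine_amplitude_recovered(self):
        """A cosine of amplitude 2 at the only bin of a one-bin-wide band
        gives ALFF exactly 2 (one-sided amplitude-spectrum normalization)."""
        n_t = 200  # df = 1/400 Hz
        k = 10  # f = 0.025 Hz
        band = BandDefinition("one-bin", 0.024, 0.026)
        y = 2.0 * np.cos(2 * np.pi * k * np.arange(n_t) / n_t + 0.7)
        # widen band check: exactly one bin falls inside
        assert band.bin_mask(n_t, TR).sum() == 1
        with pytest.raises(ValueError):
            alff(y, band, TR)  # <2 bins is rejected for general use
        wide = BandDefinition("two-bin", 0.024, 0.0285)
        got = alff(y, wide, TR)[0]
        assert got == pytest.approx(1.0, abs=1e-10)  # mean over 2 bins: (2+0)/2

    def test_matches_periodogram_oracle(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal((5, 145))
        for band in DEFAULT_BANDS:
            assert np.allclose(alff(y, band, TR), alff_oracle(y, band, TR), atol=1e-10)

    def test_positive_homogeneity(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal((4, 145))
        assert np.allclose(alff(3.5 * y, SLOW4, TR), 3.5 * alff(y, SLOW4, TR))

    def test_band_partition_property(self):
        """Signal confined to one band leaves ~zero ALFF in the other two."""
        rng = np.random.default_rng(3)
        n_t = 290
        freqs = np.fft.rfftfreq(n_t, TR)
        for inj in DEFAULT_BANDS:
            spec = np.zeros((2, freqs.size), complex)
            mask = inj.bin_mask(n_t, TR)
            spec[:, mask] = rng.standard_normal((2, mask.sum())) + 1j * rng.standard_normal(
                (2, mask.sum())
            )
            y = np.fft.irfft(spec, n=n_t, axis=1)
            in_alff = alff(y, inj, TR)
            for other in DEFAULT_BANDS:
                if other.name != inj.name:
                    assert np.all(alff(y, other, TR) < 1e-10 * in_alff)

    def test_alff_on_filtered_equals_alff_on_raw(self):
        """Restricting the raw spectrum to band bins is equivalent to
        computing ALFF on the ideal band-filtered series."""
        rng = np.random.default_rng(14)
        y = rng.standard_normal((6, 145)) + 100.0
        for band in DEFAULT_BANDS:
            assert np.allclose(
                alff(y, band, TR), alff(bandpass_ideal(y, band, TR), band, TR), atol=1e-10
            )

    def test_sum_variant(self):
        rng = np.random.default_rng(4)
        y = rng.standard_normal((3, 145))
        n_bins = SLOW4.bin_mask(145, TR).sum()
        assert np.allclose(
            alff(y, SLOW4, TR, reduce="sum"), n_bins * alff(y, SLOW4, TR)
        )


# --------------------------------------------------------------------- ReHo
class TestReHo:
    def test_identical_series_give_unity(self):
        x = np.sin(np.linspace(0, 7, 50))
        block = np.tile(x, (8, 1))
        neigh = [np.arange(8)] * 8
        assert np.allclose(reho_kcc(block, neigh), 1.0)

    def test_reversed_pair_gives_zero(self):
        """K=2, n=3 with ranks (1,2,3) vs (3,2,1): rank sums are constant."""
        block = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        neigh = [np.array([0, 1]), np.array([0, 1])]
        assert np.allclose(reho_kcc(block, neigh), 0.0)

    def test_matches_bruteforce_oracle_random_neighborhoods(self, mesh5):
        """50 random K<=61, n<=145 neighborhoods agree with the rank-sum
        oracle to 1e-10."""
        rng = np.random.default_rng(5)
        n_v = mesh5.n_vertices
        data = rng.standard_normal((n_v, 145))
        neigh = [
            kring_neighbors(mesh5, int(v), int(rng.integers(1, 5)))
            for v in rng.choice(n_v, 50, replace=False)
        ]
        # pad to all vertices: vertex v gets its own 1-ring
        full = [kring_neighbors(mesh5, v, 1) for v in range(n_v)]
        for i, v in enumerate(rng.choice(n_v, 50, replace=False)):
            full[v] = neigh[i]
        W = reho_kcc(data, full)
        for v in range(n_v):
            expected = kcc_oracle(data[full[v]])
            assert W[v] == pytest.approx(expected, abs=1e-10)

    def test_expected_value_under_independence(self, mesh9):
        """E[W] = 1/K for independent series: mean over interior 61-vertex
        neighborhoods is 1/61 within 0.005."""
        from conftest import interior_vertices

        rng = np.random.default_rng(6)
        neigh = all_kring_neighborhoods(mesh9, 4)
        interior = interior_vertices(9, 4)
        vals = []
        for _ in range(4):
            data = rng.standard_normal((mesh9.n_vertices, 145))
            vals.append(reho_kcc(data, neigh)[interior].mean())
        assert np.mean(vals) == pytest.approx(1.0 / 61.0, abs=0.005)

    def test_constant_series_warns_but_defined(self):
        block = np.vstack([np.ones(10), np.random.default_rng(7).standard_normal(10)])
        neigh = [np.array([0, 1])] * 2
        with pytest.warns(UserWarning, match="constant"):
            W = reho_kcc(block, neigh)
        assert np.all((W >= 0) & (W <= 1))

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(st.integers(0, 2**31 - 1))
    def test_range_invariant(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((12, 20))
        neigh = [rng.choice(12, rng.integers(1, 12), replace=False) for _ in range(12)]
        W = reho_kcc(data, neigh)
        assert np.all((W >= 0.0) & (W <= 1.0))


# --------------------------------------------------------------------- VMHC
class TestVMHC:
    def _pairing(self, n):
        return np.r_[np.arange(n, 2 * n), np.arange(n)]

    def test_identical_pairs_hit_clip(self):
        x = np.random.default_rng(8).standard_normal((3, 60))
        data = np.vstack([x, x])
        v = vmhc(data, self._pairing(3))
        assert np.allclose(v, np.arctanh(1 - 1e-6))
        assert v[0] == pytest.approx(7.2543, abs=1e-3)

    def test_known_correlation(self):
        """r = 0.5 -> VMHC = atanh(0.5) = 0.5493 (constructed exactly)."""
        rng = np.random.default_rng(9)
        n_t = 4000
        a = rng.standard_normal(n_t)
        b = rng.standard_normal(n_t)
        a = (a - a.mean()) / a.std()
        b = (b - b.mean()) / b.std()
        b = b - (a @ b / n_t) * a  # orthogonalize
        b /= b.std()
        y = 0.5 * a + np.sqrt(0.75) * b  # corr(a, y) = 0.5 exactly
        v = vmhc(np.vstack([a, y]), np.array([1, 0]))
        assert v[0] == pytest.approx(np.arctanh(0.5), abs=1e-10)
        assert v[0] == pytest.approx(0.5493, abs=1e-4)

    def test_independent_pairs_average_near_zero(self):
        rng = np.random.default_rng(10)
        data = rng.standard_normal((400, 145))
        v = vmhc(data, self._pairing(200))
        assert abs(np.tanh(v).mean()) < 0.02

    def test_symmetric_across_pairing(self, mesh5):
        rng = np.random.default_rng(11)
        data = rng.standard_normal((mesh5.n_vertices, 80))
        v = vmhc(data, mesh5.homotopic_pair)
        assert np.allclose(v, v[mesh5.homotopic_pair])

    def test_zero_variance_pair_warns_and_zero(self):
        data = np.vstack([np.zeros(20), np.random.default_rng(12).standard_normal(20)])
        with pytest.warns(UserWarning, match="zero-variance"):
            v = vmhc(data, np.array([1, 0]))
        assert v[0] == 0.0 and v[1] == 0.0


# ---------------------------------------------------------------- summaries
class TestGlobalSummary:
    def test_constant_map(self):
        mean, sd = global_summary(np.full(10, 3.3), np.ones(10, bool))
        assert (mean, sd) == (pytest.approx(3.3), 0.0)

    def test_two_vertex_hand_computation(self):
        mean, sd = global_summary(np.array([0.0, 2.0, 99.0]), np.array([True, True, False]))
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(np.sqrt(2.0))  # ddof=1

    def test_order_invariance(self):
        rng = np.random.default_rng(13)
        vals = rng.standard_normal(40)
        mask = rng.random(40) > 0.3
        perm = rng.permutation(40)
        assert global_summary(vals, mask) == pytest.approx(
            global_summary(vals[perm], mask[perm])
        )

    def test_single_vertex_mask_rejected(self):
        with pytest.raises(ValueError):
            global_summary(np.ones(5), np.eye(5, dtype=bool)[0])


def test_average_scans():
    assert average_scans((10.0, 2.0), (14.0, 4.0)) == (12.0, 3.0)
    assert average_scans((5.0, 1.0), (5.0, 1.0)) == (5.0, 1.0)
    assert average_scans((10.0, 2.0), (14.0, 4.0)) == average_scans(
        (14.0, 4.0), (10.0, 2.0)
    )
    with pytest.raises(ValueError, match="provenance"):
        average_scans((1, 1), (1, 1), check_provenance=(("s1", 1), ("s2", 1)))


# ------------------------------------------------------------------- table
@pytest.fixture(scope="module")
def small_dataset(mesh5):
    spec = CohortSpec(n_subjects=3, visits_per_subject=2)
    sig = SignalSpec()
    scans, cohort, _ = generate_dataset(spec, sig, mesh5, seed=21)
    pre = [preprocess_scan(s) for s in scans]
    mask = np.ones(mesh5.n_vertices, bool)
    return pre, cohort, mask


class TestCsaTable:
    def test_row_schema_and_count(self, mesh5, small_dataset):
        pre, cohort, mask = small_dataset
        table = compute_csa_table(pre, mesh5, mask, cohort=cohort)
        # visits x 3 metrics x 3 bands x 2 statistics
        assert len(table) == 6 * 18
        assert set(table["metric"]) == {"ALFF", "ReHo", "VMHC"}
        assert set(table["statistic"]) == {"mean", "SD"}
        assert table["value"].notna().all()
        assert {"age", "sex", "education", "cohort"} <= set(table.columns)

    def test_metric_ranges(self, mesh5, small_dataset):
        pre, cohort, mask = small_dataset
        table = compute_csa_table(pre, mesh5, mask)
        reho = table[(table.metric == "ReHo") & (table.statistic == "mean")]["value"]
        assert ((reho >= 0) & (reho <= 1)).all()
        alff_means = table[(table.metric == "ALFF") & (table.statistic == "mean")]["value"]
        assert (alff_means >= 0).all()

    def test_homotopic_coupling_raises_vmhc(self, mesh5):
        """A w_h=1 cohort has larger global slow-4 VMHC than a w_h=0 cohort."""
        spec = CohortSpec(n_subjects=2, visits_per_subject=1)

        def vmhc_mean(w_h):
            sig = SignalSpec(homotopic_weight=w_h, noise_sd=0.0)
            scans, _, _ = generate_dataset(spec, sig, mesh5, seed=5)
            pre = [preprocess_scan(s) for s in scans]
            t = compute_csa_table(pre, mesh5, np.ones(mesh5.n_vertices, bool))
            sel = (t.metric == "VMHC") & (t.band == "slow-4") & (t.statistic == "mean")
            return t[sel]["value"].mean()

        assert vmhc_mean(1.0) > vmhc_mean(0.0) + 1.0
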