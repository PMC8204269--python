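"""Electrode-to-state linkage: bipolar derivation, TFR, correlation spectra,
FDR, assignment, agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainstates.linkage import (
    AssignmentTable,
    ContactGeometry,
    CorrelationSpectrum,
    ElectrodeAssignment,
    TFRMatrix,
    VoxelGrid,
    agreement_test,
    broadcast_to_grid,
    correlation_spectrum,
    fdr_mask,
    functional_assign,
    middle_bipolar,
    spatial_assign,
    tfr_power,
)


def _geom(n, label="e0"):
    coords = np.column_stack(
        [np.zeros(n), np.zeros(n), np.arange(n) * 3.5]
    )
    return ContactGeometry(electrode=label, subject="s00", coords=coords)


class TestMiddleBipolar:
    def test_common_mode_rejection(self, rng):
        sig = rng.standard_normal(100)
        rec = np.tile(sig[:, None], (1, 8))
        ch, _ = middle_bipolar(rec, _geom(8))
        np.testing.assert_allclose(ch, 0.0)

    @pytest.mark.parametrize("n,pair", [(8, (4, 5)), (16, (8, 9))])
    def test_pair_selection_and_subtraction_oracle(self, rng, n, pair):
        rec = rng.standard_normal((200, n))
        ch, mid = middle_bipolar(rec, _geom(n))
        a, b = pair
        np.testing.assert_array_equal(ch, rec[:, a - 1] - rec[:, b - 1])
        expected_mid = 0.5 * (np.array([0, 0, (a - 1) * 3.5]) + [0, 0, (b - 1) * 3.5])
        np.testing.assert_allclose(mid, expected_mid)

    def test_unsupported_layout_rejected(self, rng):
        with pytest.raises(ValueError, match="12"):
            middle_bipolar(np.zeros((10, 12)), _geom(12))


class TestTFRPower:
    def test_pure_tone_peaks_at_its_bin(self):
        fs, T = 250.0, 5000
        t = np.arange(T) / fs
        ch = np.sin(2 * np.pi * 10.0 * t)
        tfr = tfr_power(ch, fs=fs)
        mean_p = tfr.power[500:-500].mean(axis=0)
        assert tfr.freqs[mean_p.argmax()] == pytest.approx(10.0)

    def test_zero_signal_zero_power(self):
        tfr = tfr_power(np.zeros(1000), fs=250.0)
        np.testing.assert_allclose(tfr.power, 0.0)

    def test_white_noise_total_power_tracks_variance(self, rng):
        # Parseval-style check: total wavelet power averaged over time scales
        # with signal variance (ratio constant across variance levels)
        fs = 250.0
        a = rng.standard_normal(8000)
        b = 2.0 * rng.standard_normal(8000)
        pa = tfr_power(a, fs=fs).power[1000:-1000].mean()
        pb = tfr_power(b, fs=fs).power[1000:-1000].mean()
        assert pb / pa == pytest.approx(4.0, rel=0.2)

    def test_frequency_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="[Nn]yquist"):
            tfr_power(np.zeros(100), freqs=np.array([60.0]), fs=100.0)

    def test_alignment_selection(self, rng):
        ch = rng.standard_normal(500)
        idx = np.arange(7, 493)
        tfr = tfr_power(ch, fs=250.0, sample_indices=idx)
        assert tfr.power.shape[0] == idx.size


class TestCorrelationSpectrum:
    def test_hand_example(self):
        g = np.array([0.1, 0.9, 0.5, 0.3, 0.7])
        power = np.array([1.0, 5.0, 3.0, 2.0, 10.0])[:, None]
        tfr = TFRMatrix(power=power, freqs=np.array([10.0]), fs=250.0)
        cs = correlation_spectrum(g, tfr)
        assert cs.r[0] == pytest.approx(0.710, abs=5e-4)

    def test_affine_power_perfect_correlation(self):
        g = np.random.default_rng(0).uniform(0, 1, 50)
        power = np.column_stack([2.0 * g + 1.0, 5.0 * g + 0.2])
        tfr = TFRMatrix(power=power, freqs=np.array([5.0, 10.0]), fs=250.0)
        cs = correlation_spectrum(g, tfr)
        np.testing.assert_allclose(cs.r, 1.0, atol=1e-12)

    def test_constant_gamma_fully_flagged(self):
        power = np.random.default_rng(0).uniform(0, 1, (40, 3))
        tfr = TFRMatrix(power=power, freqs=np.array([1.0, 2.0, 3.0]), fs=250.0)
        cs = correlation_spectrum(np.full(40, 0.5), tfr)
        assert not cs.valid.any()
        assert cs.peak is None
        assert np.isnan(cs.r).all()

    def test_zero_variance_bin_excluded_from_peak(self, rng):
        g = rng.uniform(0, 1, 60)
        power = np.column_stack([np.full(60, 3.0), 0.5 * g])
        tfr = TFRMatrix(power=power, freqs=np.array([4.0, 8.0]), fs=250.0)
        cs = correlation_spectrum(g, tfr)
        assert not cs.valid[0] and cs.valid[1]
        assert cs.peak[1] == 8.0

    def test_matches_naive_pearson(self, rng):
        from scipy.stats import pearsonr

        g = rng.uniform(0, 1, 80)
        power = rng.uniform(0, 2, (80, 5))
        tfr = TFRMatrix(power=power, freqs=np.arange(5.0), fs=250.0)
        cs = correlation_spectrum(g, tfr)
        for j in range(5):
            r, p = pearsonr(g, power[:, j])
            assert abs(cs.r[j] - r) < 1e-12
            assert abs(cs.p[j] - p) < 1e-12


class TestFDRMask:
    def test_all_ones_empty(self):
        assert not fdr_mask(np.ones(20)).any()

    def test_single_small_p_survives(self):
        mask = fdr_mask(np.array([0.01]), q=0.05)
        assert mask.all()

    def test_matches_step_up_oracle(self, rng):
        p = rng.uniform(0, 1, 100) ** 2
        mask = fdr_mask(p, q=0.05)
        # direct BH: largest i with p_(i) <= i q / m
        order = np.argsort(p)
        ps = p[order]
        m = len(p)
        thresh = np.arange(1, m + 1) * 0.05 / m
        below = np.flatnonzero(ps <= thresh)
        oracle = np.zeros(m, dtype=bool)
        if below.size:
            oracle[order[: below.max() + 1]] = True
        np.testing.assert_array_equal(mask, oracle)

    def test_returns_min_surviving_r(self):
        p = np.array([0.001, 0.002, 0.9])
        r = np.array([0.5, -0.3, 0.9])
        mask, r_min = fdr_mask(p, q=0.05, r_values=r)
        assert mask[:2].all() and not mask[2]
        assert r_min == pytest.approx(0.3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_monotone_shrinking_p_never_removes_survivors(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 30)
        base = fdr_mask(p, q=0.1)
        j = int(rng.integers(30))
        p2 = p.copy()
        p2[j] *= rng.uniform(0, 1)
        new = fdr_mask(p2, q=0.1)
        assert np.all(new[base])  # previously significant stays significant


def _cs(state, r_peak, p_peak, f=10.0):
    return CorrelationSpectrum(
        r=np.array([r_peak]), p=np.array([p_peak]), freqs=np.array([f]),
        state=state, electrode="e", valid=np.array([True]),
        peak=(r_peak, f, p_peak),
    )


class TestFunctionalAssign:
    def test_clear_winner(self):
        spectra = [_cs(0, 0.1, 0.5), _cs(1, 0.5, 0.001), _cs(2, 0.05, 0.7)]
        state, r, f, p, tied = functional_assign(spectra)
        assert state == 1 and not tied

    def test_no_significant_state(self):
        spectra = [_cs(0, 0.1, 0.5), _cs(1, 0.2, 0.3)]
        state, *_ = functional_assign(spectra)
        assert state is None

    def test_tie_breaks_to_lower_index_and_flags(self):
        spectra = [_cs(1, 0.4, 0.01), _cs(0, 0.4, 0.01)]
        state, _, _, _, tied = functional_assign(spectra)
        assert state == 0 and tied

    def test_fully_degenerate_returns_none(self):
        cs = CorrelationSpectrum(
            r=np.array([np.nan]), p=np.array([np.nan]), freqs=np.array([1.0]),
            state=0, electrode="e", valid=np.array([False]), peak=None,
        )
        state, *_ = functional_assign([cs])
        assert state is None


def _line_grid():
    # voxels along x at 8 mm spacing, one parcel each
    coords = np.column_stack([np.arange(6) * 8.0, np.zeros(6), np.zeros(6)])
    return VoxelGrid(coords=coords, parcel=np.arange(6) % 3, spacing=8.0)


class TestSpatialAssign:
    def test_hand_distance_three_voxel_cluster(self):
        coords = np.array([[0, 0, 0], [8, 0, 0], [16, 0, 0]], dtype=float)
        grid = VoxelGrid(coords=coords, parcel=np.zeros(3, dtype=int), spacing=8.0)
        topo = np.array([[1.0, 2.0, 3.0]])  # one state, increasing along x
        # percentile 0 keeps all three voxels as one cluster
        state, d, tied = spatial_assign(np.array([8.0, 0, 0]), topo, grid, percentile=0.0)
        assert state == 0
        assert d[0] == pytest.approx(16.0 / 3.0)

    def test_midpoint_at_sole_suprathreshold_voxel(self):
        rngc = np.arange(10)
        coords = np.column_stack([rngc * 8.0, np.zeros(10), np.zeros(10)])
        grid = VoxelGrid(coords=coords, parcel=np.zeros(10, dtype=int), spacing=8.0)
        topo = np.zeros((2, 10))
        topo[0, 9] = 1.0  # state-0 cluster far away at x=72
        topo[1, 1] = 1.0  # state-1 cluster at x=8
        state, d, _ = spatial_assign(np.array([8.0, 0, 0]), topo, grid)
        assert state == 1
        assert d[1] == 0.0

    def test_identical_topographies_tie_flagged(self):
        grid = _line_grid()
        topo = np.tile(np.array([0.0, 1.0, 0.0, 0.0, 2.0, 0.0]), (2, 1))
        state, _, tied = spatial_assign(np.array([0.0, 0, 0]), topo, grid)
        assert state == 0 and tied

    def test_constant_topography_rejected(self):
        grid = _line_grid()
        with pytest.raises(ValueError, match="constant"):
            spatial_assign(np.zeros(3), np.ones((1, 6)), grid)

    def test_invariant_to_constant_offset(self, rng):
        grid = _line_grid()
        topo = rng.uniform(0, 1, (3, 6))
        s1, d1, _ = spatial_assign(np.array([4.0, 0, 0]), topo, grid)
        s2, d2, _ = spatial_assign(np.array([4.0, 0, 0]), topo + 100.0, grid)
        assert s1 == s2
        np.testing.assert_allclose(d1, d2)

    def test_broadcast_to_grid(self):
        grid = _line_grid()
        vals = np.array([10.0, 20.0, 30.0])
        vox = broadcast_to_grid(vals, grid)
        np.testing.assert_allclose(vox, [10, 20, 30, 10, 20, 30])


def _table(pairs):
    rows = [
        ElectrodeAssignment(
            electrode=f"e{i}", subject="s", functional_state=f, spatial_state=s
        )
        for i, (f, s) in enumerate(pairs)
    ]
    return AssignmentTable(rows=rows)


class TestAgreementTest:
    def test_hand_2x2_chi2(self):
        pairs = [(0, 0)] * 20 + [(0, 1)] * 5 + [(1, 0)] * 5 + [(1, 1)] * 20
        res = agreement_test(_table(pairs))
        assert res.chi2 == pytest.approx(18.0)
        assert res.dof == 1
        assert res.fraction == pytest.approx(0.8)

    def test_exact_independence_chi2_zero(self):
        # observed equals expected: counts proportional to row x col margins
        pairs = (
            [(0, 0)] * 4 + [(0, 1)] * 4 + [(1, 0)] * 4 + [(1, 1)] * 4
        )
        res = agreement_test(_table(pairs))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_unassigned_excluded(self):
        pairs = [(0, 0)] * 5 + [(1, 1)] * 5 + [(None, 0)] * 3
        res = agreement_test(_table(pairs))
        assert res.total == 10
        assert res.n_unassigned == 3

    def test_degenerate_margins_rejected(self):
        res_pairs = [(0, 0)] * 5 + [(0, 1)] * 5  # single functional category
        with pytest.raises(ValueError, match="degenerate"):
            agreement_test(_table(res_pairs))
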