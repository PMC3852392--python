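"""Windowed heterozygosity profiles, empirical thresholds, region calling
and timeline classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sweepscan import sweep as sw
from sweepscan.sweep import (
    ScanConfig,
    SweepRegion,
    call_regions,
    classify_timeline,
    empirical_threshold,
    marker_het,
    n_independent_windows,
    profile_change,
    profile_difference,
    window_profile,
)

from conftest import make_map


class TestMarkerHet:
    @pytest.mark.parametrize("m,expected", [(0.5, 0.5), (1.0, 0.0), (0.8, 0.32)])
    def test_known_values(self, m, expected):
        assert marker_het(m) == pytest.approx(expected)

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=1000, derandomize=True)
    def test_equals_2m_1_minus_m(self, m):
        # algebraic identity: 1 - (m^2 + (1-m)^2) == 2m(1-m)
        assert marker_het(m) == pytest.approx(2 * m * (1 - m), abs=1e-15)

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            marker_het(bad)

    def test_symmetric_in_allele_labelling(self):
        m = np.linspace(0, 1, 11)
        assert np.allclose(marker_het(m), marker_het(1 - m))


def _profile(het, markers, W=3, step=1):
    return window_profile(np.asarray(het, float), markers,
                          ScanConfig(window_size=W, step=step))


class TestWindowProfile:
    def test_simple_means(self):
        p = _profile([0.1, 0.2, 0.3, 0.4], make_map(4))
        assert np.allclose(p.hz, [0.2, 0.3])

    def test_constant_input(self):
        p = _profile([0.25] * 6, make_map(6))
        assert np.allclose(p.hz, 0.25)

    def test_windows_never_span_chromosomes(self):
        markers = make_map(6, chrom=["chr1"] * 3 + ["chr2"] * 3)
        p = _profile([0.1] * 6, markers)
        assert p.n_windows == 2
        assert list(p.chromosome) == ["chr1", "chr2"]

    def test_short_chromosome_skipped(self, caplog):
        markers = make_map(5, chrom=["chr1"] * 3 + ["chr2"] * 2)
        p = _profile([0.1] * 5, markers)
        assert p.n_windows == 1

    def test_nan_markers_renormalized(self):
        p = _profile([0.1, np.nan, 0.3], make_map(3))
        assert p.hz[0] == pytest.approx(0.2)

    def test_matches_bruteforce_on_random_input(self):
        rng = np.random.default_rng(7)
        het = rng.uniform(0, 0.5, 57)
        markers = make_map(57)
        W = 10
        p = window_profile(het, markers, ScanConfig(window_size=W))
        brute = np.array([het[i:i + W].mean() for i in range(57 - W + 1)])
        assert np.allclose(p.hz, brute)


class TestProfileArithmetic:
    def test_difference_identity_and_antisymmetry(self):
        markers = make_map(5)
        a = _profile([0.4] * 5, markers)
        b = _profile([0.1] * 5, markers)
        assert np.allclose(profile_difference(a, a), 0.0)
        assert np.allclose(profile_difference(a, b), 0.3)
        assert np.allclose(profile_difference(a, b), -profile_difference(b, a))

    def test_mismatched_grids_rejected(self):
        a = _profile([0.1] * 5, make_map(5))
        b = _profile([0.1] * 6, make_map(6))
        with pytest.raises(ValueError):
            profile_difference(a, b)

    def test_change_semantics(self):
        d1 = np.array([0.0, 0.1, 0.2])
        d2 = np.array([0.3, 0.1, 0.0])
        assert np.allclose(profile_change(d1, d1), 0.0)
        assert np.allclose(profile_change(np.zeros(3), d2), d2)
        assert np.allclose(profile_change(d1, d2), -profile_change(d2, d1))


class TestEmpiricalThreshold:
    def test_nonoverlapping_window_count(self):
        # genome of 55,983 markers in 100-marker windows -> 560 windows
        assert n_independent_windows(55_983, 100) == 560

    def test_standard_normal_cut(self):
        # per-tail q = 0.025/560 ~ 4.46e-5; Phi^-1(q) = -3.9180 (frozen from
        # an independent erfinv evaluation)
        rng = np.random.default_rng(0)
        change = rng.standard_normal(500_000)
        cfg = ScanConfig(window_size=100)
        lo, hi = empirical_threshold(change, cfg, 55_983)
        mu, sd = change.mean(), change.std(ddof=1)
        assert lo == pytest.approx(mu - 3.9180026787853977 * sd, rel=1e-9)
        assert hi == pytest.approx(mu + 3.9180026787853977 * sd, rel=1e-9)

    def test_location_scale_equivariance(self):
        rng = np.random.default_rng(1)
        change = rng.standard_normal(10_000)
        cfg = ScanConfig()
        lo1, hi1 = empirical_threshold(change, cfg, 10_000)
        lo2, hi2 = empirical_threshold(3 * change + 1, cfg, 10_000)
        assert lo2 == pytest.approx(3 * lo1 + 1)
        assert hi2 == pytest.approx(3 * hi1 + 1)

    def test_degenerate_null_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            empirical_threshold(np.zeros(100), ScanConfig(), 1000)


class TestCallRegions:
    def _grid(self, n, W=3):
        markers = make_map(n + 2)
        return _profile([0.1] * (n + 2), markers, W=W)

    def test_no_flagged_windows(self):
        grid = self._grid(10)
        assert call_regions(np.zeros(grid.n_windows), (-1, 1), grid) == []

    def test_isolated_window_spans_its_markers(self):
        grid = self._grid(10)
        change = np.zeros(grid.n_windows)
        change[4] = -2.0
        regions = call_regions(change, (-1, 1), grid)
        assert len(regions) == 1
        r = regions[0]
        assert r.direction == "loss"
        assert r.start_bp == grid.start_bp[4] and r.end_bp == grid.end_bp[4]

    def test_runs_merged_and_disjoint(self):
        grid = self._grid(20)
        rng = np.random.default_rng(5)
        change = rng.normal(0, 1, grid.n_windows)
        regions = call_regions(change, (-1.5, 1.5), grid)
        # every flagged window covered exactly once; regions sorted & disjoint
        flagged = set(np.flatnonzero((change < -1.5) | (change > 1.5)))
        covered = [w for r in regions for w in r.window_indices]
        assert sorted(covered) == sorted(set(covered))
        assert flagged <= set(covered)
        for r1, r2 in zip(regions, regions[1:]):
            if r1.chromosome == r2.chromosome:
                assert r1.last_marker_index >= r1.first_marker_index
                if r1.direction == r2.direction:
                    assert r2.first_marker_index > r1.last_marker_index

    def test_tie_at_cut_not_flagged(self):
        grid = self._grid(10)
        change = np.full(grid.n_windows, -1.0)
        assert call_regions(change, (-1, 1), grid) == []


def _uniform_profile(pop, hz_value, n_win=10, region=None, region_hz=None):
    """Profile with constant Hz and optionally a distinct region level."""
    hz = np.full(n_win, hz_value, dtype=float)
    if region is not None:
        hz[list(region)] = region_hz
    markers = make_map(n_win)
    return sw.HetProfile(pop, 1, 1, np.array(["chr1"] * n_win, dtype=object),
                         np.arange(n_win), np.arange(n_win),
                         markers.position_bp, markers.position_bp, hz)


class TestClassifyTimeline:
    REGION = SweepRegion("chr1", 3000, 4000, "loss", -0.3, (2, 3), 2, 3)

    def _profiles(self, states):
        """states: role -> 'fixed' | 'reduced' | 'polymorphic'."""
        level = {"fixed": 0.0, "reduced": 0.05, "polymorphic": 0.3}
        return {
            role: _uniform_profile(role, 0.3, region=(2, 3), region_hz=level[s])
            for role, s in states.items()
        }

    def test_hw_sweep_between_split_and_gen50(self):
        # polymorphic at 40, fixed at 50/53, reduced in the relaxed line:
        # onset in (40,45], fixation in (45,50]
        states = dict.fromkeys(sw.SUBGROUPS, "polymorphic")
        states.update(HWS50="fixed", HWS53="fixed", HWR9="reduced")
        call = classify_timeline(self.REGION, self._profiles(states), ScanConfig())
        assert call.rule == "c" and call.lineage == "HW"
        assert call.onset_interval == "(40,45]"
        assert call.fixation_interval == "(45,50]"

    def test_all_fixed_predates_gen40(self):
        states = dict.fromkeys(sw.SUBGROUPS, "fixed")
        call = classify_timeline(self.REGION, self._profiles(states), ScanConfig())
        assert call.rule == "a" and call.lineage == "both"
        assert call.onset_interval == "<=40"

    def test_all_polymorphic_is_not_fixed(self):
        states = dict.fromkeys(sw.SUBGROUPS, "polymorphic")
        call = classify_timeline(self.REGION, self._profiles(states), ScanConfig())
        assert call.rule == "e"
        assert call.fixation_interval == "not fixed"

    def test_relaxed_line_fixed_leaves_fixation_open(self):
        states = dict.fromkeys(sw.SUBGROUPS, "polymorphic")
        states.update(LWS50="fixed", LWS53="fixed", LWR9="fixed")
        call = classify_timeline(self.REGION, self._profiles(states), ScanConfig())
        assert call.rule == "b" and call.lineage == "LW"
        assert call.onset_interval == "(40,45]"

    def test_late_fixation_only_in_53(self):
        states = dict.fromkeys(sw.SUBGROUPS, "polymorphic")
        states.update(HWS53="fixed")
        call = classify_timeline(self.REGION, self._profiles(states), ScanConfig())
        assert call.rule == "d"
        assert call.fixation_interval == "(50,53]"

    def test_missing_subgroup_is_error(self):
        states = dict.fromkeys(sw.SUBGROUPS, "polymorphic")
        profiles = self._profiles(states)
        del profiles["LWR9"]
        with pytest.raises(ValueError, match="LWR9"):
            classify_timeline(self.REGION, profiles, ScanConfig())
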