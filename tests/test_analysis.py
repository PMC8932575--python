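"""Avalanche detection, power-law fitting, correlations, profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epivertex.analysis import (
    FitError,
    FrameRecord,
    circularity,
    detect_avalanches,
    fit_power_law,
    packing_stats,
    radial_profile,
    record_frame,
    spearman,
    trajectories,
)
from epivertex.mesh import Cell, TissueState


def scalar_table(times, mean_areas, total=None):
    n = len(times)
    total = total if total is not None else 100.0 * np.ones(n)
    return pd.DataFrame(
        {
            "time": times,
            "mean_cell_area": mean_areas,
            "total_area": total,
            "anterior_area": total,
            "posterior_area": np.zeros(n),
        }
    )


class TestDetector:
    def test_threshold_rule_single_event(self):
        tab = scalar_table([31, 32, 33, 34], [5.00, 4.90, 4.80, 4.95],
                           total=np.array([100.0, 99, 98, 101]))
        evs = detect_avalanches(tab, threshold=0.1, burn_in=30.0)
        assert len(evs) == 1
        assert evs[0].mean_area_jump == pytest.approx(0.15)
        assert evs[0].magnitude == pytest.approx(100 * 3 / 98)
        assert evs[0].pre_mean_area == pytest.approx(4.80)

    def test_strictly_decreasing_series_has_no_events(self):
        tab = scalar_table([31, 32, 33, 34], [5.0, 4.9, 4.8, 4.7])
        assert detect_avalanches(tab, threshold=0.1, burn_in=30.0) == []

    def test_burn_in_suppresses_early_events(self):
        tab = scalar_table([19, 20, 21], [4.8, 5.0, 5.0])
        assert detect_avalanches(tab, threshold=0.1, burn_in=30.0) == []
        assert len(detect_avalanches(tab, threshold=0.1, burn_in=10.0)) == 1

    def test_prepending_pre_burn_in_frames_is_invariant(self):
        tail_t, tail_m = [31, 32, 33, 34], [5.00, 4.90, 4.80, 4.95]
        tab1 = scalar_table(tail_t, tail_m)
        tab2 = scalar_table([5, 12] + tail_t, [7.0, 6.0] + tail_m)
        e1 = detect_avalanches(tab1, threshold=0.1, burn_in=30.0)
        e2 = detect_avalanches(tab2, threshold=0.1, burn_in=30.0)
        assert [(e.time, e.magnitude) for e in e1] == [(e.time, e.magnitude) for e in e2]

    def test_consecutive_jumps_merge_into_one_event(self):
        tab = scalar_table([31, 32, 33, 34, 35], [4.0, 4.15, 4.31, 4.31, 4.31])
        evs = detect_avalanches(tab, threshold=0.1, burn_in=30.0)
        assert len(evs) == 1
        assert evs[0].mean_area_jump == pytest.approx(0.31)

    def test_length_scale_converts_threshold(self):
        # 0.05 sim jump with scale 2 -> 0.2 square microns
        tab = scalar_table([31, 32], [1.00, 1.05])
        assert len(detect_avalanches(tab, threshold=0.1, burn_in=30, length_scale=2.0)) == 1
        assert detect_avalanches(tab, threshold=0.1, burn_in=30, length_scale=1.0) == []

    def test_growth_corrected_magnitude_subtracts_baseline(self):
        # steady 1% growth per frame, one real discontinuity
        t = np.arange(31, 41, dtype=float)
        A = 100 * 1.01 ** np.arange(10)
        A[6:] *= 1.05                      # 5% jump between frames 5 and 6
        m = np.full(10, 5.0)
        m[6:] += 0.2                       # detectable density jump
        tab = scalar_table(t, m, total=A)
        ev = detect_avalanches(tab, threshold=0.1, burn_in=30.0, growth_corrected=True)
        assert len(ev) == 1
        assert ev[0].magnitude == pytest.approx(5.0, abs=0.3)   # baseline removed
        assert ev[0].magnitude_raw == pytest.approx(6.05, abs=0.3)

    def test_too_few_frames(self):
        assert detect_avalanches(scalar_table([31], [5.0]), burn_in=30.0) == []


class TestPowerLawFit:
    def test_recovers_known_exponent(self):
        rng = np.random.default_rng(1)
        # inverse-CDF sampling of p(x) ~ x^-1.5 on [1, 100]
        u = rng.uniform(size=100000)
        a, b, tau = 1.0, 100.0, 1.5
        x = (a ** (1 - tau) + u * (b ** (1 - tau) - a ** (1 - tau))) ** (1 / (1 - tau))
        fit = fit_power_law(x)
        assert 1.45 <= fit.tau <= 1.55

    @pytest.mark.parametrize("tau", [1.2, 1.5, 2.0])
    def test_recovery_within_two_standard_errors(self, tau):
        rng = np.random.default_rng(int(tau * 10))
        u = rng.uniform(size=30000)
        a, b = 1.0, 100.0
        x = (a ** (1 - tau) + u * (b ** (1 - tau) - a ** (1 - tau))) ** (1 / (1 - tau))
        fit = fit_power_law(x)
        assert abs(fit.tau - tau) <= max(2 * fit.stderr, 0.05)

    def test_exponential_sample_prefers_semilog(self):
        rng = np.random.default_rng(2)
        x = rng.exponential(scale=3.0, size=50000) + 0.5
        fit = fit_power_law(x, x_cut=np.quantile(x, 0.99))
        assert fit.r2_semilog > fit.r2_loglog

    def test_degenerate_sample_raises(self):
        with pytest.raises(FitError):
            fit_power_law(np.full(100, 3.0))
        with pytest.raises(FitError):
            fit_power_law([1.0, 2.0])

    def test_few_events_warns(self):
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning, match="noisy"):
            fit_power_law(rng.uniform(1, 50, size=30))


class TestSpearman:
    def test_strictly_decreasing_is_minus_one(self):
        x = np.arange(10.0)
        rho, p = spearman(x, -(x**3))
        assert rho == pytest.approx(-1.0)
        assert p < 0.01

    def test_independent_samples_near_zero(self):
        rng = np.random.default_rng(4)
        rho, p = spearman(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(rho) < 0.1
        assert p > 0.01

    def test_matches_brute_force_ranks(self):
        x = [3.1, 1.2, 5.0, 2.2, 4.4]
        y = [10.0, 30.0, 5.0, 20.0, 8.0]
        rho, _ = spearman(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_constant_input_is_undefined(self):
        rho, p = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho) and np.isnan(p)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [1, 2])


class TestProfilesAndTrajectories:
    def test_flat_profile_on_uniform_lattice(self, hex_patch):
        frame = record_frame(hex_patch)
        centers, means, spread = radial_profile(frame, n_bins=4)
        assert spread < 0.02 * np.nanmean(means)

    def test_binning_matches_brute_force(self, circle_tissue):
        frame = record_frame(circle_tissue)
        n_bins = 5
        centers, means, _ = radial_profile(frame, n_bins=n_bins)
        cells = frame.cells
        w = cells["area"].to_numpy()
        cx = (cells["x"] * w).sum() / w.sum()
        cy = (cells["y"] * w).sum() / w.sum()
        r = np.hypot(cells["x"] - cx, cells["y"] - cy).to_numpy()
        edges = np.linspace(0, r.max() * (1 + 1e-12), n_bins + 1)
        for b in range(n_bins):
            sel = (r >= edges[b]) & (r < edges[b + 1])
            if sel.any():
                assert means[b] == pytest.approx(w[sel].mean())

    def test_identity_frames_have_zero_displacement(self, circle_tissue):
        f = record_frame(circle_tissue)
        tr = trajectories(f, f)
        assert tr["length"].abs().max() == 0.0

    def test_rigid_translation(self, circle_tissue):
        f0 = record_frame(circle_tissue)
        moved = circle_tissue.copy()
        moved.vertices = moved.vertices + np.array([1.0, 0.0])
        f1 = record_frame(moved)
        tr = trajectories(f0, f1)
        assert tr["length"].to_numpy() == pytest.approx(np.ones(len(tr)), abs=1e-9)
        assert tr["angle"].to_numpy() == pytest.approx(np.zeros(len(tr)), abs=1e-9)

    def test_synthetic_vortex_field(self, circle_tissue):
        # rotate the tissue about its center: tangential displacements,
        # lengths growing with radius
        f0 = record_frame(circle_tissue)
        center = circle_tissue.vertices[circle_tissue.used_vertices()].mean(axis=0)
        th = 0.2
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = circle_tissue.copy()
        moved.vertices = center + (moved.vertices - center) @ rot.T
        f1 = record_frame(moved)
        tr = trajectories(f0, f1)
        r = np.hypot(f0.cells["x"] - center[0], f0.cells["y"] - center[1]).to_numpy()
        rho, p = spearman(r, tr["length"].to_numpy())
        assert rho > 0.9  # displacement grows with radius
        # displacement is perpendicular to the radius vector
        rad = np.stack([f0.cells["x"] - center[0], f0.cells["y"] - center[1]], 1)
        disp = np.stack([tr["dx"], tr["dy"]], 1)
        dots = (rad * disp).sum(1) / (np.linalg.norm(rad, axis=1) * np.linalg.norm(disp, axis=1))
        assert np.abs(dots).max() < 0.2

    def test_no_shared_ids_raises(self, circle_tissue):
        f0 = record_frame(circle_tissue)
        f1 = FrameRecord(
            time=1, total_area=1, anterior_area=1, posterior_area=0, n_cells=1,
            mean_cell_area=1,
            cells=pd.DataFrame({"id": [99999], "x": [0.0], "y": [0.0]}),
        )
        with pytest.raises(ValueError):
            trajectories(f0, f1)


class TestPacking:
    def test_perfect_hex_lattice_is_degenerate(self, hex_patch):
        interior_only = TissueState(
            vertices=hex_patch.vertices.copy(),
            cells={
                cid: hex_patch.cells[cid]
                for cid in hex_patch.cells
                if len(hex_patch.neighbors()[cid]) == 6
            },
        )
        ps = packing_stats(record_frame(interior_only))
        assert ps.degenerate
        assert ps.side_distribution == {6: 1.0}

    def test_class_counts_match_brute_force(self, circle_tissue):
        frame = record_frame(circle_tissue)
        ps = packing_stats(frame)
        sides = [len(c.vertices) for c in circle_tissue.cells.values()]
        for n in set(sides):
            assert ps.side_distribution[n] == pytest.approx(sides.count(n) / len(sides))

    def test_lewis_law_positive_slope_on_disordered_tissue(self, circle_tissue):
        ps = packing_stats(record_frame(circle_tissue))
        assert not ps.degenerate
        assert ps.lewis_slope > 0  # bigger cells have more sides


class TestCircularity:
    def test_circle_is_one(self):
        ang = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        t = TissueState(
            vertices=np.stack([np.cos(ang), np.sin(ang)], 1),
            cells={0: Cell(vertices=list(range(200)))},
        )
        assert circularity(t) == pytest.approx(1.0, abs=1e-3)

    def test_square_value(self, unit_square):
        assert circularity(unit_square) == pytest.approx(np.pi / 4, abs=1e-12)

    def test_relaxed_fixture_is_nearly_circular(self, circle_tissue):
        assert circularity(circle_tissue) >= 0.9
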