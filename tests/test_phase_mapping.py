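"""Phase computation, PS detection by topological charge, tracking,
density maps, and the tethering label."""

import numpy as np
import pandas as pd
import pytest

from rotortether.monodomain_sim import StateHistory
from rotortether.phase_mapping import (PS_COLUMNS, boundary_winding,
                                       combine_maps, compute_phase, detect_ps,
                                       density_mass, link_tracks, ps_density,
                                       tethering_mask, track_summary)
from rotortether.tissue import make_sheet_domain


def _vortex_phase(dom, x0, y0, sign=1):
    dx = dom.positions[:, 0] - x0
    return np.arctan2(dom.positions[:, 1] - y0, sign * dx)


class TestDetector:
    @pytest.mark.parametrize("n", [11, 21, 41])
    def test_analytic_vortex_detected_exactly(self, n):
        dom = make_sheet_domain(n, n, 1.0)
        x0 = y0 = (n - 1) / 2.0 + 0.3
        ps = detect_ps(_vortex_phase(dom, x0, y0), dom)
        assert len(ps) == 1
        assert ps["chirality"].iloc[0] == 1
        # localized within one grid cell of the true center
        assert abs(ps["x_mm"].iloc[0] - x0) <= 1.0
        assert abs(ps["y_mm"].iloc[0] - y0) <= 1.0

    def test_mirrored_field_flips_chirality(self):
        dom = make_sheet_domain(15, 15, 1.0)
        ps = detect_ps(_vortex_phase(dom, 7.2, 6.8, sign=-1), dom)
        assert len(ps) == 1 and ps["chirality"].iloc[0] == -1

    def test_uniform_phase_yields_no_ps(self):
        dom = make_sheet_domain(15, 15, 1.0)
        assert len(detect_ps(np.full(dom.n_nodes, 0.7), dom)) == 0

    def test_net_chirality_equals_boundary_winding(self, rng):
        """Charge bookkeeping on a simply connected sheet."""
        dom = make_sheet_domain(25, 25, 1.0)
        for _ in range(5):
            centers = rng.uniform(3, 21, size=(3, 2))
            signs = rng.choice([-1, 1], size=3)
            phase = np.zeros(dom.n_nodes)
            for (cx, cy), s in zip(centers, signs):
                phase = phase + s * np.arctan2(dom.positions[:, 1] - cy,
                                               dom.positions[:, 0] - cx)
            phase = (phase + np.pi) % (2 * np.pi) - np.pi
            ps = detect_ps(phase, dom)
            assert ps["chirality"].sum() == boundary_winding(phase, dom)


class TestPhaseField:
    def test_axis_case(self):
        hist = StateHistory(time=np.array([0.0]),
                            v=np.array([[0.5]], dtype=np.float32),
                            h=np.array([[0.9]], dtype=np.float32),
                            dt=1.0, sample_interval=1.0)
        theta = compute_phase(hist, origin=(0.5, 0.6), check_origin=False)
        assert theta[0, 0] == pytest.approx(np.pi / 2, abs=1e-6)

    def test_resting_tissue_has_constant_phase(self):
        v = np.zeros((10, 5), dtype=np.float32)
        h = np.ones((10, 5), dtype=np.float32)
        hist = StateHistory(time=np.arange(10.0), v=v, h=h, dt=1.0,
                            sample_interval=1.0)
        theta = compute_phase(hist, check_origin=False)
        assert np.ptp(theta) < 1e-6

    def test_action_potential_winds_once(self, default_params):
        """A full beat traces a loop encircling the phase origin once."""
        from rotortether.mms_model import simulate_single_cell
        out = simulate_single_cell(default_params, [5.0], duration=500.0)
        v = out["v"][None].T.astype(np.float32)  # (T, 1)
        h = out["h"][None].T.astype(np.float32)
        hist = StateHistory(time=out["t"], v=v.reshape(-1, 1),
                            h=h.reshape(-1, 1), dt=0.02, sample_interval=0.02)
        theta = compute_phase(hist, origin=(0.5, 0.6))[:, 0]
        d = np.diff(theta.astype(float))
        d = (d + np.pi) % (2 * np.pi) - np.pi
        assert abs(abs(d.sum()) - 2 * np.pi) < 0.1

    def test_warns_if_origin_outside_loop(self):
        v = np.zeros((40, 20), dtype=np.float32)
        h = np.ones((40, 20), dtype=np.float32)
        hist = StateHistory(time=np.arange(40.0), v=v, h=h, dt=1.0,
                            sample_interval=1.0)
        with pytest.warns(UserWarning, match="origin"):
            compute_phase(hist, origin=(0.5, 0.6))


class TestTracks:
    def _records(self, entries):
        return pd.DataFrame(entries, columns=PS_COLUMNS[:-1]).assign(track_id=-1)

    def test_stationary_ps_makes_one_track(self):
        rec = self._records([[t, 5.0, 5.0, 0.0, 1, 0] for t in range(10)])
        linked = link_tracks(rec, max_jump=2.0)
        assert linked["track_id"].nunique() == 1
        assert len(linked) == 10

    def test_distant_ps_split_tracks(self):
        rec = self._records([[0, 0.0, 0.0, 0.0, 1, 0], [1, 50.0, 0.0, 0.0, 1, 1]])
        linked = link_tracks(rec, max_jump=5.0)
        assert linked["track_id"].nunique() == 2

    def test_chirality_never_mixes_in_a_track(self):
        rec = self._records([[0, 0.0, 0.0, 0.0, 1, 0], [1, 0.5, 0.0, 0.0, -1, 1]])
        linked = link_tracks(rec, max_jump=5.0)
        assert linked["track_id"].nunique() == 2

    def test_creation_annihilation_pair(self):
        entries = []
        for t in range(5):
            entries.append([10 + t, 5.0 - 0.2 * t, 5.0, 0.0, 1, 0])
            entries.append([10 + t, 8.0 + 0.2 * t, 5.0, 0.0, -1, 1])
        linked = link_tracks(self._records(entries), max_jump=2.0)
        summary = track_summary(linked)
        assert len(summary) == 2
        assert set(summary["chirality"]) == {-1, 1}
        assert (summary["t_birth"] == 10).all()
        assert (summary["t_death"] == 14).all()


class TestDensityAndMask:
    def _stationary_density(self, dom, window=(0.0, 100.0), smoothing=0.0):
        elem = 40
        times = np.arange(window[0], window[1], 2.0)
        rec = pd.DataFrame({
            "t_ms": times, "x_mm": 5.0, "y_mm": 5.0, "z_mm": 0.0,
            "chirality": 1, "element": elem, "track_id": 0})
        return rec, ps_density(rec, dom, window, sample_interval=2.0,
                               smoothing_radius=smoothing)

    def test_mass_conservation(self):
        dom = make_sheet_domain(15, 15, 1.0)
        rec, dmap = self._stationary_density(dom, smoothing=2.0)
        assert density_mass(dmap, dom) == pytest.approx(len(rec) * 2.0, rel=1e-9)

    def test_zero_ps_gives_zero_map(self):
        dom = make_sheet_domain(15, 15, 1.0)
        empty = pd.DataFrame(columns=PS_COLUMNS)
        dmap = ps_density(empty, dom, (0.0, 100.0), sample_interval=2.0)
        assert not dmap.density.any()

    def test_normalized_density_invariant_to_window_length(self):
        dom = make_sheet_domain(15, 15, 1.0)
        _, d1 = self._stationary_density(dom, window=(0.0, 100.0))
        _, d2 = self._stationary_density(dom, window=(0.0, 200.0))
        assert np.allclose(d1.density, d2.density, rtol=1e-6, atol=1e-12)

    def test_empty_window_rejected(self):
        dom = make_sheet_domain(15, 15, 1.0)
        empty = pd.DataFrame(columns=PS_COLUMNS)
        with pytest.raises(ValueError, match="window"):
            ps_density(empty, dom, (100.0, 100.0), sample_interval=2.0)

    def test_threshold_arithmetic(self):
        from rotortether.phase_mapping import PSDensityMap
        dmap = PSDensityMap(density=np.array([0.0, 0.0, 0.0, 10.0]),
                            window=(0, 1), smoothing_radius=0, domain_nodes=4)
        mask = tethering_mask(dmap)
        assert mask.threshold == pytest.approx(7.5)
        assert mask.label.tolist() == [False, False, False, True]

    def test_uniform_density_gives_empty_mask(self):
        from rotortether.phase_mapping import PSDensityMap
        dmap = PSDensityMap(density=np.full(50, 3.3), window=(0, 1),
                            smoothing_radius=0, domain_nodes=50)
        assert tethering_mask(dmap).label.sum() == 0

    def test_mask_shift_invariant(self, rng):
        from rotortether.phase_mapping import PSDensityMap
        d = rng.exponential(size=200)
        m1 = tethering_mask(PSDensityMap(d, (0, 1), 0, 200))
        m2 = tethering_mask(PSDensityMap(d + 17.0, (0, 1), 0, 200))
        assert np.array_equal(m1.label, m2.label)


class TestCombineMaps:
    def _map(self, density):
        from rotortether.phase_mapping import PSDensityMap
        return PSDensityMap(np.asarray(density, dtype=float), (0, 1), 0,
                            len(density))

    def test_identical_maps_have_zero_dissimilarity(self):
        m = self._map([1.0, 2.0, 3.0])
        _, dis = combine_maps([m, m])
        assert dis[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_maps_fully_dissimilar(self):
        _, dis = combine_maps([self._map([1.0, 0.0]), self._map([0.0, 1.0])])
        assert dis[0, 1] == pytest.approx(1.0)

    def test_sum_preserves_mass(self):
        maps = [self._map([1.0, 2.0]), self._map([3.0, 4.0]),
                self._map([5.0, 6.0])]
        combined, _ = combine_maps(maps)
        assert combined.density.sum() == pytest.approx(21.0)

    def test_mismatched_domains_rejected(self):
        with pytest.raises(ValueError, match="domain"):
            combine_maps([self._map([1.0, 2.0]), self._map([1.0, 2.0, 3.0])])


class TestSpiralFixture:
    """Sustained cross-field spiral: single dominant track, unimodal map."""

    def test_single_dominant_track_and_unimodal_density(self, spiral_run):
        from rotortether.experiments import spiral_track_report
        domain, hist = spiral_run
        window = (1000.0, 2000.0)
        linked, summary = spiral_track_report(domain, hist, window)
        assert len(linked) > 0
        span = window[1] - window[0]
        dominant = summary[summary["duration"] >= 0.6 * span]
        assert len(dominant) == 1
        # unimodal density: the peak region is spatially compact
        dmap = ps_density(linked, domain, window,
                          sample_interval=hist.sample_interval,
                          smoothing_radius=2.0)
        peak = dmap.density.max()
        high = domain.positions[dmap.density > 0.5 * peak, :2]
        centroid = high.mean(axis=0)
        assert np.linalg.norm(high - centroid, axis=1).max() < 12.0

    def test_density_peak_inside_core_region(self, spiral_run):
        domain, hist = spiral_run
        from rotortether.phase_mapping import detect_ps_history
        window = (1000.0, 2000.0)
        rec = detect_ps_history(hist, domain, window=window)
        dmap = ps_density(rec, domain, window,
                          sample_interval=hist.sample_interval)
        peak_node = int(np.argmax(dmap.density))
        core = rec[["x_mm", "y_mm"]].median().to_numpy()
        assert np.linalg.norm(domain.positions[peak_node, :2] - core) < 6.0
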