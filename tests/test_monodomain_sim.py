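"""Monodomain solver: propagation, activation maps, refractoriness, pacing."""

import numpy as np
import pytest
from dataclasses import replace

from rotortether.mms_model import MMSParameters, ParameterFieldSet, cable_cv
from rotortether.monodomain_sim import (ERP_ABOVE_GRID, ERP_BELOW_GRID,
                                        StateHistory, burst_protocol,
                                        extract_lat, make_pacing_sites,
                                        measure_erp, run, s1s2_protocol,
                                        single_pulse)
from rotortether.tissue import make_sheet_domain


def _left_edge(dom):
    ny, nx = dom.shape
    idx = np.arange(dom.n_nodes)
    return idx[idx % nx < 2]


class TestProtocols:
    def test_pulse_duration_must_be_positive(self):
        with pytest.raises(ValueError, match="duration"):
            single_pulse([0], duration=0.0)

    def test_s2_must_be_premature(self):
        with pytest.raises(ValueError, match="S2"):
            s1s2_protocol([0], s1_count=2, s1_cl=300.0, s2_couplings=[350.0])

    def test_burst_needs_at_least_one_beat(self):
        with pytest.raises(ValueError, match="beat count"):
            burst_protocol([0], n_beats=0)


class TestSolverBasics:
    def test_rest_is_conserved_without_stimulus(self, uniform_fields_60):
        dom = make_sheet_domain(15, 15, 1.0)
        f = uniform_fields_60(dom.n_nodes)
        proto = single_pulse(_left_edge(dom), amplitude=0.0)
        hist = run(dom, f, proto, duration=100.0, dt=0.02)
        assert np.abs(hist.v).max() < 1e-12

    def test_bitwise_determinism(self, uniform_fields_60):
        dom = make_sheet_domain(21, 21, 1.0)
        f = uniform_fields_60(dom.n_nodes)
        proto = single_pulse(_left_edge(dom))
        h1 = run(dom, f, proto, duration=60.0, dt=0.02)
        h2 = run(dom, f, proto, duration=60.0, dt=0.02)
        assert np.array_equal(h1.v, h2.v) and np.array_equal(h1.h, h2.h)

    def test_unstable_dt_rejected_with_bound(self, uniform_fields_60):
        dom = make_sheet_domain(15, 15, 0.5)
        f = uniform_fields_60(dom.n_nodes)
        with pytest.raises(ValueError, match="stability bound"):
            run(dom, f, single_pulse(_left_edge(dom)), duration=10.0, dt=0.2)

    def test_duration_must_cover_protocol(self, uniform_fields_60):
        dom = make_sheet_domain(15, 15, 1.0)
        f = uniform_fields_60(dom.n_nodes)
        with pytest.raises(ValueError, match="protocol"):
            run(dom, f, single_pulse(_left_edge(dom), start=50.0),
                duration=20.0, dt=0.02)

    def test_circular_wavefront_from_central_stimulus(self, uniform_fields_60):
        dom = make_sheet_domain(41, 41, 1.0)
        f = uniform_fields_60(dom.n_nodes)
        center = np.flatnonzero(
            np.linalg.norm(dom.positions[:, :2] - [20, 20], axis=1) <= 1.5)
        hist = run(dom, f, single_pulse(center), duration=60.0, dt=0.02)
        lat = extract_lat(hist).lat.reshape(41, 41)
        # four-fold symmetry: equidistant nodes activate simultaneously
        probes = [lat[20, 30], lat[20, 10], lat[30, 20], lat[10, 20]]
        assert np.ptp(probes) < 1e-6

    def test_zero_flux_boundary_quiet_until_arrival(self, uniform_fields_60):
        dom = make_sheet_domain(41, 41, 1.0)
        f = uniform_fields_60(dom.n_nodes)
        center = np.flatnonzero(
            np.linalg.norm(dom.positions[:, :2] - [20, 20], axis=1) <= 1.5)
        hist = run(dom, f, single_pulse(center), duration=60.0, dt=0.02)
        # boundary ring is 20 mm from the source: at 10 ms the wave
        # (~0.6 mm/ms) is still far away; only a vanishing diffusive tail
        # may have reached the edge
        i10 = int(np.searchsorted(hist.time, 10.0))
        assert np.abs(hist.v[i10][dom.boundary]).max() < 1e-6

    def test_plane_wave_speed_matches_cable(self, default_params):
        from rotortether.mms_model import conductivity_from_cvmax
        D = conductivity_from_cvmax(60.0, default_params, dx=0.5)
        p = MMSParameters(diffusivity=D)
        dom = make_sheet_domain(81, 81, 0.5)
        f = ParameterFieldSet.uniform(dom.n_nodes, p)
        hist = run(dom, f, single_pulse(_left_edge(dom)), duration=90.0, dt=0.02)
        lat = extract_lat(hist).lat.reshape(81, 81)
        cv = 100.0 * (20 * 0.5) / (lat[40, 60] - lat[40, 40])
        assert cv == pytest.approx(60.0, rel=0.05)

    def test_refinement_convergence(self, default_params):
        """Halving dx and dt changes the plane-wave speed by < 3 %."""
        p = replace(default_params, diffusivity=0.6)
        cv_coarse = cable_cv(p, dx=0.5, dt=0.02)
        cv_fine = cable_cv(p, dx=0.25, dt=0.01)
        assert abs(cv_coarse - cv_fine) / cv_fine < 0.03


class TestExtractLat:
    def _history(self, v_rows):
        v = np.asarray(v_rows, dtype=np.float32)
        t = np.arange(v.shape[0], dtype=float) + 10.0
        return StateHistory(time=t, v=v, h=np.ones_like(v), dt=0.02,
                            sample_interval=1.0)

    def test_linear_interpolation_between_samples(self):
        hist = self._history([[0.05], [0.15]])
        amap = extract_lat(hist, v_thr=0.1, window=(10.0, 11.0), t_ref=0.0)
        assert amap.lat[0] == pytest.approx(10.5)

    def test_subthreshold_node_gets_marker(self):
        hist = self._history([[0.01], [0.05], [0.02]])
        amap = extract_lat(hist, window=(10.0, 12.0))
        assert np.isnan(amap.lat[0])
        assert not amap.activated[0]

    def test_two_beats_in_window_rejected(self):
        hist = self._history([[0.0], [0.5], [0.0], [0.5], [0.0]])
        with pytest.raises(ValueError, match="beat"):
            extract_lat(hist, window=(10.0, 14.0))

    def test_empty_window_rejected(self):
        hist = self._history([[0.0], [0.5]])
        with pytest.raises(ValueError, match="window"):
            extract_lat(hist, window=(50.0, 60.0))


class TestMeasureErp:
    @pytest.fixture(scope="class")
    def erp_setup(self, uniform_fields_60):
        dom = make_sheet_domain(31, 31, 1.0)
        f = uniform_fields_60(dom.n_nodes)
        site = np.flatnonzero(
            np.linalg.norm(dom.positions[:, :2] - [15, 15], axis=1) <= 3.0)
        return dom, f, site

    def test_erp_tracks_single_cell_threshold(self, erp_setup, default_params):
        from rotortether.mms_model import erp_single_cell
        dom, f, site = erp_setup
        grid = np.arange(100.0, 260.0, 5.0)
        erp = measure_erp(dom, f, site, s1_count=2, s1_cl=400.0, s2_grid=grid)
        cell = erp_single_cell(f.local_parameters(0))
        assert isinstance(erp, float)
        # the tissue threshold tracks the cell one but depends on stimulus
        # geometry (liminal-size/source-sink effects shift it by ~10-25 ms)
        assert abs(erp - cell) < 25.0

    def test_all_capture_returns_below_grid_marker(self, erp_setup):
        dom, f, site = erp_setup
        erp = measure_erp(dom, f, site, s1_count=2, s1_cl=400.0,
                          s2_grid=np.array([300.0, 350.0]))
        assert erp == ERP_BELOW_GRID

    def test_none_capture_returns_above_grid_marker(self, erp_setup):
        dom, f, site = erp_setup
        erp = measure_erp(dom, f, site, s1_count=2, s1_cl=400.0,
                          s2_grid=np.array([20.0, 40.0]))
        assert erp == ERP_ABOVE_GRID


class TestPacingSites:
    def test_twelve_sites_in_four_zones_of_three(self):
        dom = make_sheet_domain(101, 101, 0.5)
        sites = make_pacing_sites(dom)
        assert len(sites) == 12
        zones = {}
        for s in sites:
            zones.setdefault(s.zone, []).append(s)
        assert len(zones) == 4
        assert all(len(v) == 3 for v in zones.values())

    def test_sites_pairwise_disjoint(self):
        dom = make_sheet_domain(101, 101, 0.5)
        sites = make_pacing_sites(dom)
        seen = set()
        for s in sites:
            assert not (seen & set(s.nodes))
            seen |= set(s.nodes)

    def test_site_ids_stable_across_calls(self):
        dom = make_sheet_domain(75, 75, 0.75)
        a = make_pacing_sites(dom)
        b = make_pacing_sites(dom)
        assert [(s.site_id, s.zone, s.nodes) for s in a] == \
               [(s.site_id, s.zone, s.nodes) for s in b]

    def test_domain_too_small_rejected(self):
        dom = make_sheet_domain(5, 5, 1.0)
        with pytest.raises(ValueError, match="too small"):
            make_pacing_sites(dom)
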