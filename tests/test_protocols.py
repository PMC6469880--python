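"""Latency measurement, stimulation protocols, scans, reversion searches
and calibration."""

import numpy as np
import pytest

import gfsim
from gfsim.engine import SimConfig, Simulation, Trace
from gfsim.scans import calibrate, find_iso_latency, find_reversion_value, grid_scan

FAST = SimConfig(dt=0.005, t_stop=5.0)   # coarser but converged scan config


class TestMeasureLatency:
    def _trace(self, v):
        t = np.arange(len(v)) * 0.01
        return Trace(t, [("X", "axon", 1.0)], np.asarray(v)[:, None])

    def test_synthetic_peak_location(self):
        t = np.arange(0, 5, 0.01)
        v = -80 + 120 * np.exp(-((t - 2.0) / 0.3) ** 2)
        tr = Trace(t, [("X", "axon", 1.0)], v[:, None])
        res = gfsim.measure_latency(tr, "X", stimulus_onset=0.5)
        assert res.spike_found
        assert res.t_ap_peak == pytest.approx(1.5, abs=1e-3)
        assert res.latency_total == pytest.approx(1.85, abs=1e-3)

    def test_flat_trace_reports_no_spike(self):
        res = gfsim.measure_latency(self._trace(np.full(100, -80.0)), "X")
        assert not res.spike_found
        assert np.isnan(res.latency_total)

    def test_subzero_depolarization_is_not_a_spike(self):
        v = -80 + 60 * np.exp(-((np.arange(100) - 50) / 10.0) ** 2)   # peaks at -20
        res = gfsim.measure_latency(self._trace(v), "X")
        assert not res.spike_found

    def test_first_excursion_wins(self):
        t = np.arange(0, 8, 0.01)
        v = (-80 + 110 * np.exp(-((t - 2.0) / 0.2) ** 2)
             + 140 * np.exp(-((t - 5.0) / 0.2) ** 2))
        tr = Trace(t, [("X", "axon", 1.0)], v[:, None])
        res = gfsim.measure_latency(tr, "X")
        assert res.t_ap_peak == pytest.approx(2.0, abs=0.01)


def test_sim_config_yaml_round_trip(tmp_path):
    cfg = SimConfig(dt=0.005, t_stop=4.0,
                    record_sites=[("GF", "axon", 1.0)])
    import yaml
    path = tmp_path / "sim.yaml"
    path.write_text(yaml.safe_dump(cfg.to_dict()))
    back = SimConfig.from_file(path)
    assert back == cfg


class TestHeadStimulation:
    def test_each_cell_fires_exactly_one_ap(self, young_result):
        trace = young_result["trace"]
        for cell in ("TTMn", "PSI", "DLMn"):
            v = trace[cell]
            crossings = np.sum(np.diff((v > 0).astype(int)) == 1)
            assert crossings == 1, cell

    def test_gf_spike_precedes_ttmn_spike(self, young_result):
        trace = young_result["trace"]
        gf = gfsim.measure_latency(trace, "GF")
        ttmn = gfsim.measure_latency(trace, "TTMn")
        assert gf.spike_found and gf.t_ap_peak < ttmn.t_ap_peak

    def test_dlm_lags_ttm(self, young_result, old_result):
        for res in (young_result, old_result):
            assert res["DLM"].latency_total > res["TTM"].latency_total

    def test_no_stimulus_keeps_circuit_at_rest(self, young_circuit):
        sim = Simulation(young_circuit, SimConfig(t_stop=15.0))
        trace = sim.run([])
        tail = trace.values[trace.times >= 5.0]
        assert np.ptp(tail, axis=0).max() < 0.1
        assert trace.values.max() < 0.0

    def test_uncoupled_circuit_does_not_propagate(self, young_circuit):
        res = gfsim.run_head_stimulation(
            gfsim.apply_overrides(young_circuit, {"g_gap": 0.0}))
        assert not res["TTM"].spike_found
        assert not res["DLM"].spike_found

    def test_deterministic_rerun_bitwise(self, young_circuit, young_result):
        res = gfsim.run_head_stimulation(young_circuit)
        assert np.array_equal(res["trace"].values,
                              young_result["trace"].values)
        assert res["TTM"].latency_total == young_result["TTM"].latency_total


class TestThoracicStimulation:
    def test_auto_escalation_finds_suprathreshold_pulse(self, young_circuit):
        res = gfsim.run_thoracic_stimulation(young_circuit)
        assert res.spike_found
        assert res.nmj_delay == 0.0
        assert res.amplitude_nA >= 10.0

    def test_zero_amplitude_no_spike(self, young_circuit):
        res = gfsim.run_thoracic_stimulation(young_circuit, amplitude=0.001)
        assert not res.spike_found


class TestGridScan:
    def test_degenerate_grid_equals_single_run(self, young_circuit):
        scan = grid_scan(young_circuit, ("g_gap", [135.0]), sim_config=FAST)
        single = gfsim.run_head_stimulation(young_circuit, FAST)
        assert scan.latency["TTM"][0] == pytest.approx(
            single["TTM"].latency_total, abs=1e-12)
        assert scan.latency["DLM"][0] == pytest.approx(
            single["DLM"].latency_total, abs=1e-12)

    def test_latency_monotone_in_g_gap(self, young_circuit):
        g = np.linspace(20, 200, 7)
        scan = grid_scan(young_circuit, ("g_gap", g), sim_config=FAST)
        assert np.all(np.diff(scan.latency["TTM"]) <= 0)
        # DLM: monotone over the coupling range where the branch propagates;
        # both experimental operating points (34.5, 135) must propagate
        dlm = scan.latency["DLM"]
        ok = np.isfinite(dlm)
        assert ok[g >= 34.5].all()
        assert np.all(np.diff(dlm[ok]) <= 0)
        assert np.all(dlm[ok] > scan.latency["TTM"][ok])

    def test_2d_scan_shape_and_nat_direction(self, young_circuit):
        scan = grid_scan(young_circuit,
                         ("g_gap", [34.5, 135.0]),
                         ("membrane.gbar_nat", [200.0, 300.0, 450.0]),
                         sim_config=FAST)
        assert scan.latency["TTM"].shape == (2, 3)
        # latency decreases along the Na-conductance axis at fixed g_gap
        assert np.all(np.diff(scan.latency["TTM"], axis=1) < 0)

    def test_failed_points_recorded_not_raised(self, young_circuit):
        scan = grid_scan(young_circuit, ("g_gap", [0.0, 135.0]),
                         sim_config=FAST)
        assert scan.failed["TTM"][0] and not scan.failed["TTM"][1]
        assert np.isnan(scan.latency["TTM"][0])

    def test_dataframe_round_trip(self, young_circuit):
        scan = grid_scan(young_circuit, ("g_gap", [34.5, 135.0]),
                         sim_config=FAST)
        df = scan.to_dataframe()
        assert list(df["g_gap"]) == [34.5, 135.0]
        assert np.allclose(df["latency_TTM_ms"], scan.latency["TTM"])


class TestIsoLatency:
    def _scan(self, young_circuit):
        return grid_scan(young_circuit,
                         ("g_gap", np.linspace(30, 200, 8)),
                         sim_config=FAST)

    def test_unreachable_target_empty(self, young_circuit):
        scan = self._scan(young_circuit)
        assert find_iso_latency(scan, 50.0) == []

    def test_band_contains_point_nearest_young_value(self, young_circuit):
        scan = self._scan(young_circuit)
        target = gfsim.run_head_stimulation(young_circuit,
                                            FAST)["TTM"].latency_total
        pts = find_iso_latency(scan, target, readout="TTM", tol_fraction=0.02)
        nearest = int(np.argmin(np.abs(scan.axis_values[0] - 135.0)))
        assert (nearest,) in pts

    def test_exact_hit_with_zero_tolerance(self, young_circuit):
        scan = self._scan(young_circuit)
        lat = scan.latency["TTM"][3]
        assert find_iso_latency(scan, lat, tol_fraction=0.0) == [(3,)]


def test_iso_latency_contours_2d(young_circuit):
    """Marching-squares polylines follow the latency level set of a 2D
    scan in axis units."""
    from gfsim.scans import iso_latency_contours
    scan = grid_scan(young_circuit,
                     ("g_gap", np.linspace(34.5, 135.0, 4)),
                     ("membrane.gbar_nat", np.linspace(200.0, 450.0, 4)),
                     sim_config=FAST)
    lat = scan.latency["TTM"]
    level = float(np.nanmean(lat))
    polys = iso_latency_contours(scan, level, readout="TTM")
    assert polys, "level inside the grid range must produce a contour"
    for poly in polys:
        assert poly.ndim == 2 and poly.shape[1] == 2
        assert poly[:, 0].min() >= 34.5 and poly[:, 0].max() <= 135.0
        assert poly[:, 1].min() >= 200.0 and poly[:, 1].max() <= 450.0


class TestDirectionOfEffect:
    """Latency sensitivity directions for conductances and reversals."""

    @pytest.mark.parametrize("path,value,direction", [
        ("membrane.gbar_nat", 450.0, -1),   # more Na -> faster
        ("membrane.g_leak", 0.035, +1),     # more leak shunt -> slower
        ("membrane.gbar_k", 30.0, +1),      # more K -> slower
        ("membrane.e_na", 80.0, -1),        # depolarized E_Na -> faster
        ("membrane.e_k", -64.0, -1),        # depolarized E_K -> faster
    ])
    def test_conductance_and_reversal_directions(self, young_circuit,
                                                 young_result, path, value,
                                                 direction):
        res = gfsim.run_head_stimulation(
            gfsim.apply_overrides(young_circuit, {path: value}))
        delta = res["TTM"].latency_total - young_result["TTM"].latency_total
        assert delta * direction > 0, (path, delta)

    def test_extreme_low_k_prolongs_latency(self, young_circuit, young_result):
        """The K/latency relation is non-monotone: strong K-density
        reduction depolarizes rest, inactivates Na and prolongs the latency
        somewhere on the low flank before propagation breaks down."""
        base = young_result["TTM"].latency_total
        low_flank = []
        for gk in (0.7, 1.0, 1.5, 2.0):
            res = gfsim.run_head_stimulation(
                gfsim.apply_overrides(young_circuit, {"membrane.gbar_k": gk}))
            if res["trace"]["GF"][0] > -45.0:
                continue   # depolarization block: past the breakdown point
            ttm = res["TTM"]
            low_flank.append(ttm.latency_total if ttm.spike_found else np.inf)
        assert low_flank and max(low_flank) > base

    def test_axon_length_latency_is_u_shaped(self, young_circuit):
        lengths = np.array([5.0, 15.0, 30.0, 50.0, 80.0, 120.0])
        scan = grid_scan(young_circuit, ("cells.TTMn.axon.length", lengths),
                         sim_config=FAST)
        lat = scan.latency["TTM"]
        k = int(np.nanargmin(lat))
        assert 0 < k < len(lengths) - 1   # interior minimum

    def test_medial_dendrite_more_influential_than_lateral(self, young_circuit,
                                                           young_result):
        base = young_result["TTM"].latency_total
        med = gfsim.run_head_stimulation(gfsim.apply_overrides(
            young_circuit, {"cells.TTMn.medial_dendrite.length": 120.0}))
        lat = gfsim.run_head_stimulation(gfsim.apply_overrides(
            young_circuit, {"cells.TTMn.lateral_dendrite.length": 90.0}))
        d_med = abs(med["TTM"].latency_total - base)
        d_lat = abs(lat["TTM"].latency_total - base)
        assert d_med > d_lat

    def test_synapse_location_less_influential_than_weight(self, young_circuit):
        """Moving the PSI->DLMn synapse along the DLMn dendrite barely moves
        the DLM latency compared with a 50% change of the synapse weight."""
        lats = []
        for pos in (0.1, 0.9):
            circ = gfsim.apply_overrides(young_circuit, {
                "synapses.chemical.post_section": "dendrite",
                "synapses.chemical.post_pos": pos})
            lats.append(gfsim.run_head_stimulation(circ)["DLM"].latency_total)
        loc_effect = abs(lats[1] - lats[0])
        ref = gfsim.run_head_stimulation(gfsim.apply_overrides(
            young_circuit, {"synapses.chemical.post_section": "dendrite",
                            "synapses.chemical.post_pos": 0.1}))
        half = gfsim.run_head_stimulation(gfsim.apply_overrides(
            young_circuit, {"synapses.chemical.post_section": "dendrite",
                            "synapses.chemical.post_pos": 0.1,
                            "synapses.chemical.g_peak": 40.0}))
        weight_effect = abs(half["DLM"].latency_total
                            - ref["DLM"].latency_total)
        assert loc_effect < weight_effect


class TestReversionSearch:
    def test_g_gap_reversion_recovers_young_value(self, young_circuit,
                                                  old_circuit, young_result):
        target = young_result["TTM"].latency_total
        res = find_reversion_value(old_circuit, "g_gap", default_value=34.5,
                                   target_latency=target, readout="TTM",
                                   bracket=(20.0, 220.0))
        assert res.reachable
        assert res.value == pytest.approx(135.0, rel=0.05)

    def test_unreachable_target_reported(self, old_circuit):
        res = find_reversion_value(old_circuit, "membrane.gbar_nat",
                                   default_value=300.0, target_latency=0.5,
                                   readout="TTM", bracket=(150.0, 450.0))
        assert not res.reachable
        assert "outside" in res.message or "monotone" in res.message


class TestCalibrate:
    def test_already_met_targets_near_identity(self, young_circuit,
                                               young_result):
        targets = {"TTM": young_result["TTM"].latency_total,
                   "DLM": young_result["DLM"].latency_total}
        res = calibrate(young_circuit, {"g_gap": (100.0, 170.0)}, targets,
                        sweeps=2, grid=5)
        assert res.converged
        assert max(abs(r) for r in res.residuals.values()) < 0.02 * 0.93

    def test_perturbed_kinetics_restored_within_tolerance(self, young_circuit,
                                                          young_result):
        """Scaling the Na activation time constant by 1.2 detunes the
        latencies; recalibrating the free conductance parameters restores
        the young targets within 2%."""
        kin = young_circuit.kinetics
        slow = gfsim.apply_overrides(young_circuit, {
            "kinetics.nat_m.tau_min": kin.nat_m.tau_min * 1.2,
            "kinetics.nat_m.tau_amp": kin.nat_m.tau_amp * 1.2})
        targets = {"TTM": young_result["TTM"].latency_total,
                   "DLM": young_result["DLM"].latency_total}
        res = calibrate(slow, {"g_gap": (80.0, 400.0),
                               "synapses.chemical.g_peak": (40.0, 400.0)},
                        targets, sweeps=3, grid=7)
        assert res.converged, res
        recal = calibrate(
            gfsim.apply_overrides(slow, res.overrides),
            {"g_gap": (80.0, 400.0)}, targets, sweeps=2, grid=5)
        # idempotence: recalibrating cannot worsen the residuals
        assert max(abs(r) for r in recal.residuals.values()) <= \
            max(abs(r) for r in res.residuals.values()) + 1e-9
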