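"""ISC life-cycle experiments: typical protocol, phase detection, scans,
the Mg-depletion hypothesis test and the ATP-turnover estimator."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from iscsim import (NoCollapseError, apply_pump_inhibition,
                    atp_turnover_ratio, detect_phases, lifecycle,
                    mg_depletion_test, parse_protocol, scan_ca_ratio,
                    scan_pa, typical_isc_protocol, write_protocol)
from iscsim.dynamics import TimeSeries


def test_typical_protocol_shape():
    p = typical_isc_protocol()
    assert p.duration_h == 120.0                       # 5 days
    assert len([s for s in p.stages if s.kind == "lingering"]) == 3
    inh = p.inhibition_stage()
    assert inh.time == 96.0
    assert 0.0 < inh.params["factor"] < 1.0
    assert parse_protocol(write_protocol(p)) == p      # round trip


def test_typical_protocol_overrides():
    p = typical_isc_protocol(duration_h=48.0, reference={"PzA": 100.0})
    assert p.reference.PzA == 100.0
    assert all(s.time <= 48.0 for s in p.stages)
    with pytest.raises(TypeError):
        typical_isc_protocol(bogus=1)


def test_apply_pump_inhibition_rules():
    p = typical_isc_protocol()
    p2 = apply_pump_inhibition(p, 100.0, 0.5)
    times = [s.time for s in p2.stages if s.kind == "pump-inhibition"]
    assert 100.0 in times
    # factor 1 removes the step at that time (no change event)
    p3 = apply_pump_inhibition(p2, 100.0, 1.0)
    assert 100.0 not in [s.time for s in p3.stages
                         if s.kind == "pump-inhibition"]
    with pytest.raises(ValueError):
        apply_pump_inhibition(p, 100.0, 0.0)
    with pytest.warns(UserWarning, match="phase 2"):
        apply_pump_inhibition(p, 2.0, 0.5)


def test_detect_phases_synthetic_trough():
    """A clean volume trace with one minimum puts t_trough at the minimum."""
    n = 200
    t = np.linspace(0.0, 100.0, n)
    v = 0.6 + 0.4 * np.abs(t - 30.0) / 100.0
    tr = pd.DataFrame({
        "t_start": t, "t_end": t + 0.5, "kind": [1, 0] * (n // 2),
        "amplitude": 1.0, "Vw_mean": v, "pHi_mean": 7.0, "Em_mean": -20.0,
        "relative_volume_mean": v, "JNa_pump_min": -40.0,
        "JNa_pump_max": -30.0, "JNa_pump_mean": -35.0, "JCa_pump_mean": -1.0,
        "MgF_min": 0.4, "MgT_mean": 2.7, "pHi_min": 6.9, "CaF_mean": 1e-4})
    ps = detect_phases(TimeSeries(data=pd.DataFrame(), transits=tr))
    assert ps.t_trough == pytest.approx(30.0, abs=1.5)


def test_no_collapse_raises():
    tr = pd.DataFrame({
        "t_start": [0.0, 1.0], "t_end": [1.0, 2.0], "kind": [0, 1],
        "amplitude": [0.0, 1.0], "Vw_mean": [0.75, 0.74],
        "pHi_mean": [7.2, 7.2], "Em_mean": [-12.0, -12.0],
        "relative_volume_mean": [1.0, 0.99], "JNa_pump_min": [-26.0] * 2,
        "JNa_pump_max": [-26.0] * 2, "JNa_pump_mean": [-26.0] * 2,
        "JCa_pump_mean": [-0.1] * 2, "MgF_min": [0.4] * 2,
        "MgT_mean": [2.7] * 2, "pHi_min": [7.2] * 2, "CaF_mean": [1e-4] * 2})
    with pytest.raises(NoCollapseError):
        detect_phases(TimeSeries(data=pd.DataFrame(), transits=tr))


def test_without_inhibition_no_phase3(typical_run):
    """Removing the inhibition event keeps the cell in the phase-2 band to
    day 5: sodium-pump decline is the only rehydration trigger."""
    p = typical_isc_protocol()
    p.stages = [s for s in p.stages if s.kind != "pump-inhibition"]
    ts, ref = lifecycle.run_protocol(p, seed=1)
    ps = detect_phases(ts, ref, t_inhibition=None)
    sm = lifecycle._smooth_transits(ts.transits)
    tail = sm[sm["t_start"] >= 108.0]["relative_volume_mean_cycle"]
    assert abs(tail.mean() - ps.V_trough) < 0.05
    # whereas the run with the step rehydrates clearly
    ts_i, ref_i, ps_i = typical_run
    end = ts_i.data["relative_volume"].iloc[-1]
    assert end > ps_i.V_trough + 0.2


def test_rehydration_direction_strong_inhibition():
    """A strong inhibitory step starts net NaCl and water gain within
    hours (positive rehydration slope)."""
    p = typical_isc_protocol(duration_h=108.0)
    p = apply_pump_inhibition(
        replace(p, stages=[s for s in p.stages
                           if s.kind != "pump-inhibition"]), 96.0, 0.1)
    ts, ref = lifecycle.run_protocol(p, seed=1)
    sm = lifecycle._smooth_transits(ts.transits)
    before = sm[(sm["t_end"] > 90.0) & (sm["t_end"] <= 96.0)]
    after = sm[sm["t_start"] >= 102.0]
    assert after["relative_volume_mean_cycle"].mean() > \
        before["relative_volume_mean_cycle"].mean() + 0.02


def test_scan_pa_controlled_comparison():
    """Shared seed: differences across PA are attributable to PA alone, and
    the phase-3 rehydration half-time is ordered (PA = 1.3 slowest)."""
    tab = scan_pa((1.3, 50.0, 100.0), seed=1)
    assert list(tab["PA"]) == [1.3, 50.0, 100.0]
    r = tab.set_index("PA")["rehydration_half_time"]
    assert r[1.3] > r[50.0] >= r[100.0] - 1e-9
    # same seed, same PA -> identical result
    tab2 = scan_pa((50.0,), seed=1)
    assert tab2["t_trough"][0] == tab.set_index("PA")["t_trough"][50.0]


def test_scan_ca_ratio_threshold_and_monotonicity():
    """No collapse as the ratio -> 0; collapse time strictly decreasing in
    the ratio; the smallest collapsing ratio is about 10-fold."""
    tab = scan_ca_ratio((0.1, 4.0, 8.0, 10.0, 15.0), seed=1,
                        collapse_horizon=48.0)
    t = tab.set_index("ca_ratio")["t_trough"]
    assert np.isnan(t[0.1])
    assert np.isnan(t[4.0])
    collapsing = t.dropna()
    assert list(collapsing.index) == [8.0, 10.0, 15.0]
    assert collapsing.is_monotonic_decreasing
    smallest = min(i for i in collapsing.index if collapsing[i] <= 36.0)
    assert 5.0 <= smallest <= 15.0


def test_mg_depletion_hypothesis(typical_run):
    """Free Mg never approaches the 50 uM pump half-activation and total Mg
    rises during phase 2 (inward-reversed gradient under
    hyperpolarization)."""
    rep = mg_depletion_test(seed=1, duration_h=96.0)
    assert not rep["crosses_half_activation"]
    assert rep["min_MgF"] > 0.050
    assert rep["phase2_MgT_increasing"]


def test_mg_conserved_without_piezo_mg_path():
    p = typical_isc_protocol(duration_h=12.0, reference={"PzMg": 0.0})
    ts, ref = lifecycle.run_protocol(p, seed=1)
    q = ts.data["QMgT"]
    assert q.max() - q.min() < 1e-12


def test_atp_turnover_ratio_estimator(typical_run):
    ts, ref, ps = typical_run
    # a baseline equal to the phase-2 fluxes themselves gives exactly 1
    tr = ts.transits
    seg = tr[(tr["t_start"] >= ps.t_trough) & (tr["t_end"] <= 96.0)]
    w = (seg["t_end"] - seg["t_start"]).to_numpy()
    jna = np.average(np.abs(seg["JNa_pump_mean"]), weights=w)
    jca = np.average(np.abs(seg["JCa_pump_mean"]), weights=w)
    unit = atp_turnover_ratio(ts, (ps.t_trough, 96.0), (jna, jca))
    assert unit == pytest.approx(1.0, rel=1e-9)
    with pytest.raises(ValueError, match="empty"):
        atp_turnover_ratio(ts, (200.0, 201.0), (2.6, 0.01))


def test_atp_ratio_independent_of_output_cadence():
    p = typical_isc_protocol(duration_h=24.0)
    p.stages = [s for s in p.stages if s.kind != "pump-inhibition"]
    ts1, ref = lifecycle.run_protocol(p, seed=1, record_every=60.0)
    ts2, _ = lifecycle.run_protocol(p, seed=1, record_every=600.0)
    base = (ref.ref_na_pump_flux / 10.0, ref.ref_ca_pump_flux / 40.0)
    r1 = atp_turnover_ratio(ts1, (10.0, 24.0), base)
    r2 = atp_turnover_ratio(ts2, (10.0, 24.0), base)
    assert r1 == pytest.approx(r2, rel=1e-9)
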