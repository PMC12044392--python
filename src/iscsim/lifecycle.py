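"""The ISC circulatory-life-cycle experiments.

The "typical" 5-day ISC protocol: a stress-reticulocyte reference state with
Ca- and Na-pump turnovers of 36 and 26 mmol/Loch, deoxy-PIEZO1 anion
permeability 50/h, a deoxy Ca influx ten-fold the resting PMCA flux, three
40-min lingering episodes, and a sudden Na-pump inhibitory step late in
phase 2. Phase detection and per-phase summary statistics work on
transit-averaged traces (window of one oxy+deoxy cycle) to suppress the
oscillation aliasing produced by the stochastic schedule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd

from . import _kernel as K
from .circulation import sample_schedule
from .dynamics import ParameterChange, TimeSeries, run
from .model import Reference, ReferenceConfig, build_reference_state
from .protocol import Protocol, Stage

#: Na-pump scale factor applied at the phase-3 trigger; calibrated so the
#: settled phase-3 pump flux lands near -10 mmol/Loch.
DEFAULT_INHIBITION_FACTOR = 0.22
DEFAULT_INHIBITION_TIME = 96.0     # hours (day 4, "arbitrary" along phase 2)
LINGERING_TIMES = (12.0, 26.4, 84.0)   # 0.5, 1.1 and 3.5 days


class NoCollapseError(RuntimeError):
    """The run never produced a hyperdense collapse (volume never fell
    below the configured fraction of the initial volume)."""


@dataclass
class PhaseSummary:
    """Detected phase boundaries and per-phase summary statistics."""

    t_trough: float            #: hours; phase 1 -> 2 boundary
    V_trough: float            #: relative volume at the trough
    t_inhibition: float | None  #: hours; phase 2 -> 3 boundary (None: no ev.)
    pH_dip: float              #: min transit-averaged pHi, first 1.5 days
    pH_phase2_mean: float
    pH_phase2_range: tuple[float, float]
    pump_envelope_min: float   #: 5th pct of per-transit JNa_pump minima
    pump_envelope_max: float   #: 95th pct of per-transit JNa_pump maxima
    pump_phase3_settled: float | None   #: mean JNa_pump, final 12 h
    hb_osm_reference: float    #: fHb*CHb, mOsmol/Lcw
    hb_osm_trough: float
    atp_turnover_ratio: float | None

    def to_dict(self) -> dict:
        return asdict(self)


def typical_isc_protocol(**overrides) -> Protocol:
    """The full 5-day typical-ISC protocol.

    Keyword overrides are applied to the protocol (``duration_h``, ``seed``,
    ...) or, via a ``reference`` mapping, to the reference configuration.
    """
    ref_over = overrides.pop("reference", {})
    p = Protocol(
        name="typical_5day_isc",
        duration_h=120.0,
        seed=1234,
        reference=ReferenceConfig(**ref_over) if isinstance(ref_over, dict)
        else ref_over,
        stages=[Stage(t, "lingering") for t in LINGERING_TIMES]
        + [Stage(DEFAULT_INHIBITION_TIME, "pump-inhibition",
                 {"factor": DEFAULT_INHIBITION_FACTOR})],
    )
    for k, v in overrides.items():
        if not hasattr(p, k):
            raise TypeError(f"unknown protocol override {k!r}")
        setattr(p, k, v)
    p.stages = [s for s in p.stages if s.time <= p.duration_h]
    return p


def apply_pump_inhibition(protocol: Protocol, t_event: float,
                          factor: float) -> Protocol:
    """Replace (or add) the sudden Na-pump inhibitory step.

    ``factor`` multiplies the pump scale at ``t_event``; 1 means no change.
    A multi-step ramp can be built by calling this repeatedly with
    increasing times (stages accumulate if their times differ). Warns when
    the event lies before the typical trough (the step belongs in phase 2).
    """
    if not (0.0 < factor <= 1.0):
        raise ValueError("factor must be in (0, 1]")
    if t_event < 24.0:
        warnings.warn("pump inhibition scheduled before the typical "
                      "collapse trough (~1 day); the step belongs in "
                      "phase 2", stacklevel=2)
    stages = [s for s in protocol.stages
              if not (s.kind == "pump-inhibition" and s.time == t_event)]
    if factor < 1.0:
        stages.append(Stage(t_event, "pump-inhibition", {"factor": factor}))
    stages.sort(key=lambda s: s.time)
    return replace(protocol, stages=stages)


def run_protocol(protocol: Protocol, seed: int | None = None,
                 dt: float = 1.0, record_every: float = 60.0,
                 ) -> tuple[TimeSeries, Reference]:
    """Build the reference state, sample the schedule and run the protocol."""
    ref = build_reference_state(protocol.reference)
    schedule = sample_schedule(protocol.circulation_config(seed))
    events = []
    for s in protocol.stages:
        if s.kind == "pump-inhibition":
            factor = float(s.params.get("factor", DEFAULT_INHIBITION_FACTOR))
            events.append(ParameterChange(
                s.time, "pump_inhibition_factor",
                factor * ref.transport.pump_inhibition_factor))
        elif s.kind == "parameter-change":
            events.append(ParameterChange(
                s.time, str(s.params["name"]), float(s.params["value"])))
    ts = run(ref, schedule, events=events, dt=dt, record_every=record_every)
    return ts, ref


def _smooth_transits(tr: pd.DataFrame) -> pd.DataFrame:
    """Duration-weighted rolling mean over one full oxy+deoxy cycle."""
    d = tr["t_end"] - tr["t_start"]
    out = tr.copy()
    for col in ("relative_volume_mean", "pHi_mean", "Em_mean", "Vw_mean"):
        w = (tr[col] * d).rolling(2, min_periods=1).sum() \
            / d.rolling(2, min_periods=1).sum()
        out[col + "_cycle"] = w
    out["duration"] = d
    return out


def detect_phases(ts: TimeSeries, ref: Reference | None = None,
                  t_inhibition: float | None = None,
                  collapse_fraction: float = 0.7,
                  baseline: tuple[float, float] | None = None,
                  ) -> PhaseSummary:
    """Locate the three phases and compute their summary statistics.

    The trough (phase 1 -> 2 boundary) is the minimum of the cycle-averaged
    relative volume before the inhibition event; phase 2 runs from the
    trough to the inhibition event; phase 3 to the end of the run. Raises
    :class:`NoCollapseError` when the volume never falls below
    ``collapse_fraction`` of the initial volume.
    """
    tr = _smooth_transits(ts.transits)
    pre = tr if t_inhibition is None else tr[tr["t_end"] <= t_inhibition]
    if len(pre) == 0:
        raise ValueError("no transits before the inhibition event")
    v = pre["relative_volume_mean_cycle"]
    v_min = float(v.min())
    # earliest entry into the trough band: the argmin of a noisy plateau
    # would place the boundary anywhere within phase 2
    in_band = pre[v <= v_min + 0.005]
    i_min = int(in_band.index[0])
    v_trough = float(pre.loc[i_min, "relative_volume_mean_cycle"])
    t_trough = float(0.5 * (pre.loc[i_min, "t_start"]
                            + pre.loc[i_min, "t_end"]))
    if v_trough >= collapse_fraction:
        raise NoCollapseError(
            f"relative volume never fell below {collapse_fraction} "
            f"(min {v_trough:.3f}): the protocol did not produce an ISC")

    first = tr[tr["t_end"] <= 36.0]
    ph_dip = float(first["pHi_mean"].min()) if len(first) else float("nan")

    t_end_run = float(tr["t_end"].iloc[-1])
    t2_hi = t_inhibition if t_inhibition is not None else t_end_run
    ph2 = tr[(tr["t_start"] >= t_trough) & (tr["t_end"] <= t2_hi)]
    w = ph2["duration"].to_numpy()
    ph2_mean = float(np.average(ph2["pHi_mean"], weights=w))
    ph2_rng = (float(ph2["pHi_mean"].min()), float(ph2["pHi_mean"].max()))
    env_min = float(np.percentile(ph2["JNa_pump_min"], 5.0))
    env_max = float(np.percentile(ph2["JNa_pump_max"], 95.0))

    settled = None
    if t_inhibition is not None:
        tail = tr[tr["t_start"] >= t_end_run - 12.0]
        settled = float(np.average(tail["JNa_pump_mean"],
                                   weights=tail["duration"]))

    if ref is not None:
        chb0 = ref.cell.QHb / ref.cell.Vw
        hb0 = K.hb_osmotic_coeff(chb0, ref.hb.b1, ref.hb.b2) * chb0
        chb_t = ref.cell.QHb / float(pre.loc[i_min, "Vw_mean_cycle"])
        hb_t = K.hb_osmotic_coeff(chb_t, ref.hb.b1, ref.hb.b2) * chb_t
    else:
        hb0 = hb_t = float("nan")

    ratio = None
    if baseline is not None:
        ratio = atp_turnover_ratio(ts, (t_trough, t2_hi), baseline)
    elif ref is not None:
        ratio = atp_turnover_ratio(
            ts, (t_trough, t2_hi),
            (ref.ref_na_pump_flux / 10.0, ref.ref_ca_pump_flux / 40.0))

    return PhaseSummary(
        t_trough=t_trough, V_trough=v_trough, t_inhibition=t_inhibition,
        pH_dip=ph_dip, pH_phase2_mean=ph2_mean, pH_phase2_range=ph2_rng,
        pump_envelope_min=env_min, pump_envelope_max=env_max,
        pump_phase3_settled=settled, hb_osm_reference=hb0,
        hb_osm_trough=hb_t, atp_turnover_ratio=ratio)


def atp_turnover_ratio(ts: TimeSeries, interval: tuple[float, float],
                       baseline: tuple[float, float]) -> float:
    """Pump ATP turnover in ``interval`` relative to a mature-RBC baseline.

    ATP consumption is |JNa_pump|/3 + |JCa_pump| (one ATP per pump cycle);
    the baseline is the same quantity for the mature-cell pump rates,
    conventionally the reference rates divided by (10, 40). Computed from
    per-transit means so the estimate is independent of the output cadence.
    """
    t0, t1 = interval
    tr = ts.transits
    seg = tr[(tr["t_start"] >= t0) & (tr["t_end"] <= t1)]
    if len(seg) == 0:
        raise ValueError("empty phase-2 segment")
    w = (seg["t_end"] - seg["t_start"]).to_numpy()
    atp = np.average(np.abs(seg["JNa_pump_mean"]) / 3.0
                     + np.abs(seg["JCa_pump_mean"]), weights=w)
    base_na, base_ca = baseline
    return float(atp / (abs(base_na) / 3.0 + abs(base_ca)))


def scan_pa(values=(1.3, 50.0, 100.0), seed: int = 1234,
            protocol: Protocol | None = None, dt: float = 1.0,
            ) -> pd.DataFrame:
    """One typical run per deoxy-PIEZO1 anion permeability, shared seed.

    Reports time-to-trough and the phase-3 rehydration half-time per PA
    value; with a shared seed the differences are attributable to PA alone.
    """
    base = protocol if protocol is not None else typical_isc_protocol()
    rows = []
    for pa in values:
        p = replace(base, reference=base.reference.overridden(PzA=float(pa)))
        ts, ref = run_protocol(p, seed=seed, dt=dt)
        stage = p.inhibition_stage()
        t_inh = stage.time if stage else None
        try:
            ps = detect_phases(ts, ref, t_inhibition=t_inh)
            t_trough, v_trough = ps.t_trough, ps.V_trough
        except NoCollapseError:
            t_trough = v_trough = float("nan")
        rows.append({"PA": pa, "t_trough": t_trough, "V_trough": v_trough,
                     "rehydration_half_time":
                     _rehydration_half_time(ts, t_inh)})
    return pd.DataFrame(rows)


def _rehydration_half_time(ts: TimeSeries,
                           t_inhibition: float | None) -> float:
    """Hours from the inhibition step until the cycle-averaged relative
    volume recovers halfway from its value at the step to its final value."""
    if t_inhibition is None:
        return float("nan")
    tr = _smooth_transits(ts.transits)
    post = tr[tr["t_start"] >= t_inhibition]
    if len(post) < 3:
        return float("nan")
    v = post["relative_volume_mean_cycle"].to_numpy()
    t = 0.5 * (post["t_start"] + post["t_end"]).to_numpy()
    v0, v1 = v[0], v[-1]
    if v1 <= v0:
        return float("nan")
    half = 0.5 * (v0 + v1)
    idx = np.argmax(v >= half)
    return float(t[idx] - t_inhibition)


def scan_ca_ratio(ratios, seed: int = 1234,
                  protocol: Protocol | None = None, dt: float = 1.0,
                  collapse_horizon: float | None = None) -> pd.DataFrame:
    """Time-to-trough as a function of the deoxy-Ca-influx / PMCA ratio.

    Each entry re-derives the PIEZO1 Ca permeability from the requested
    ratio (mean deoxy Ca influx scale over the resting PMCA flux); a run
    whose volume never collapses within the horizon reports NaN.
    """
    base = protocol if protocol is not None else typical_isc_protocol()
    rows = []
    for r in ratios:
        if r < 0:
            raise ValueError("ratios must be positive")
        p = replace(base,
                    reference=base.reference.overridden(ca_ratio=float(r)))
        if collapse_horizon is not None:
            p = replace(p, duration_h=collapse_horizon,
                        stages=[s for s in p.stages
                                if s.time <= collapse_horizon])
        ts, ref = run_protocol(p, seed=seed, dt=dt)
        stage = p.inhibition_stage()
        try:
            ps = detect_phases(ts, ref,
                               t_inhibition=stage.time if stage else None)
            rows.append({"ca_ratio": r, "t_trough": ps.t_trough})
        except NoCollapseError:
            rows.append({"ca_ratio": r, "t_trough": float("nan")})
    return pd.DataFrame(rows)


def mg_depletion_test(protocol: Protocol | None = None, seed: int = 1234,
                      duration_h: float = 168.0, dt: float = 1.0) -> dict:
    """Can deoxy-induced Mg depletion inhibit the Na pump in circulation?

    Runs phase 2 out to a week with no pump-inhibition event and reports the
    minimum free [Mg2+]i against the 0.050 mmol/Lcw half-activation level,
    plus the direction of the total-Mg trend during phase 2 (the
    hyperpolarized phase-2 potential reverses the Mg gradient inward, so
    total Mg *rises* and free Mg never reaches inhibitory levels).
    """
    base = protocol if protocol is not None else typical_isc_protocol()
    p = replace(base, duration_h=duration_h,
                stages=[s for s in base.stages
                        if s.kind != "pump-inhibition"
                        and s.time <= duration_h])
    ts, ref = run_protocol(p, seed=seed, dt=dt)
    ps = detect_phases(ts, ref, t_inhibition=None)
    tr = ts.transits
    ph2 = tr[tr["t_start"] >= ps.t_trough]
    mgf_min = float(tr["MgF_min"].min())
    t_mid = 0.5 * (ph2["t_start"] + ph2["t_end"]).to_numpy()
    slope = float(np.polyfit(t_mid, ph2["MgT_mean"].to_numpy(), 1)[0])
    return {
        "min_MgF": mgf_min,
        "crosses_half_activation": bool(mgf_min < ref.transport.KMg),
        "KMg": ref.transport.KMg,
        "phase2_MgT_slope_per_h": slope,
        "phase2_MgT_increasing": bool(slope > 0.0),
        "t_trough": ps.t_trough,
    }
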