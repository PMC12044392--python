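"""Stochastic circulation scheduler (the synthetic-input generator).

Generates the alternating oxy/deoxy inter-capillary transit sequence a cell
experiences in the systemic circulation: per-transit durations drawn
uniformly within configured bounds, a random PIEZO1 amplitude factor for each
deoxy transit (the fraction of channels opening varies stochastically between
deoxy episodes), and optional 40-min "lingering" episodes representing cells
trapped in venules. A single global seed feeds two independent substreams
(durations, amplitudes) so either source of randomness can be frozen
independently; the same seed always yields a bit-identical schedule.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict

import numpy as np

OXY, DEOXY, LINGERING = 0, 1, 2
_KIND_NAMES = {OXY: "oxy", DEOXY: "deoxy", LINGERING: "lingering-deoxy"}
_KIND_CODES = {v: k for k, v in _KIND_NAMES.items()}


@dataclass
class Transit:
    """One circulatory transit."""

    kind: str                 #: "oxy" | "deoxy" | "lingering-deoxy"
    duration: float           #: seconds
    piezo_amplitude: float    #: dimensionless; > 0 only for deoxy kinds

    def __post_init__(self):
        if self.kind not in _KIND_CODES:
            raise ValueError(f"unknown transit kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("transit duration must be positive")
        if self.kind == "oxy" and self.piezo_amplitude != 0.0:
            raise ValueError("oxy transits carry no PIEZO1 amplitude")
        if self.kind != "oxy" and self.piezo_amplitude <= 0.0:
            raise ValueError("deoxy transits need a positive amplitude")


@dataclass
class CirculationConfig:
    """Configuration of the stochastic transit schedule.

    Duration bounds in seconds; the amplitude distribution must have mean 1
    (amplitudes scale the configured mean PIEZO1 permeabilities).
    """

    oxy_duration_range: tuple[float, float] = (30.0, 60.0)
    deoxy_duration_range: tuple[float, float] = (30.0, 90.0)
    amplitude_range: tuple[float, float] = (0.25, 1.75)
    lingering_times: tuple[float, ...] = ()   #: schedule times, hours
    lingering_duration: float = 2400.0        #: seconds (40 min)
    seed: int = 0
    total_time: float = 120.0                 #: hours

    def __post_init__(self):
        for name in ("oxy_duration_range", "deoxy_duration_range",
                     "amplitude_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi < np.inf):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi < inf")
        lo, hi = self.amplitude_range
        if abs(0.5 * (lo + hi) - 1.0) > 1e-6:
            raise ValueError("amplitude distribution must have mean 1")
        if self.total_time <= 0:
            raise ValueError("total_time must be positive")


@dataclass
class TransitSchedule:
    """Ordered transit sequence, with array views for the stepper."""

    transits: list[Transit]

    @property
    def kinds(self) -> np.ndarray:
        return np.array([_KIND_CODES[t.kind] for t in self.transits],
                        dtype=np.int64)

    @property
    def durations(self) -> np.ndarray:
        return np.array([t.duration for t in self.transits])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([t.piezo_amplitude for t in self.transits])

    @property
    def total_seconds(self) -> float:
        return float(sum(t.duration for t in self.transits))

    def __len__(self) -> int:
        return len(self.transits)

    def to_text(self) -> str:
        """One transit per line: kind, duration_s, amplitude (replayable)."""
        buf = io.StringIO()
        buf.write("# kind\tduration_s\tamplitude\n")
        for t in self.transits:
            buf.write(f"{t.kind}\t{t.duration!r}\t{t.piezo_amplitude!r}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "TransitSchedule":
        transits = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            kind, dur, amp = line.split("\t")
            transits.append(Transit(kind, float(dur), float(amp)))
        return cls(transits)


def sample_schedule(config: CirculationConfig) -> TransitSchedule:
    """Draw a full stochastic schedule covering ``config.total_time``.

    Oxy and deoxy transits alternate (starting oxygenated, the arterial
    side); lingering episodes replace the deoxy transit concurrent with each
    requested time. The last transit is truncated so the durations sum to
    the total time exactly. Identical seeds give bit-identical schedules.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_dur, rng_amp = [np.random.default_rng(s) for s in ss.spawn(2)]
    total_s = config.total_time * 3600.0

    kinds: list[int] = []
    durs: list[float] = []
    amps: list[float] = []
    t = 0.0
    kind = OXY
    while t < total_s:
        if kind == OXY:
            lo, hi = config.oxy_duration_range
            amp = 0.0
        else:
            lo, hi = config.deoxy_duration_range
            amp = float(rng_amp.uniform(*config.amplitude_range))
        d = float(rng_dur.uniform(lo, hi)) if hi > lo else float(lo)
        kinds.append(kind)
        durs.append(d)
        amps.append(amp)
        t += d
        kind = DEOXY if kind == OXY else OXY

    _insert_lingering(kinds, durs, config)

    # truncate to the exact total time
    t = 0.0
    out: list[Transit] = []
    for k, d, a in zip(kinds, durs, amps):
        if t + d >= total_s:
            d = total_s - t
            if d > 1e-9:
                out.append(Transit(_KIND_NAMES[k], d, a))
            break
        out.append(Transit(_KIND_NAMES[k], d, a))
        t += d
    return TransitSchedule(out)


def _insert_lingering(kinds: list[int], durs: list[float],
                      config: CirculationConfig) -> None:
    """Replace the deoxy transit concurrent with each lingering time by a
    40-min (configurable) lingering-deoxy episode."""
    times = sorted(config.lingering_times)
    chosen: list[int] = []
    for t_h in times:
        t_s = t_h * 3600.0
        # locate the transit containing t_s, then the first deoxy at/after it
        acc = 0.0
        idx = None
        for i, d in enumerate(durs):
            if acc + d > t_s:
                idx = i
                break
            acc += d
        if idx is None:
            raise ValueError(
                f"lingering time {t_h} h lies beyond the schedule")
        if kinds[idx] == LINGERING:
            raise ValueError(
                f"overlapping lingering events: {t_h} h falls inside an "
                "already-inserted lingering episode")
        while idx < len(kinds) and kinds[idx] != DEOXY:
            idx += 1
        if idx >= len(kinds):
            raise ValueError(
                f"no deoxy transit available for lingering at {t_h} h")
        if idx in chosen:
            raise ValueError(
                f"overlapping lingering events (transit {idx} reused)")
        chosen.append(idx)
        kinds[idx] = LINGERING
        durs[idx] = config.lingering_duration
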