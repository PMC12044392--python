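"""Protocol files: a minimal line-oriented text DSL.

A protocol starts from the constitutive properties of the cell (the
reference-state block, dotted keys into the reference configuration),
carries the circulation-schedule bounds, and lists dynamic stages (lingering
episodes, the sudden Na-pump inhibitory step, arbitrary parameter changes)
with non-decreasing start times. ``parse_protocol(write_protocol(p)) == p``.

Example::

    name typical_5day_isc
    duration_h 120.0
    seed 1234
    reference.CNa 10.0
    circulation.oxy_duration_s 30.0 60.0
    stage 12.0 lingering
    stage 96.0 pump-inhibition factor=0.25
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .circulation import CirculationConfig
from .model import ReferenceConfig

STAGE_KINDS = ("lingering", "pump-inhibition", "parameter-change")


class ProtocolError(ValueError):
    """Parse/validation failure; message lists every violation with its
    line number."""


@dataclass
class Stage:
    """One dynamic-stage instruction."""

    time: float              #: start time, hours
    kind: str                #: one of STAGE_KINDS
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in STAGE_KINDS:
            raise ProtocolError(f"unknown stage kind {self.kind!r}")


@dataclass
class Protocol:
    """A full simulation protocol: reference spec + dynamic stages + seed."""

    name: str = "protocol"
    duration_h: float = 120.0
    seed: int = 0
    reference: ReferenceConfig = field(default_factory=ReferenceConfig)
    oxy_duration_s: tuple[float, float] = (30.0, 60.0)
    deoxy_duration_s: tuple[float, float] = (30.0, 90.0)
    amplitude_range: tuple[float, float] = (0.25, 1.75)
    lingering_duration_s: float = 2400.0
    stages: list[Stage] = field(default_factory=list)

    def circulation_config(self, seed: int | None = None) -> CirculationConfig:
        """Materialize the circulation configuration (lingering times come
        from the lingering stages)."""
        return CirculationConfig(
            oxy_duration_range=self.oxy_duration_s,
            deoxy_duration_range=self.deoxy_duration_s,
            amplitude_range=self.amplitude_range,
            lingering_times=tuple(s.time for s in self.stages
                                  if s.kind == "lingering"),
            lingering_duration=self.lingering_duration_s,
            seed=self.seed if seed is None else seed,
            total_time=self.duration_h)

    def inhibition_stage(self) -> Stage | None:
        for s in self.stages:
            if s.kind == "pump-inhibition":
                return s
        return None


def _flatten(obj, prefix: str) -> list[tuple[str, object]]:
    out = []
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        key = f"{prefix}.{f.name}"
        if dataclasses.is_dataclass(v):
            out.extend(_flatten(v, key))
        else:
            out.append((key, v))
    return out


def write_protocol(p: Protocol) -> str:
    """Serialize a protocol; every reference key is written explicitly."""
    lines = ["# iscsim protocol file",
             f"name {p.name}",
             f"duration_h {p.duration_h!r}",
             f"seed {p.seed}",
             ""]
    for key, v in _flatten(p.reference, "reference"):
        lines.append(f"{key} {v!r}")
    lines.append("")
    for key in ("oxy_duration_s", "deoxy_duration_s", "amplitude_range"):
        lo, hi = getattr(p, key)
        lines.append(f"circulation.{key} {lo!r} {hi!r}")
    lines.append(f"circulation.lingering_duration_s {p.lingering_duration_s!r}")
    lines.append("")
    for s in p.stages:
        kv = " ".join(f"{k}={v!r}" if not isinstance(v, str) else f"{k}={v}"
                      for k, v in s.params.items())
        lines.append(f"stage {s.time!r} {s.kind}" + (f" {kv}" if kv else ""))
    return "\n".join(lines) + "\n"


def _set_dotted(obj, path: list[str], raw: str, errors, lineno):
    head, *rest = path
    if not hasattr(obj, head):
        errors.append(f"line {lineno}: unknown key {'.'.join(path)!r}")
        return
    if rest:
        _set_dotted(getattr(obj, head), rest, raw, errors, lineno)
        return
    try:
        setattr(obj, head, float(raw))
    except ValueError:
        errors.append(f"line {lineno}: bad number {raw!r}")


def parse_protocol(text: str) -> Protocol:
    """Parse a protocol file; raises :class:`ProtocolError` listing every
    violation (with line numbers) if the text is invalid."""
    p = Protocol()
    errors: list[str] = []
    saw_reference = False
    stage_times: list[float] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        key = tokens[0]
        try:
            if key == "name":
                p.name = tokens[1]
            elif key == "duration_h":
                p.duration_h = float(tokens[1])
            elif key == "seed":
                p.seed = int(tokens[1])
            elif key.startswith("reference."):
                saw_reference = True
                _set_dotted(p.reference, key.split(".")[1:], tokens[1],
                            errors, lineno)
            elif key.startswith("circulation."):
                sub = key.split(".", 1)[1]
                if sub in ("oxy_duration_s", "deoxy_duration_s",
                           "amplitude_range"):
                    setattr(p, sub, (float(tokens[1]), float(tokens[2])))
                elif sub == "lingering_duration_s":
                    p.lingering_duration_s = float(tokens[1])
                else:
                    errors.append(
                        f"line {lineno}: unknown circulation key {sub!r}")
            elif key == "stage":
                t = float(tokens[1])
                kind = tokens[2]
                if kind not in STAGE_KINDS:
                    errors.append(
                        f"line {lineno}: unknown stage kind {kind!r}")
                    continue
                params = {}
                for tok in tokens[3:]:
                    k, _, v = tok.partition("=")
                    if not _:
                        errors.append(
                            f"line {lineno}: stage parameter {tok!r} is not "
                            "key=value")
                        continue
                    try:
                        params[k] = float(v)
                    except ValueError:
                        params[k] = v
                if stage_times and t < stage_times[-1]:
                    errors.append(
                        f"line {lineno}: stage times must be non-decreasing "
                        f"({t} after {stage_times[-1]})")
                stage_times.append(t)
                p.stages.append(Stage(time=t, kind=kind, params=params))
            else:
                errors.append(f"line {lineno}: unknown directive {key!r}")
        except (IndexError, ValueError) as exc:
            errors.append(f"line {lineno}: {exc}")
    if not saw_reference:
        errors.append("missing reference block (no 'reference.*' entries)")
    if errors:
        raise ProtocolError("invalid protocol:\n  " + "\n  ".join(errors))
    return p
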