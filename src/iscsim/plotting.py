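"""Figure-style plotting for visual QA of simulation runs."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .dynamics import TimeSeries

_REQUIRED = ("time", "relative_volume", "pHi", "Em")


def _check(ts: TimeSeries, cols) -> None:
    missing = [c for c in cols if c not in ts.data.columns]
    if missing:
        raise ValueError(f"missing columns: {', '.join(missing)}")


def plot_volume(ts: TimeSeries, path) -> None:
    """Relative volume vs time over the full lifespan (Fig 1A/B style)."""
    _check(ts, ("time", "relative_volume"))
    fig, ax = plt.subplots(figsize=(7, 4))
    d = ts.data
    ax.plot(d["time"] / 24.0, d["relative_volume"], lw=0.6, color="k")
    ax.set_xlabel("time in circulation (days)")
    ax.set_ylabel("relative cell volume")
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)


def plot_phase1_detail(ts: TimeSeries, path, t_max_h: float = 29.0) -> None:
    """First-1.2-day detail: volume, contents, fluxes, Em, pH."""
    _check(ts, _REQUIRED + ("QNa", "QK", "QA", "JK_gardos"))
    d = ts.data[ts.data["time"] <= t_max_h]
    fig, axes = plt.subplots(3, 2, figsize=(9, 8), sharex=True)
    t = d["time"] / 24.0
    axes[0, 0].plot(t, d["relative_volume"], lw=0.6)
    axes[0, 0].set_ylabel("relative volume")
    for c in ("QNa", "QK", "QA"):
        axes[0, 1].plot(t, d[c], lw=0.6, label=c)
    axes[0, 1].set_ylabel("contents (mmol/Loc)")
    axes[0, 1].legend(fontsize=7)
    for c in ("CNa", "CK", "CA"):
        axes[1, 0].plot(t, d[c], lw=0.6, label=c)
    axes[1, 0].set_ylabel("concentrations (mmol/Lcw)")
    axes[1, 0].legend(fontsize=7)
    axes[1, 1].plot(t, d["JK_gardos"], lw=0.4)
    axes[1, 1].set_ylabel("Gardos K flux (mmol/Loch)")
    axes[2, 0].plot(t, d["Em"], lw=0.6)
    axes[2, 0].set_ylabel("Em (mV)")
    axes[2, 0].set_xlabel("days")
    axes[2, 1].plot(t, d["pHi"], lw=0.6)
    axes[2, 1].set_ylabel("pHi")
    axes[2, 1].set_xlabel("days")
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)


def plot_full_span(ts: TimeSeries, path) -> None:
    """Full-lifespan panels: Em vs EA, Hb osmotic term, Mg, fluxes, ratios."""
    _check(ts, _REQUIRED + ("EA", "Hb_osm_contrib", "MgT", "MgF",
                            "JNa_pump", "rA", "rH"))
    d = ts.data
    t = d["time"] / 24.0
    fig, axes = plt.subplots(4, 2, figsize=(9, 10), sharex=True)
    axes[0, 0].plot(t, d["Em"], lw=0.5, label="Em")
    axes[0, 0].plot(t, d["EA"], lw=0.5, label="EA")
    axes[0, 0].set_ylabel("potential (mV)")
    axes[0, 0].legend(fontsize=7)
    axes[0, 1].plot(t, d["Hb_osm_contrib"], lw=0.5)
    axes[0, 1].set_ylabel("fHb*CHb (mOsmol/Lcw)")
    axes[1, 0].plot(t, d["MgT"], lw=0.5, label="[Mg]T")
    axes[1, 0].plot(t, d["MgF"], lw=0.5, label="[Mg2+]i")
    axes[1, 0].set_ylabel("Mg (mmol/Lcw)")
    axes[1, 0].legend(fontsize=7)
    for c in ("QNa", "QK", "QA"):
        axes[1, 1].plot(t, d[c], lw=0.5, label=c)
    axes[1, 1].set_ylabel("contents (mmol/Loc)")
    axes[1, 1].legend(fontsize=7)
    for c in ("CNa", "CK", "CA"):
        axes[2, 0].plot(t, d[c], lw=0.5, label=c)
    axes[2, 0].set_ylabel("conc (mmol/Lcw)")
    axes[2, 0].legend(fontsize=7)
    axes[2, 1].plot(t, d["JNa_pump"], lw=0.4)
    axes[2, 1].set_ylabel("JNa pump (mmol/Loch)")
    axes[3, 0].plot(t, d["rA"], lw=0.5, label="rA")
    axes[3, 0].plot(t, d["rH"], lw=0.5, ls="--", label="rH")
    axes[3, 0].set_ylabel("ratio")
    axes[3, 0].legend(fontsize=7)
    axes[3, 0].set_xlabel("days")
    axes[3, 1].plot(t, d["pHi"], lw=0.5)
    axes[3, 1].set_ylabel("pHi")
    axes[3, 1].set_xlabel("days")
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)


def plot_pa_scan(runs: dict[float, TimeSeries], path) -> None:
    """Overlaid volume traces, one per anion-permeability value (Fig 1C)."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for pa, ts in runs.items():
        d = ts.data
        ax.plot(d["time"] / 24.0, d["relative_volume"], lw=0.6,
                label=f"PA = {pa}/h")
    ax.set_xlabel("time in circulation (days)")
    ax.set_ylabel("relative cell volume")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)


def plot_figures(ts: TimeSeries, outdir) -> list:
    """Produce the three standard QA figures for one run."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = [outdir / "volume.png", outdir / "phase1_detail.png",
             outdir / "full_span.png"]
    plot_volume(ts, paths[0])
    plot_phase1_detail(ts, paths[1])
    plot_full_span(ts, paths[2])
    return paths
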