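import pytest

from iscsim import build_reference_state, lifecycle


@pytest.fixture(scope="session")
def reference():
    """Default stress-reticulocyte reference state (pump-leak constructed)."""
    return build_reference_state()


@pytest.fixture(scope="session")
def typical_runs():
    """Three seeded runs of the full 5-day typical-ISC protocol.

    Returns {seed: (TimeSeries, Reference, PhaseSummary)} for seeds 1-3.
    """
    out = {}
    for seed in (1, 2, 3):
        protocol = lifecycle.typical_isc_protocol()
        ts, ref = lifecycle.run_protocol(protocol, seed=seed)
        ps = lifecycle.detect_phases(
            ts, ref, t_inhibition=protocol.inhibition_stage().time)
        out[seed] = (ts, ref, ps)
    return out


@pytest.fixture(scope="session")
def typical_run(typical_runs):
    """Single 5-day typical run (seed 1) with its phase summary."""
    return typical_runs[1]
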