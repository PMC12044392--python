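"""Fast algebraic equilibration: Dalmark charge, fHb, Jacobs-Stewart +
electroneutrality + osmotic solve, divalent buffering."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iscsim import (BufferParams, HbParams, build_reference_state, ca_free,
                    hb_charge, hb_osmotic_coeff, mg_free, solve_ph_em_water)
from iscsim.constants import RTF_MV
from iscsim.equilibria import anion_nernst_potential


@pytest.mark.parametrize("phi, pi, expected", [
    (7.4, 7.4, 0.0),           # isoelectric point
    (6.4, 7.4, 8.0),           # acidified: positive net charge
    (7.65, 7.4, -2.0),
])
def test_hb_charge_examples(phi, pi, expected):
    assert hb_charge(phi, pi, -8.0) == pytest.approx(expected, abs=1e-12)


def test_fhb_ideal_dilute_limit():
    assert hb_osmotic_coeff(0.0) == 1.0
    with pytest.raises(ValueError):
        hb_osmotic_coeff(-1.0)


@given(c1=st.floats(0.0, 30.0), c2=st.floats(0.0, 30.0))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_hb_osmotic_contribution_strictly_increasing(c1, c2):
    lo, hi = sorted((c1, c2))
    if hi - lo < 1e-9:
        return
    assert hb_osmotic_coeff(hi) * hi > hb_osmotic_coeff(lo) * lo


def test_reference_hb_contribution_near_seven(reference):
    """Calibrated virials put the reference fHb*CHb near 7 mOsmol/Lcw."""
    chb = reference.cell.QHb / reference.cell.Vw
    contrib = hb_osmotic_coeff(chb, reference.hb.b1, reference.hb.b2) * chb
    assert contrib == pytest.approx(7.0, rel=0.02)


def test_anion_nernst_examples():
    assert anion_nernst_potential(1.0) == 0.0
    assert anion_nernst_potential(1.4) == \
        pytest.approx(-RTF_MV * math.log(1.4), abs=1e-12)
    assert anion_nernst_potential(1.4) == pytest.approx(-8.99, abs=0.01)


def test_solve_residuals_and_idempotence(reference):
    res, state = solve_ph_em_water(reference.cell, reference.medium,
                                   reference.hb, reference.buffers,
                                   reference.nX, reference.transport)
    assert res.converged
    assert abs(res.rH - res.rA) / res.rA < 1e-6
    res2, state2 = solve_ph_em_water(state, reference.medium, reference.hb,
                                     reference.buffers, reference.nX,
                                     reference.transport)
    assert state2.pHi == pytest.approx(state.pHi, abs=1e-10)
    assert state2.Vw == pytest.approx(state.Vw, abs=1e-10)
    assert state2.Em == pytest.approx(state.Em, abs=1e-8)


def test_dehydration_acidifies(reference):
    """Removing KA at fixed medium concentrates the impermanent anions,
    displaces diffusible anions and drives pHi down (rA up)."""
    c = reference.cell
    shrunk = replace(c, QK=c.QK - 30.0, QA=c.QA - 30.0)
    res0, _ = solve_ph_em_water(c, reference.medium, reference.hb,
                                reference.buffers, reference.nX)
    res1, _ = solve_ph_em_water(shrunk, reference.medium, reference.hb,
                                reference.buffers, reference.nX)
    assert res1.pHi < res0.pHi
    assert res1.rA > res0.rA
    assert res1.Vw < res0.Vw


def test_solver_beats_grid_search(reference):
    """Brute-force oracle: the solver's (pHi, Vw) attains a smaller joint
    residual norm than any point of a surrounding grid."""
    c = replace(reference.cell, QK=reference.cell.QK - 20.0)
    res, state = solve_ph_em_water(c, reference.medium, reference.hb,
                                   reference.buffers, reference.nX)
    m, hb, b = reference.medium, reference.hb, reference.buffers

    def norm(phi, vw):
        cai = m.CAo * 10 ** (phi - m.pHo)     # Jacobs-Stewart equality
        chb = c.QHb / vw
        fhb = hb_osmotic_coeff(chb, hb.b1, hb.b2)
        mgf = mg_free(c.QMgT, vw, b, oxy=True)
        caf = ca_free(c.QCaT, vw, b)
        charge = (c.QNa / vw + c.QK / vw + 2 * (caf + mgf) - cai
                  + hb.alpha * (phi - hb.pI_oxy) * chb
                  + reference.nX * c.QX / vw)
        osm = (c.QNa + c.QK + c.QCaT + c.QMgT + c.QX) / vw + cai \
            + fhb * chb - m.Osmo
        return math.hypot(charge, osm)

    best_grid = min(norm(phi, vw)
                    for phi in np.linspace(state.pHi - 0.1, state.pHi + 0.1, 21)
                    for vw in np.linspace(state.Vw * 0.9, state.Vw * 1.1, 21))
    assert norm(state.pHi, state.Vw) <= best_grid + 1e-12


def test_mg_free_unbuffered_and_deoxy_shift():
    b = BufferParams()
    none = BufferParams(ATP_total=0.0, BPG_total=0.0)
    assert mg_free(2.0, 0.75, none) == pytest.approx(2.0 / 0.75, rel=1e-12)
    oxy = mg_free(2.0, 0.75, b, oxy=True)
    deoxy = mg_free(2.0, 0.75, b, oxy=False)
    assert deoxy > oxy    # deoxy-Hb sequesters the buffers, freeing Mg


@given(q=st.floats(0.1, 5.0), dq=st.floats(0.01, 2.0))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_mg_free_monotone_in_total(q, dq):
    b = BufferParams()
    assert mg_free(q + dq, 0.75, b) > mg_free(q, 0.75, b)


def test_ca_free_linear_buffer():
    b = BufferParams(ca_buffer_ratio=0.2)
    assert ca_free(0.0, 0.75, b) == 0.0
    assert ca_free(0.3, 0.75, BufferParams(ca_buffer_ratio=1.0)) == \
        pytest.approx(0.4)
    # halving water at fixed content doubles the free concentration
    assert ca_free(0.3, 0.375, b) == pytest.approx(2 * ca_free(0.3, 0.75, b))


def test_buffer_validation():
    with pytest.raises(ValueError):
        BufferParams(Kd_ATP_deoxy=0.01)      # deoxy Kd below oxy
    with pytest.raises(ValueError):
        BufferParams(ca_buffer_ratio=0.0)
    with pytest.raises(ValueError):
        HbParams(pI_oxy=7.5, pI_deoxy=7.4)
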