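"""Membrane flux laws: Goldman limits, pump kinetics, Gardos gating,
PIEZO1 contribution, K:Cl cotransport, pathway decomposition."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.optimize import brentq

from iscsim import (TransportParams, build_reference_state, gardos_flux,
                    goldman_flux, kcl_flux, na_pump_flux, piezo_fluxes,
                    pmca_flux, total_fluxes)
from iscsim import circulation, dynamics
from iscsim.constants import RTF_MV
from iscsim.transport import gardos_permeability


def test_goldman_zero_field_limit():
    assert goldman_flux(2.0, 1.0, 0.0, 130.0, 5.0) == \
        pytest.approx(2.0 * 125.0, rel=1e-9)
    assert goldman_flux(2.0, 1.0, 0.0, 5.0, 5.0) == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("z", [1.0, -1.0, 2.0])
def test_goldman_nernst_equilibrium(z):
    em = -43.0
    u = z * em / RTF_MV
    co = 100.0
    ci = co * math.exp(-u)
    assert goldman_flux(5.0, z, em, ci, co) == pytest.approx(0.0, abs=1e-9)


def test_goldman_series_branch_continuity():
    # the u -> 0 series must join the generic branch smoothly
    a = goldman_flux(1.0, 1.0, 1e-7 * RTF_MV, 130.0, 5.0)
    b = goldman_flux(1.0, 1.0, 1e-5 * RTF_MV, 130.0, 5.0)
    assert a == pytest.approx(b, rel=1e-4)
    with pytest.raises(ValueError):
        goldman_flux(-1.0, 1.0, 0.0, 1.0, 1.0)


@pytest.fixture(scope="module")
def params():
    return build_reference_state().transport


def test_na_pump_no_substrate(params):
    assert na_pump_flux(0.0, 130.0, 0.4, params) == (0.0, 0.0)


def test_na_pump_mg_half_activation(params):
    """[Mg2+]i = KMg = 0.050 mmol/Lcw gives exactly half the Mg-saturated
    pump rate (the ~50 uM half-activation)."""
    j_half, _ = na_pump_flux(10.0, 130.0, 0.050, params)
    j_sat, _ = na_pump_flux(10.0, 130.0, 1e9, params)
    assert j_half == pytest.approx(0.5 * j_sat, rel=1e-9)


def test_na_pump_k_inhibition_relief(params):
    """Lowering intracellular K from 130 to 5 mmol/Lcw increases the pump
    rate at fixed Na (relief of the K inhibition of Na affinity)."""
    j_high_k, _ = na_pump_flux(10.0, 130.0, 0.4, params)
    j_low_k, _ = na_pump_flux(10.0, 5.0, 0.4, params)
    assert abs(j_low_k) > abs(j_high_k)


def test_na_pump_stoichiometry_exact(params):
    for cna, ck in [(10.0, 130.0), (50.0, 30.0), (3.0, 80.0)]:
        jna, jk = na_pump_flux(cna, ck, 0.4, params)
        assert jk == -(2.0 / 3.0) * jna


def test_pmca_michaelis(params):
    assert pmca_flux(0.0, params) == 0.0
    assert pmca_flux(params.KmCa, params) == \
        pytest.approx(-params.pmca_Fmax / 2, rel=1e-12)
    assert pmca_flux(1e6, params) == pytest.approx(-36.0, rel=1e-4)


def test_gardos_gating(params):
    assert gardos_flux(0.0, 130.0, 5.0, -9.0, params) == 0.0
    assert gardos_permeability(params.K05Ca, params) == \
        pytest.approx(params.gardos_PKmax / 2, rel=1e-12)
    # gradient exhaustion: CK at its Nernst value -> no net flux despite
    # fully open channels (the K-depleted phase-2 condition)
    em = -43.0
    ck_eq = 5.0 * math.exp(-em / RTF_MV)
    assert gardos_flux(1.0, ck_eq, 5.0, em, params) == pytest.approx(0, abs=1e-9)


def test_piezo_closed_when_oxygenated(reference):
    fl = piezo_fluxes(reference.cell, reference.medium, reference.transport)
    assert fl.Na == fl.K == fl.A == fl.CaT == fl.MgT == 0.0


def test_piezo_hyperpolarization_boosts_ca_influx(reference):
    deoxy = replace(reference.cell, oxy=False)
    j1 = piezo_fluxes(deoxy, reference.medium, reference.transport).JCa_piezo
    deeper = replace(deoxy, Em=deoxy.Em - 20.0)
    j2 = piezo_fluxes(deeper, reference.medium, reference.transport).JCa_piezo
    assert j2 > j1 > 0.0
    with pytest.raises(ValueError):
        piezo_fluxes(deoxy, reference.medium, reference.transport, -1.0)


def test_deoxy_anion_permeability_ratio(reference):
    """Default deoxy-PIEZO1 anion permeability 50/h against the 1.3/h
    ground value: ratio ~ 38.5."""
    pz = reference.transport.piezo
    assert pz.PzA / reference.transport.PA_ground == pytest.approx(38.46, 0.01)


def test_kcl_cotransport(params):
    assert kcl_flux(130.0, 79.0, 5.0, 125.0, params) == (0.0, 0.0)  # off
    p = replace(params, kcl_rate=1e-4)
    ck, ca = 5.0 * 125.0 / 79.0, 79.0
    jk, ja = kcl_flux(ck, ca, 5.0, 125.0, p)
    assert jk == pytest.approx(0.0, abs=1e-12)   # product equilibrium
    jk, ja = kcl_flux(130.0, 79.0, 5.0, 125.0, p)
    assert jk == ja < 0.0                         # equal, efflux


def test_pathway_decomposition_sums(reference):
    deoxy = replace(reference.cell, oxy=False)
    fl = total_fluxes(deoxy, reference.medium, reference.transport,
                      reference.buffers, amplitude=1.3)
    assert fl.Na == pytest.approx(fl.JNa_pump + fl.JNa_leak + fl.JNa_piezo,
                                  abs=1e-12)
    assert fl.K == pytest.approx(fl.JK_pump + fl.JK_gardos + fl.JK_leak
                                 + fl.JK_piezo + fl.JK_kcl, abs=1e-12)
    assert fl.A == pytest.approx(fl.JA_leak + fl.JA_piezo + fl.JA_kcl,
                                 abs=1e-12)


def test_donnan_relaxation_oracle():
    """With pumps off and PIEZO1 held open, long integration relaxes to the
    analytic Donnan equilibrium (common ratio r for all permeant species,
    rH = rA, electroneutrality and osmotic balance with the impermanent
    pool)."""
    from iscsim.model import ReferenceConfig
    ref = build_reference_state(ReferenceConfig(PzNa=5.0, PzK=5.0, PzMg=1.0))
    ref.transport.napump_Fmax = 0.0
    ref.transport.pmca_Fmax = 0.0
    sched = circulation.TransitSchedule(
        [circulation.Transit("deoxy", 3600.0, 1.0)] * 300)
    ts = dynamics.run(ref, sched, dt=2.0, record_every=3600.0)
    end = ts.data.iloc[-1]

    m, hb, b = ref.medium, ref.hb, ref.buffers
    QHb, QX, nX = ref.cell.QHb, ref.cell.QX, ref.nX

    def osm_residual(r):
        caf, mgf = m.CaO * r * r, m.MgO * r * r
        phi = m.pHo - math.log10(r)
        nhb = hb.alpha * (phi - hb.pI_deoxy)
        vw = -(nhb * QHb + nX * QX) / (145.0 * r - 125.0 / r
                                       + 2.0 * (caf + mgf))
        mg_bound = b.ATP_total * mgf / (b.Kd_ATP_deoxy + mgf) \
            + b.BPG_total * mgf / (b.Kd_BPG_deoxy + mgf)
        chb = QHb / vw
        fhb = 1 + hb.b1 * chb + hb.b2 * chb ** 2
        return (145.0 * r + 125.0 / r + caf / b.ca_buffer_ratio + mgf
                + mg_bound + QX / vw + fhb * chb - m.Osmo)

    r = brentq(osm_residual, 0.93, 1.2, xtol=1e-14)
    assert end["CNa"] / m.CNao == pytest.approx(r, abs=1e-6)
    assert end["CK"] / m.CKo == pytest.approx(r, abs=1e-6)
    assert end["CA"] / m.CAo == pytest.approx(1.0 / r, abs=1e-6)
    assert end["Em"] == pytest.approx(-RTF_MV * math.log(r), abs=1e-4)


def test_transport_params_validation():
    with pytest.raises(ValueError):
        TransportParams(PNa=-1.0)
    with pytest.raises(ValueError):
        TransportParams(pump_inhibition_factor=0.0)
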