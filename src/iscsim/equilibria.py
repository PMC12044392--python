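"""Fast algebraic sub-solvers applied after every flux step.

Between slow content changes, three processes are treated as instantaneous:

* the Jacobs-Stewart cycle (anion exchanger + CO2 shunt), which restores the
  equality of the transmembrane proton and diffusible-anion concentration
  ratios, rH = rA, by moving H+ and A- together;
* osmotic water equilibration, including the strongly nonlinear hemoglobin
  virial term fHb(CHb)*CHb;
* electroneutrality, with the hemoglobin net charge given by the Dalmark
  relation nHb = alpha*(pHi - pI) and a fixed charge nX on the impermeant
  organic/inorganic phosphate pool.

Free cytosolic Mg2+ follows 1:1 mass-action binding to ATP and 2,3-BPG
(with deoxy-shifted dissociation constants), and free Ca2+ a linear buffer.

The membrane potential is solved from the zero-net-current condition over the
electrodiffusive pathways plus the electrogenic pumps; with the diffusible
anions dominating the membrane conductance it stays within ~1 mV of the anion
Nernst potential EA = -(RT/F)*ln(rA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernel as K
from .constants import RTF_MV
from .model import (BufferParams, CellState, HbParams, MediumState,
                    TransportParams, PiezoParams)


class EquilibrationError(RuntimeError):
    """Equilibration failed; the message carries the diagnostic."""


@dataclass
class EquilibriumResult:
    """Outcome of a fast-equilibration solve, with residual diagnostics."""

    pHi: float
    Em: float
    Vw: float
    nHb: float        #: Eq/mol
    fHb: float        #: dimensionless osmotic coefficient
    rA: float         #: CAo/CAi
    rH: float         #: [H+]i/[H+]o
    residual_charge: float    #: mEq/Lcw
    residual_osmotic: float   #: mOsm/Lcw
    residual_ratio: float     #: |rH - rA|/rA

    @property
    def converged(self) -> bool:
        return (abs(self.residual_charge) < 1e-6
                and abs(self.residual_osmotic) < 1e-6
                and self.residual_ratio < 1e-6)


def hb_charge(pHi: float, pI: float, alpha: float = -8.0) -> float:
    """Net charge on hemoglobin (Eq/mol) from the Dalmark relation.

    nHb = alpha*(pHi - pI); with alpha = -8 for HbS the charge is positive
    when the cell pH sits below the isoelectric point, as in acidified ISCs.
    """
    return K.hb_charge(pHi, pI, alpha)


def hb_osmotic_coeff(CHb: float, b1: float = 0.0645,
                     b2: float = 0.0258) -> float:
    """Osmotic coefficient of hemoglobin, fHb = 1 + b1*CHb + b2*CHb**2.

    Strictly increasing and convex in CHb (mmol/Lcw); the hemoglobin
    contribution to cell osmolarity is fHb*CHb.
    """
    if CHb < 0:
        raise ValueError("CHb must be >= 0")
    return K.hb_osmotic_coeff(CHb, b1, b2)


def mg_free(QMgT: float, Vw: float, buffers: BufferParams,
            oxy: bool = True) -> float:
    """Free [Mg2+]i (mmol/Lcw) from mass-action binding to ATP and 2,3-BPG.

    In the deoxy state the effective dissociation constants are larger
    (deoxy-Hb binds the nucleotide buffers), so MgF(deoxy) > MgF(oxy) at
    equal total Mg.
    """
    kd_atp = buffers.Kd_ATP_oxy if oxy else buffers.Kd_ATP_deoxy
    kd_bpg = buffers.Kd_BPG_oxy if oxy else buffers.Kd_BPG_deoxy
    return K.mg_free(QMgT, Vw, buffers.ATP_total, buffers.BPG_total,
                     kd_atp, kd_bpg, 0.0)


def ca_free(QCaT: float, Vw: float, buffers: BufferParams) -> float:
    """Free [Ca2+]i (mmol/Lcw) with a linear cytosolic buffer."""
    if QCaT < 0:
        raise ValueError("QCaT must be >= 0")
    return buffers.ca_buffer_ratio * QCaT / Vw


def anion_nernst_potential(rA: float) -> float:
    """EA = -(RT/F)*ln(rA) at 37 degC, in mV."""
    return -RTF_MV * math.log(rA)


def solve_ph_em_water(state: CellState, medium: MediumState, hb: HbParams,
                      buffers: BufferParams, nX: float,
                      transport: TransportParams | None = None,
                      Vw0: float = 0.75, Vs: float = 0.25,
                      ) -> tuple[EquilibriumResult, CellState]:
    """Joint (pHi, Vw, Em) equilibration at fixed cation contents.

    Returns the unique solution of (i) rH = rA, (ii) electroneutrality with
    the Dalmark nHb and fixed nX, (iii) osmotic equality including fHb*CHb.
    QA is shifted by the (electroneutral) Jacobs-Stewart flux. Em comes from
    the zero-net-current condition when ``transport`` is given, else it is
    set to the anion Nernst potential EA (the anion-dominated limit).
    """
    from .model import Reference, ReferenceConfig
    tp = transport if transport is not None else TransportParams()
    cfg = ReferenceConfig(medium=medium, hb=hb, buffers=buffers, Vw=Vw0,
                          Vs=Vs)
    ref = Reference(cell=state, transport=tp, medium=medium, hb=hb,
                    buffers=buffers, nX=nX, Vs=Vs, ref_na_pump_flux=0.0,
                    ref_ca_pump_flux=0.0, config=cfg)
    p = ref.params_array()
    s = state.to_array()
    code = K.equilibrate(s, p)
    if code == 1:
        raise EquilibrationError(
            "anion depletion: no osmotic solution in the admissible pH "
            "bracket (CA would exceed the medium osmolarity)")
    if code != 0:
        raise EquilibrationError(
            f"no convergence in the pH bracket [4.5, 9.5] (code {code})")
    piezo_open = tp.piezo.open and s[K.S_OXY] < 0.5
    if transport is not None:
        s[K.S_EM] = K.solve_em(s, p, piezo_open, tp.piezo.amplitude)
    else:
        s[K.S_EM] = anion_nernst_potential(medium.CAo / (s[K.S_QA] / s[K.S_VW]))

    new = CellState.from_array(s, t=state.t)
    res = _diagnostics(new, medium, hb, buffers, nX)
    return res, new


def _diagnostics(state: CellState, medium: MediumState, hb: HbParams,
                 buffers: BufferParams, nX: float) -> EquilibriumResult:
    vw = state.Vw
    cai = state.QA / vw
    rA = medium.CAo / cai
    rH = 10.0 ** (medium.pHo - state.pHi)
    pi = hb.pI_oxy if state.oxy else hb.pI_deoxy
    nhb = K.hb_charge(state.pHi, pi, hb.alpha)
    chb = state.QHb / vw
    fhb = K.hb_osmotic_coeff(chb, hb.b1, hb.b2)
    charge = (state.QNa / vw + state.QK / vw
              + 2.0 * (state.CaF + state.MgF) - cai
              + nhb * chb + nX * state.QX / vw)
    osm = (state.QNa + state.QK + state.QCaT + state.QMgT
           + state.QX) / vw + cai + fhb * chb - medium.Osmo
    return EquilibriumResult(
        pHi=state.pHi, Em=state.Em, Vw=vw, nHb=nhb, fHb=fhb, rA=rA, rH=rH,
        residual_charge=charge, residual_osmotic=osm,
        residual_ratio=abs(rH - rA) / rA)
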