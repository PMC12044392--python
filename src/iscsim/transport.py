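"""Membrane flux laws.

Ground electrodiffusive leaks and the PIEZO1 open-state pathway follow the
constant-field (Goldman) flux equation; the Na/K pump has cubic Na-site
kinetics with competitive intracellular-K inhibition of its apparent Na
affinity, saturable [Mg2+]i activation and exact 3:2 stoichiometry; the
plasma-membrane Ca pump (PMCA) is a saturating Michaelis pump; the Gardos
channel is a Ca2+-activated K permeability with Hill gating; K:Cl cotransport
(off by default) is an electroneutral product-gradient pathway.

Sign conventions: :func:`goldman_flux` returns flux in the *efflux-positive*
form in which the constant-field equation is usually written; everything
stored in a :class:`FluxVector` uses the reporting convention of the package,
influx positive / efflux negative (so pump fluxes are negative numbers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel as K
from .model import CellState, MediumState, TransportParams, BufferParams


@dataclass
class FluxVector:
    """Per-species net fluxes with per-pathway decomposition, mmol/Loch.

    Influx positive, efflux negative. Species totals are exact sums of their
    pathway terms; the Na-pump terms satisfy JK_pump = -(2/3)*JNa_pump.
    """

    JNa_pump: float = 0.0
    JK_pump: float = 0.0
    JCa_pump: float = 0.0
    JK_gardos: float = 0.0
    JNa_leak: float = 0.0
    JK_leak: float = 0.0
    JA_leak: float = 0.0
    JCa_leak: float = 0.0
    JNa_piezo: float = 0.0
    JK_piezo: float = 0.0
    JA_piezo: float = 0.0
    JCa_piezo: float = 0.0
    JMg_piezo: float = 0.0
    JK_kcl: float = 0.0
    JA_kcl: float = 0.0

    @property
    def Na(self) -> float:
        return self.JNa_pump + self.JNa_leak + self.JNa_piezo

    @property
    def K(self) -> float:
        return (self.JK_pump + self.JK_gardos + self.JK_leak
                + self.JK_piezo + self.JK_kcl)

    @property
    def A(self) -> float:
        return self.JA_leak + self.JA_piezo + self.JA_kcl

    @property
    def CaT(self) -> float:
        return self.JCa_pump + self.JCa_leak + self.JCa_piezo

    @property
    def MgT(self) -> float:
        return self.JMg_piezo

    @classmethod
    def from_kernel(cls, fl: np.ndarray) -> "FluxVector":
        return cls(JNa_pump=fl[0], JK_pump=fl[1], JCa_pump=fl[2],
                   JK_gardos=fl[3], JNa_leak=fl[4], JK_leak=fl[5],
                   JA_leak=fl[6], JCa_leak=fl[7], JNa_piezo=fl[8],
                   JK_piezo=fl[9], JA_piezo=fl[10], JCa_piezo=fl[11],
                   JMg_piezo=fl[12], JK_kcl=fl[13], JA_kcl=fl[14])

    def __add__(self, other: "FluxVector") -> "FluxVector":
        return FluxVector(*[a + b for a, b in
                            zip(self.__dict__.values(),
                                other.__dict__.values())])


def goldman_flux(P: float, z: float, Em: float, Ci: float, Co: float) -> float:
    """Constant-field electrodiffusive flux, mmol/Loch, *efflux positive*.

    J = P*u*(Ci - Co*exp(-u))/(1 - exp(-u)) with u = z*F*Em/RT; the u -> 0
    limit is handled by series expansion. P in 1/h, concentrations in
    mmol/Lcw (cell) and mmol/L (medium).
    """
    if P < 0:
        raise ValueError("permeability must be >= 0")
    return K.ghk_flux(P, z, Em, Ci, Co)


def na_pump_flux(CNa: float, CK: float, MgF: float,
                 p: TransportParams) -> tuple[float, float]:
    """Na/K pump fluxes (JNa_pump, JK_pump), efflux negative.

    JNa = -Fmax*inh*[CNa/(CNa + KmNa*(1 + CK/KiK))]**3 * MgF/(MgF + KMg),
    JK = -(2/3)*JNa. The magnitude increases with CNa and MgF and decreases
    with CK (the intracellular-K inhibition whose relief drives the rising
    pump activity during the hyperdense collapse).
    """
    return K.na_pump(CNa, CK, MgF, _pack(p))


def pmca_flux(CaF: float, p: TransportParams) -> float:
    """PMCA Ca extrusion, -Fmax*CaF/(CaF + KmCa), efflux negative."""
    if CaF < 0:
        raise ValueError("CaF must be >= 0")
    return K.pmca(CaF, _pack(p))


def gardos_permeability(CaF: float, p: TransportParams) -> float:
    """Ca-activated K permeability, PKmax*CaF^h/(CaF^h + K05Ca^h), 1/h."""
    return K.gardos_pk(CaF, _pack(p))


def gardos_flux(CaF: float, CK: float, CKo: float, Em: float,
                p: TransportParams) -> float:
    """Gardos-channel K flux (efflux negative): Goldman flux through the
    Ca-activated permeability. Zero at resting CaF (channels silent) and
    zero again once CK reaches electrochemical equilibrium, the K-depleted
    phase-2 condition."""
    pk = K.gardos_pk(CaF, _pack(p))
    return -K.ghk_flux(pk, 1.0, Em, CK, CKo)


def kcl_flux(CK: float, CA: float, CKo: float, CAo: float,
             p: TransportParams) -> tuple[float, float]:
    """Electroneutral K:Cl cotransport, equal K and A terms (efflux
    negative), proportional to the product gradient CK*CA - CKo*CAo."""
    j = K.kcl_cotransport(CK, CA, CKo, CAo, p.kcl_rate)
    return j, j


def piezo_fluxes(state: CellState, medium: MediumState, p: TransportParams,
                 amplitude: float = 1.0) -> FluxVector:
    """PIEZO1 open-state flux contribution (all species, poor selectivity).

    Deoxygenation opens the channel for the whole transit; on reoxygenation
    the contribution is zero (spontaneous inactivation restored instantly).
    The amplitude factor scales all per-species permeabilities.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if state.oxy:
        return FluxVector()
    pz = p.piezo
    em = state.Em
    vw = state.Vw
    return FluxVector(
        JNa_piezo=-K.ghk_flux(amplitude * pz.PzNa, 1.0, em,
                              state.QNa / vw, medium.CNao),
        JK_piezo=-K.ghk_flux(amplitude * pz.PzK, 1.0, em,
                             state.QK / vw, medium.CKo),
        JA_piezo=-K.ghk_flux(amplitude * pz.PzA, -1.0, em,
                             state.QA / vw, medium.CAo),
        JCa_piezo=-K.ghk_flux(amplitude * pz.PzCa, 2.0, em,
                              state.CaF, medium.CaO),
        JMg_piezo=-K.ghk_flux(amplitude * pz.PzMg, 2.0, em,
                              state.MgF, medium.MgO))


def total_fluxes(state: CellState, medium: MediumState, p: TransportParams,
                 buffers: BufferParams | None = None,
                 piezo_open: bool | None = None,
                 amplitude: float = 1.0) -> FluxVector:
    """All pathway fluxes at the given state (influx positive).

    ``piezo_open`` defaults to the deoxygenated condition of the state
    (deoxygenation is necessary and sufficient to open PIEZO1).
    """
    from .model import Reference, ReferenceConfig, HbParams
    if piezo_open is None:
        piezo_open = not state.oxy
    b = buffers if buffers is not None else BufferParams()
    cfg = ReferenceConfig(medium=medium, buffers=b)
    ref = Reference(cell=state, transport=p, medium=medium, hb=HbParams(),
                    buffers=b, nX=-1.0, Vs=0.25, ref_na_pump_flux=0.0,
                    ref_ca_pump_flux=0.0, config=cfg)
    fl = K.fluxes(state.to_array(), ref.params_array(), piezo_open, amplitude)
    return FluxVector.from_kernel(fl)


def _pack(p: TransportParams) -> np.ndarray:
    arr = np.zeros(K.NPAR)
    arr[K.I_NAP_FMAX] = p.napump_Fmax
    arr[K.I_KM_NA] = p.KmNa
    arr[K.I_KI_K] = p.KiK
    arr[K.I_K_MG] = p.KMg
    arr[K.I_PUMP_INH] = p.pump_inhibition_factor
    arr[K.I_PMCA_FMAX] = p.pmca_Fmax
    arr[K.I_KM_CA] = p.KmCa
    arr[K.I_GARDOS_PKMAX] = p.gardos_PKmax
    arr[K.I_K05CA] = p.K05Ca
    arr[K.I_HILL] = p.hill
    return arr
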