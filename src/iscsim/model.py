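"""Domain types and construction of the reference (initial steady) state.

The simulated cell is an ISC-destined stress reticulocyte: a macrocytic,
low-hemoglobin immature red cell with strongly elevated Na- and Ca-pump
turnover. The reference state is an *oxygenated steady state* built by
pump-leak construction: the user specifies the medium, the intracellular
composition and the pump turnover rates, and the ground leak permeabilities
are back-computed so that passive leaks exactly cancel the pump fluxes for
every species. Dynamics in a simulation are then attributable entirely to the
deoxygenation responses (PIEZO1 opening, pI shift, Mg-buffer shift) and to
protocol events, never to an unbalanced start.

Unit conventions: see :mod:`iscsim.constants`. Contents are mmol per liter of
original cells (mmol/Loc), concentrations mmol per liter cell water
(mmol/Lcw), fluxes mmol/(Loc*h) with influx positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from . import _kernel as K


class NoSteadyStateError(ValueError):
    """Raised when no electroneutral, osmotically balanced steady state
    exists for the requested composition and pump rates; the message names
    the residual that fails."""


@dataclass
class MediumState:
    """Plasma, treated as an infinite constant reservoir at 37 degC."""

    CNao: float = 140.0    #: plasma Na+, mmol/L
    CKo: float = 5.0       #: plasma K+, mmol/L
    CAo: float = 125.0     #: plasma Cl- + HCO3- (lumped A-), mmol/L
    pHo: float = 7.40
    CaO: float = 1.2       #: plasma free Ca2+, mmol/L
    MgO: float = 0.5       #: plasma free Mg2+, mmol/L
    Osmo: float = 290.0    #: plasma osmolarity, mOsm/L
    temperature: float = 37.0

    def __post_init__(self):
        for name in ("CNao", "CKo", "CAo", "CaO", "MgO", "Osmo"):
            if getattr(self, name) <= 0:
                raise ValueError(f"medium {name} must be positive")


@dataclass
class HbParams:
    """Hemoglobin titration (Dalmark) and osmotic (virial) behavior.

    ``nHb = alpha*(pHi - pI)`` with alpha = -8 Eq/(mol*pH) for HbS, so the
    net charge is positive below the isoelectric point. Deoxygenation raises
    the pI (7.4 for deoxy-HbS at 37 degC); ``fHb = 1 + b1*CHb + b2*CHb**2``.
    """

    pI_oxy: float = 7.20
    pI_deoxy: float = 7.40
    alpha: float = -8.0    #: Eq/(mol*pH-unit)
    b1: float = 0.0645     #: Lcw/mmol
    b2: float = 0.0258     #: (Lcw/mmol)**2

    def __post_init__(self):
        if self.pI_deoxy < self.pI_oxy:
            raise ValueError("pI_deoxy must be >= pI_oxy")


@dataclass
class BufferParams:
    """Cytosolic Mg buffering by ATP and 2,3-BPG, and linear Ca buffering.

    Deoxy-Hb sequesters ATP and 2,3-BPG, which is represented as larger
    effective Mg dissociation constants in the deoxy state (freeing Mg2+
    during deoxy transits).
    """

    ATP_total: float = 1.8       #: mmol/Lcw
    BPG_total: float = 7.0       #: mmol/Lcw
    Kd_ATP_oxy: float = 0.08     #: mmol/Lcw
    Kd_ATP_deoxy: float = 0.14
    Kd_BPG_oxy: float = 3.0
    Kd_BPG_deoxy: float = 5.5
    ca_buffer_ratio: float = 0.2  #: free/total cytosolic Ca fraction

    def __post_init__(self):
        if self.Kd_ATP_deoxy < self.Kd_ATP_oxy or \
                self.Kd_BPG_deoxy < self.Kd_BPG_oxy:
            raise ValueError("deoxy Kd values must be >= oxy values")
        if not (0.0 < self.ca_buffer_ratio <= 1.0):
            raise ValueError("ca_buffer_ratio must be in (0, 1]")


@dataclass
class PiezoParams:
    """PIEZO1 open-state per-species permeabilities (1/h) and gating."""

    PzNa: float = 0.0
    PzK: float = 0.0
    PzA: float = 50.0
    PzCa: float = 0.0
    PzMg: float = 0.0
    open: bool = False
    amplitude: float = 1.0


@dataclass
class TransportParams:
    """Permeabilities and pump/channel kinetic constants.

    Permeabilities in 1/h (1/h ~ 2e-8 cm/s); pump scales in mmol/Loch;
    affinities in mmol/Lcw. ``KMg`` is the [Mg2+]i half-activation of the
    Na pump (0.050 mmol/Lcw). ``pump_inhibition_factor`` scales the Na pump
    and implements the terminal (phase-3) inhibitory step.
    """

    PNa: float = 0.0
    PK: float = 0.0
    PA_ground: float = 1.3
    PCa_ground: float = 0.0
    piezo: PiezoParams = field(default_factory=PiezoParams)
    napump_Fmax: float = 0.0
    KmNa: float = 0.25
    KiK: float = 20.0
    KMg: float = 0.050
    pmca_Fmax: float = 36.0
    KmCa: float = 0.010
    gardos_PKmax: float = 32.0
    K05Ca: float = 3.2e-3
    hill: float = 3.5
    kcl_rate: float = 0.0
    pump_inhibition_factor: float = 1.0

    def __post_init__(self):
        for name in ("PNa", "PK", "PA_ground", "PCa_ground", "napump_Fmax",
                     "pmca_Fmax", "gardos_PKmax", "kcl_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.pump_inhibition_factor <= 1.0):
            raise ValueError("pump_inhibition_factor must be in (0, 1]")


@dataclass
class CellState:
    """Full homeostatic state of one cell at one time."""

    t: float           #: hours since circulatory emergence
    Vw: float          #: cell water, Lcw per Loc (reference cell ~0.75)
    QNa: float         #: mmol/Loc
    QK: float
    QA: float          #: lumped diffusible anion A- = Cl- + HCO3-
    QCaT: float        #: total cell calcium
    QMgT: float        #: total cell magnesium
    QHb: float         #: hemoglobin (impermeant, constant)
    QX: float          #: impermeant organic/inorganic phosphate pool
    pHi: float
    Em: float          #: mV
    CaF: float         #: free [Ca2+]i, mmol/Lcw
    MgF: float         #: free [Mg2+]i, mmol/Lcw
    oxy: bool = True

    def to_array(self) -> np.ndarray:
        s = np.empty(K.NSTATE)
        s[K.S_QNA] = self.QNa
        s[K.S_QK] = self.QK
        s[K.S_QA] = self.QA
        s[K.S_QCAT] = self.QCaT
        s[K.S_QMGT] = self.QMgT
        s[K.S_QHB] = self.QHb
        s[K.S_QX] = self.QX
        s[K.S_VW] = self.Vw
        s[K.S_PHI] = self.pHi
        s[K.S_EM] = self.Em
        s[K.S_CAF] = self.CaF
        s[K.S_MGF] = self.MgF
        s[K.S_OXY] = 1.0 if self.oxy else 0.0
        return s

    @classmethod
    def from_array(cls, s: np.ndarray, t: float = 0.0) -> "CellState":
        return cls(t=t, Vw=s[K.S_VW], QNa=s[K.S_QNA], QK=s[K.S_QK],
                   QA=s[K.S_QA], QCaT=s[K.S_QCAT], QMgT=s[K.S_QMGT],
                   QHb=s[K.S_QHB], QX=s[K.S_QX], pHi=s[K.S_PHI],
                   Em=s[K.S_EM], CaF=s[K.S_CAF], MgF=s[K.S_MGF],
                   oxy=s[K.S_OXY] > 0.5)

    def concentration(self, species: str) -> float:
        """Concentration Q/Vw (mmol/Lcw) of a content species."""
        return getattr(self, "Q" + species) / self.Vw


@dataclass
class ReferenceConfig:
    """Everything needed to construct the reference steady state.

    Reference composition values the source literature does not pin down
    (volume, Hb content, CNa/CK, trace resting Ca) are explicit calibration
    knobs here, none hard-coded.
    """

    medium: MediumState = field(default_factory=MediumState)
    hb: HbParams = field(default_factory=HbParams)
    buffers: BufferParams = field(default_factory=BufferParams)
    # intracellular reference composition
    CNa: float = 10.0       #: mmol/Lcw
    CK: float = 130.0
    CHb: float = 4.107      #: mmol/Lcw (low-Hb stress reticulocyte)
    pHi: float = 7.24
    Vw: float = 0.75        #: Lcw/Loc
    Vs: float = 0.25        #: osmotically inactive (solids) volume, L/Loc
    MgF: float = 0.40       #: resting free Mg, mmol/Lcw
    CaF: float = 6.0e-5     #: resting free Ca, mmol/Lcw (60 nmol/Lcw)
    # pump turnovers (stress reticulocyte: ~10x / ~40x mature values)
    na_pump_flux: float = 26.0   #: reference Na-pump flux, mmol/Loch
    pmca_Fmax: float = 36.0      #: PMCA maximal rate, mmol/Loch
    # kinetic constants
    KmNa: float = 0.25
    KiK: float = 20.0
    KMg: float = 0.050
    KmCa: float = 0.010
    gardos_PKmax: float = 32.0
    K05Ca: float = 3.2e-3
    hill: float = 3.5
    # permeabilities
    PA_ground: float = 1.3
    PzA: float = 50.0
    PzNa: float = 0.02
    PzK: float = 0.02
    PzMg: float = 0.02
    ca_ratio: float = 10.0  #: mean deoxy-PIEZO1 Ca influx / reference PMCA flux
    kcl_rate: float = 0.0

    def overridden(self, **kw) -> "ReferenceConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Reference:
    """Result of pump-leak construction: a self-consistent steady start."""

    cell: CellState
    transport: TransportParams
    medium: MediumState
    hb: HbParams
    buffers: BufferParams
    nX: float                 #: charge per X, Eq/mmol (fitted)
    Vs: float
    ref_na_pump_flux: float   #: mmol/Loch
    ref_ca_pump_flux: float   #: resting (pump-leak balanced) PMCA flux
    config: ReferenceConfig = None

    def params_array(self) -> np.ndarray:
        """Pack medium/Hb/buffer/transport parameters for the kernel."""
        p = np.zeros(K.NPAR)
        m, h, b, tp = self.medium, self.hb, self.buffers, self.transport
        p[K.I_CNAO], p[K.I_CKO], p[K.I_CAO] = m.CNao, m.CKo, m.CAo
        p[K.I_PHO], p[K.I_OSMO] = m.pHo, m.Osmo
        p[K.I_CAFO], p[K.I_MGFO] = m.CaO, m.MgO
        p[K.I_PI_OXY], p[K.I_PI_DEOXY] = h.pI_oxy, h.pI_deoxy
        p[K.I_ALPHA], p[K.I_B1], p[K.I_B2] = h.alpha, h.b1, h.b2
        p[K.I_ATP], p[K.I_BPG] = b.ATP_total, b.BPG_total
        p[K.I_KD_ATP_OXY], p[K.I_KD_ATP_DEOXY] = b.Kd_ATP_oxy, b.Kd_ATP_deoxy
        p[K.I_KD_BPG_OXY], p[K.I_KD_BPG_DEOXY] = b.Kd_BPG_oxy, b.Kd_BPG_deoxy
        p[K.I_CA_BUF] = b.ca_buffer_ratio
        p[K.I_PNA], p[K.I_PK] = tp.PNa, tp.PK
        p[K.I_PA], p[K.I_PCA] = tp.PA_ground, tp.PCa_ground
        pz = tp.piezo
        p[K.I_PZNA], p[K.I_PZK], p[K.I_PZA] = pz.PzNa, pz.PzK, pz.PzA
        p[K.I_PZCA], p[K.I_PZMG] = pz.PzCa, pz.PzMg
        p[K.I_NAP_FMAX], p[K.I_KM_NA] = tp.napump_Fmax, tp.KmNa
        p[K.I_KI_K], p[K.I_K_MG] = tp.KiK, tp.KMg
        p[K.I_PUMP_INH] = tp.pump_inhibition_factor
        p[K.I_PMCA_FMAX], p[K.I_KM_CA] = tp.pmca_Fmax, tp.KmCa
        p[K.I_GARDOS_PKMAX], p[K.I_K05CA] = tp.gardos_PKmax, tp.K05Ca
        p[K.I_HILL] = tp.hill
        p[K.I_KCL] = tp.kcl_rate
        p[K.I_NX] = self.nX
        p[K.I_VW0], p[K.I_VS] = self.config.Vw, self.Vs
        return p


def build_reference_state(config: ReferenceConfig | None = None) -> Reference:
    """Construct the oxygenated reference steady state by pump-leak balance.

    Every net flux (pump + leak per species) is zero by construction: ground
    Na/K/Ca leak permeabilities are back-computed from the specified pump
    turnovers, the Na-pump Fmax is scaled so the reference pump flux equals
    ``na_pump_flux``, the impermeant-pool content QX closes the osmotic
    balance and its charge nX closes electroneutrality. Em is the value at
    which the ground anion flux vanishes (equal to the anion Nernst potential
    EA when K:Cl cotransport is off), which together with per-species balance
    makes the state a zero-current point as well.

    Raises :class:`NoSteadyStateError`, naming the failing residual, if the
    requested composition admits no steady state.
    """
    cfg = config if config is not None else ReferenceConfig()
    m, h, b = cfg.medium, cfg.hb, cfg.buffers

    # Jacobs-Stewart equilibrium fixes the anion concentration from pHi
    CA0 = m.CAo * 10.0 ** (cfg.pHi - m.pHo)
    Vw0 = cfg.Vw
    QNa, QK, QA = cfg.CNa * Vw0, cfg.CK * Vw0, CA0 * Vw0
    QHb = cfg.CHb * Vw0
    QCaT = cfg.CaF * Vw0 / b.ca_buffer_ratio
    mg_bound = (b.ATP_total * cfg.MgF / (b.Kd_ATP_oxy + cfg.MgF)
                + b.BPG_total * cfg.MgF / (b.Kd_BPG_oxy + cfg.MgF))
    QMgT = (cfg.MgF + mg_bound) * Vw0

    # osmotic closure -> impermeant pool content
    fhb = K.hb_osmotic_coeff(cfg.CHb, h.b1, h.b2)
    CX0 = (m.Osmo - cfg.CNa - cfg.CK - CA0 - QCaT / Vw0 - QMgT / Vw0
           - fhb * cfg.CHb)
    if CX0 <= 0.0:
        raise NoSteadyStateError(
            "osmotic residual: intracellular osmolarity exceeds the medium "
            f"without any impermeant pool (required CX = {CX0:.3f})")
    QX = CX0 * Vw0

    # charge closure -> charge per X
    nHb0 = K.hb_charge(cfg.pHi, h.pI_oxy, h.alpha)
    nX = -(cfg.CNa + cfg.CK + 2.0 * (cfg.CaF + cfg.MgF) - CA0
           + nHb0 * cfg.CHb) / CX0
    if nX >= 0.0:
        raise NoSteadyStateError(
            "electroneutrality residual: the impermeant pool would need a "
            f"positive charge (nX = {nX:.3f}); reduce cation contents or "
            "raise the anion concentration")

    # membrane potential: ground anion flux (plus K:Cl) must vanish
    ea0 = -K.RTF * math.log(m.CAo / CA0)
    em0 = ea0
    if cfg.kcl_rate > 0.0:
        from scipy.optimize import brentq
        jkcl = K.kcl_cotransport(cfg.CK, CA0, m.CKo, m.CAo, cfg.kcl_rate)

        def a_balance(em):
            return -K.ghk_flux(cfg.PA_ground, -1.0, em, CA0, m.CAo) + jkcl

        em0 = brentq(a_balance, ea0 - 30.0, ea0 + 30.0, xtol=1e-12)
    else:
        jkcl = 0.0

    # Na pump Fmax from the requested reference flux
    x = cfg.CNa / (cfg.CNa + cfg.KmNa * (1.0 + cfg.CK / cfg.KiK))
    mg_fac = cfg.MgF / (cfg.MgF + cfg.KMg)
    denom = x ** 3 * mg_fac
    if denom <= 0.0:
        raise NoSteadyStateError("Na-pump activation is zero at reference")
    nap_fmax = cfg.na_pump_flux / denom

    # ground leaks back-computed to balance the pumps
    na_in_unit = -K.ghk_flux(1.0, 1.0, em0, cfg.CNa, m.CNao)
    if na_in_unit <= 0.0:
        raise NoSteadyStateError(
            "Na leak residual: no passive Na influx at the reference "
            "potential; pump cannot be balanced")
    PNa = cfg.na_pump_flux / na_in_unit

    k_eff_unit = K.ghk_flux(1.0, 1.0, em0, cfg.CK, m.CKo)
    if k_eff_unit <= 0.0:
        raise NoSteadyStateError(
            "K leak residual: no passive K efflux at the reference potential")
    pump_k_influx = cfg.na_pump_flux * 2.0 / 3.0
    pk_total = (pump_k_influx + jkcl) / k_eff_unit
    ch = cfg.CaF ** cfg.hill
    pkg0 = cfg.gardos_PKmax * ch / (ch + cfg.K05Ca ** cfg.hill)
    PK = pk_total - pkg0
    if PK <= 0.0:
        raise NoSteadyStateError(
            "K leak residual: resting Gardos leak already exceeds the pump "
            "K influx; lower gardos_PKmax or raise K05Ca")

    j_pmca0 = cfg.pmca_Fmax * cfg.CaF / (cfg.CaF + cfg.KmCa)
    ca_in_unit = -K.ghk_flux(1.0, 2.0, em0, cfg.CaF, m.CaO)
    if ca_in_unit <= 0.0:
        raise NoSteadyStateError("Ca leak residual: no passive Ca influx")
    PCa = j_pmca0 / ca_in_unit

    # PIEZO1 Ca permeability from the deoxy-influx / reference-PMCA ratio;
    # at the reference potential the unit influx is the same as the ground
    # pathway's, so the scaling is direct.
    PzCa = cfg.ca_ratio * PCa

    piezo = PiezoParams(PzNa=cfg.PzNa, PzK=cfg.PzK, PzA=cfg.PzA,
                        PzCa=PzCa, PzMg=cfg.PzMg)
    transport = TransportParams(
        PNa=PNa, PK=PK, PA_ground=cfg.PA_ground, PCa_ground=PCa, piezo=piezo,
        napump_Fmax=nap_fmax, KmNa=cfg.KmNa, KiK=cfg.KiK, KMg=cfg.KMg,
        pmca_Fmax=cfg.pmca_Fmax, KmCa=cfg.KmCa,
        gardos_PKmax=cfg.gardos_PKmax, K05Ca=cfg.K05Ca, hill=cfg.hill,
        kcl_rate=cfg.kcl_rate)

    cell = CellState(t=0.0, Vw=Vw0, QNa=QNa, QK=QK, QA=QA, QCaT=QCaT,
                     QMgT=QMgT, QHb=QHb, QX=QX, pHi=cfg.pHi, Em=em0,
                     CaF=cfg.CaF, MgF=cfg.MgF, oxy=True)
    ref = Reference(cell=cell, transport=transport, medium=m, hb=h,
                    buffers=b, nX=nX, Vs=cfg.Vs,
                    ref_na_pump_flux=cfg.na_pump_flux,
                    ref_ca_pump_flux=j_pmca0, config=cfg)
    _verify_reference(ref)
    return ref


def _verify_reference(ref: Reference, tol_flux: float = 1e-8) -> None:
    """Check the constructed state: per-species net fluxes ~ 0 and the
    equilibration invariants hold. Raises NoSteadyStateError otherwise."""
    p = ref.params_array()
    s = ref.cell.to_array()
    code = K.equilibrate(s, p)
    if code != 0:
        raise NoSteadyStateError(f"equilibration failed (code {code})")
    if abs(s[K.S_PHI] - ref.cell.pHi) > 1e-7 or \
            abs(s[K.S_VW] - ref.cell.Vw) > 1e-7:
        raise NoSteadyStateError(
            "equilibration residual: constructed (pHi, Vw) is not a "
            f"fixed point (pHi {s[K.S_PHI]:.6f} vs {ref.cell.pHi:.6f}, "
            f"Vw {s[K.S_VW]:.6f} vs {ref.cell.Vw:.6f})")
    fl = K.fluxes(s, p, False, 0.0)
    jna = fl[0] + fl[4] + fl[8]
    jk = fl[1] + fl[3] + fl[5] + fl[9] + fl[13]
    ja = fl[6] + fl[10] + fl[14]
    jca = fl[2] + fl[7] + fl[11]
    for name, j in (("Na", jna), ("K", jk), ("A", ja), ("Ca", jca)):
        if abs(j) > tol_flux:
            raise NoSteadyStateError(
                f"pump-leak residual: net {name} flux {j:.3e} mmol/Loch")
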