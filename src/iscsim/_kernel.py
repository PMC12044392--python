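"""Compiled numerical core.

All membrane flux laws, the fast algebraic equilibration (Jacobs-Stewart
proton/anion ratio, electroneutrality with the Dalmark hemoglobin charge,
osmotic water balance, Mg buffering) and the transit-by-transit time stepper
live here as scalar numba functions. The public modules (`equilibria`,
`transport`, `dynamics`) are thin wrappers over these functions, so there is
exactly one implementation of the physics.

State vector layout (float64, length NSTATE):
    QNA..QMGT  contents, mmol/Loc     QHB, QX  impermeant contents
    VW         cell water, Lcw/Loc    PHI      intracellular pH
    EM         membrane potential mV  CAF/MGF  free divalents, mmol/Lcw
    OXY        1.0 oxygenated / 0.0 deoxygenated

Parameter vector layout (float64, length NPAR): see the I_* index constants.
"""

import numpy as np
from numba import njit

RTF = 26.73          # RT/F at 37 C, mV
LN10 = 2.302585092994046

# ---- state vector indices -------------------------------------------------
S_QNA, S_QK, S_QA, S_QCAT, S_QMGT, S_QHB, S_QX = 0, 1, 2, 3, 4, 5, 6
S_VW, S_PHI, S_EM, S_CAF, S_MGF, S_OXY = 7, 8, 9, 10, 11, 12
NSTATE = 13

# ---- parameter vector indices ---------------------------------------------
I_CNAO, I_CKO, I_CAO, I_PHO, I_OSMO, I_CAFO, I_MGFO = 0, 1, 2, 3, 4, 5, 6
I_PI_OXY, I_PI_DEOXY, I_ALPHA, I_B1, I_B2 = 7, 8, 9, 10, 11
I_ATP, I_BPG = 12, 13
I_KD_ATP_OXY, I_KD_ATP_DEOXY, I_KD_BPG_OXY, I_KD_BPG_DEOXY = 14, 15, 16, 17
I_CA_BUF = 18
I_PNA, I_PK, I_PA, I_PCA = 19, 20, 21, 22
I_PZNA, I_PZK, I_PZA, I_PZCA, I_PZMG = 23, 24, 25, 26, 27
I_NAP_FMAX, I_KM_NA, I_KI_K, I_K_MG, I_PUMP_INH = 28, 29, 30, 31, 32
I_PMCA_FMAX, I_KM_CA = 33, 34
I_GARDOS_PKMAX, I_K05CA, I_HILL = 35, 36, 37
I_KCL = 38
I_NX = 39
I_VW0, I_VS = 40, 41
NPAR = 42

# ---- record column indices ------------------------------------------------
R_T, R_KIND, R_AMP = 0, 1, 2
R_VW, R_RELVOL, R_PHI, R_EM, R_EA, R_CAF, R_MGF = 3, 4, 5, 6, 7, 8, 9
R_QNA, R_QK, R_QA, R_QCAT, R_QMGT = 10, 11, 12, 13, 14
R_CNA, R_CK, R_CA, R_MGT = 15, 16, 17, 18
R_NHB, R_HBOSM, R_RA = 19, 20, 21
R_JNAP, R_JKP, R_JCAP, R_JKGARDOS = 22, 23, 24, 25
R_JNA_LEAK, R_JK_LEAK, R_JA_LEAK, R_JCA_LEAK = 26, 27, 28, 29
R_JNA_PZ, R_JK_PZ, R_JA_PZ, R_JCA_PZ, R_JMG_PZ = 30, 31, 32, 33, 34
R_JK_KCL, R_JA_KCL = 35, 36
NREC = 37

# ---- per-transit summary column indices -----------------------------------
T_START, T_END, T_KIND, T_AMP = 0, 1, 2, 3
T_VW, T_PHI, T_EM, T_RELVOL = 4, 5, 6, 7
T_JNAP_MIN, T_JNAP_MAX, T_JNAP_MEAN, T_JCAP_MEAN = 8, 9, 10, 11
T_MGF_MIN, T_MGT_MEAN, T_PHI_MIN, T_CAF_MEAN = 12, 13, 14, 15
NTR = 16


@njit(cache=False)
def ghk_flux(p, z, em, ci, co):
    """Constant-field (Goldman) flux, *efflux positive*, mmol/Loch.

    ``u = z*F*Em/RT``; the u -> 0 limit switches to a series expansion.
    """
    u = z * em / RTF
    if abs(u) < 1e-6:
        # u/(1-exp(-u)) = 1 + u/2 + u^2/12 + O(u^4)
        g = 1.0 + 0.5 * u + u * u / 12.0
        return p * g * (ci - co * (1.0 - u + 0.5 * u * u))
    eu = np.exp(-u)
    return p * u * (ci - co * eu) / (1.0 - eu)


@njit(cache=False)
def hb_charge(phi, pi, alpha):
    """Dalmark net charge on hemoglobin, Eq/mol: nHb = alpha*(pHi - pI)."""
    return alpha * (phi - pi)


@njit(cache=False)
def hb_osmotic_coeff(chb, b1, b2):
    """Osmotic (virial) coefficient of hemoglobin, fHb = 1 + b1*C + b2*C^2."""
    return 1.0 + b1 * chb + b2 * chb * chb


@njit(cache=False)
def mg_free(qmgt, vw, atp, bpg, kd_atp, kd_bpg, guess):
    """Free [Mg2+]i from 1:1 mass-action binding to ATP and 2,3-BPG.

    Solves  T = M + ATP*M/(Kd_ATP+M) + BPG*M/(Kd_BPG+M)  for M (mmol/Lcw),
    with T = QMgT/Vw. Newton iteration; the left side is strictly increasing
    in M so the positive root is unique.
    """
    t = qmgt / vw
    if t <= 0.0:
        return 0.0
    if atp <= 0.0 and bpg <= 0.0:
        return t
    m = guess
    if m <= 0.0 or m > t:
        m = t * 0.2
    for _ in range(60):
        fa = atp * m / (kd_atp + m)
        fb = bpg * m / (kd_bpg + m)
        f = m + fa + fb - t
        if abs(f) < 1e-13:
            break
        df = 1.0 + atp * kd_atp / ((kd_atp + m) ** 2) \
            + bpg * kd_bpg / ((kd_bpg + m) ** 2)
        step = f / df
        m -= step
        if m <= 0.0:
            m = 1e-12
    return m


@njit(cache=False)
def _solve_vw(qs, cai, qhb, b1, b2, osmo, guess):
    """Water volume from osmotic equality at fixed diffusible-anion conc.

    Solves Qs/Vw + CAi + fHb(CHb)*CHb = Osmo for Vw; the left side is
    strictly decreasing in Vw, so the root is unique. Returns -1.0 when the
    medium osmolarity cannot be met (CAi alone exceeds Osmo).
    """
    rhs = osmo - cai
    if rhs <= 0.0:
        return -1.0
    vw = guess
    if vw <= 0.0:
        vw = 1.0
    for _ in range(80):
        chb = qhb / vw
        fhb = 1.0 + b1 * chb + b2 * chb * chb
        f = qs / vw + fhb * chb - rhs
        if abs(f) < 1e-12:
            break
        dchb = -chb / vw
        df = -qs / (vw * vw) + (1.0 + 2.0 * b1 * chb + 3.0 * b2 * chb * chb) * dchb
        vw_new = vw - f / df
        if vw_new <= 0.02:
            vw_new = 0.5 * vw
        vw = vw_new
    return vw


@njit(cache=False)
def equilibrate(s, p):
    """Instantaneous fast equilibration at fixed slow contents.

    Finds the unique (pHi, Vw, QA) satisfying simultaneously

    1. Jacobs-Stewart equality rH = rA, i.e. CAi = CAo*10**(pHi-pHo)
       (the anion exchanger + CO2 shunt move H+ and A- together, so QA is
       shifted while total cation contents stay fixed);
    2. electroneutrality with the Dalmark hemoglobin charge and fixed nX;
    3. osmotic equality including the hemoglobin virial term fHb*CHb.

    Updates VW, PHI, QA, CAF, MGF in place. Returns 0 on success, an error
    code otherwise (1: no osmotic solution / anion depletion, 2: no pH
    bracket).
    """
    oxy = s[S_OXY] > 0.5
    pi = p[I_PI_OXY] if oxy else p[I_PI_DEOXY]
    kd_atp = p[I_KD_ATP_OXY] if oxy else p[I_KD_ATP_DEOXY]
    kd_bpg = p[I_KD_BPG_OXY] if oxy else p[I_KD_BPG_DEOXY]
    qs = s[S_QNA] + s[S_QK] + s[S_QCAT] + s[S_QMGT] + s[S_QX]
    qhb = s[S_QHB]
    cao = p[I_CAO]
    pho = p[I_PHO]

    phi = s[S_PHI]
    if phi < 5.0 or phi > 9.0:
        phi = 7.2
    vw_guess = s[S_VW]
    mg_guess = s[S_MGF]

    lo = 4.5
    hi = 9.5
    r_prev = 0.0
    phi_prev = -1.0
    vw = -1.0
    mgf = 0.0
    caf = 0.0
    cai = 0.0
    ok = False
    for it in range(200):
        cai = cao * 10.0 ** (phi - pho)
        vw = _solve_vw(qs, cai, qhb, p[I_B1], p[I_B2], p[I_OSMO], vw_guess)
        if vw <= 0.0:
            # anion concentration alone exceeds medium osmolarity: pHi is
            # too high for any water balance -> shrink the bracket from above
            hi = phi
            if hi - lo < 1e-12:
                return 1
            phi = 0.5 * (lo + hi)
            phi_prev = -1.0
            continue
        mgf = mg_free(s[S_QMGT], vw, p[I_ATP], p[I_BPG], kd_atp, kd_bpg,
                      mg_guess)
        caf = p[I_CA_BUF] * s[S_QCAT] / vw
        nhb = p[I_ALPHA] * (phi - pi)
        # electroneutrality residual, mEq/Loc
        r = (s[S_QNA] + s[S_QK] + 2.0 * (caf + mgf) * vw - cai * vw
             + nhb * qhb + p[I_NX] * s[S_QX])
        if abs(r) < 1e-10:
            ok = True
            break
        # R is strictly decreasing in pHi: shrink the bracket
        if r > 0.0:
            lo = phi
        else:
            hi = phi
        # Newton step with the dominant-derivative approximation
        dr = -(LN10 * cai * vw) + p[I_ALPHA] * qhb
        if phi_prev > 0.0 and abs(phi - phi_prev) > 1e-14:
            dr_sec = (r - r_prev) / (phi - phi_prev)
            if dr_sec < 0.0:
                dr = dr_sec
        phi_prev = phi
        r_prev = r
        phi_new = phi - r / dr
        if phi_new <= lo or phi_new >= hi:
            phi_new = 0.5 * (lo + hi)
        phi = phi_new
        vw_guess = vw
        mg_guess = mgf
    if not ok:
        return 2
    s[S_PHI] = phi
    s[S_VW] = vw
    s[S_QA] = cai * vw
    s[S_CAF] = caf
    s[S_MGF] = mgf
    return 0


@njit(cache=False)
def na_pump(cna, ck, mgf, p):
    """Na/K pump fluxes (JNa, JK), mmol/Loch, efflux negative.

    Cubic Na-site kinetics with competitive intracellular-K inhibition of the
    apparent Na affinity, saturable [Mg2+]i activation (half-maximal at
    KMg = 0.050 mmol/Lcw), 3:2 Na:K stoichiometry, scaled by the
    pump-inhibition factor used to trigger terminal rehydration.
    """
    if cna <= 0.0:
        return 0.0, 0.0
    km_app = p[I_KM_NA] * (1.0 + ck / p[I_KI_K])
    x = cna / (cna + km_app)
    mg_fac = mgf / (mgf + p[I_K_MG]) if mgf > 0.0 else 0.0
    jna = -p[I_NAP_FMAX] * p[I_PUMP_INH] * x * x * x * mg_fac
    return jna, -(2.0 / 3.0) * jna


@njit(cache=False)
def pmca(caf, p):
    """Plasma-membrane Ca pump flux, mmol/Loch, efflux negative."""
    if caf <= 0.0:
        return 0.0
    return -p[I_PMCA_FMAX] * caf / (caf + p[I_KM_CA])


@njit(cache=False)
def gardos_pk(caf, p):
    """Ca-activated (Gardos) K permeability, 1/h, Hill activation."""
    if caf <= 0.0:
        return 0.0
    ch = caf ** p[I_HILL]
    kh = p[I_K05CA] ** p[I_HILL]
    return p[I_GARDOS_PKMAX] * ch / (ch + kh)


@njit(cache=False)
def kcl_cotransport(ck, ca, cko, cao, rate):
    """K:Cl cotransport, equal K and A efflux, product-gradient driven."""
    if rate <= 0.0:
        return 0.0
    return -rate * (ck * ca - cko * cao) * 1e-3


@njit(cache=False)
def fluxes(s, p, piezo_open, amp):
    """All pathway fluxes at the current state. Influx positive.

    Returns a length-15 vector:
    [jna_pump, jk_pump, jca_pump, jk_gardos,
     jna_leak, jk_leak, ja_leak, jca_leak,
     jna_pz, jk_pz, ja_pz, jca_pz, jmg_pz, jk_kcl, ja_kcl]
    """
    out = np.zeros(15)
    vw = s[S_VW]
    em = s[S_EM]
    cna = s[S_QNA] / vw
    ck = s[S_QK] / vw
    ca = s[S_QA] / vw
    caf = s[S_CAF]
    mgf = s[S_MGF]

    jnap, jkp = na_pump(cna, ck, mgf, p)
    out[0] = jnap
    out[1] = jkp
    out[2] = pmca(caf, p)
    pkg = gardos_pk(caf, p)
    out[3] = -ghk_flux(pkg, 1.0, em, ck, p[I_CKO])

    out[4] = -ghk_flux(p[I_PNA], 1.0, em, cna, p[I_CNAO])
    out[5] = -ghk_flux(p[I_PK], 1.0, em, ck, p[I_CKO])
    out[6] = -ghk_flux(p[I_PA], -1.0, em, ca, p[I_CAO])
    out[7] = -ghk_flux(p[I_PCA], 2.0, em, caf, p[I_CAFO])

    if piezo_open:
        out[8] = -ghk_flux(amp * p[I_PZNA], 1.0, em, cna, p[I_CNAO])
        out[9] = -ghk_flux(amp * p[I_PZK], 1.0, em, ck, p[I_CKO])
        out[10] = -ghk_flux(amp * p[I_PZA], -1.0, em, ca, p[I_CAO])
        out[11] = -ghk_flux(amp * p[I_PZCA], 2.0, em, caf, p[I_CAFO])
        out[12] = -ghk_flux(amp * p[I_PZMG], 2.0, em, mgf, p[I_MGFO])

    jkcl = kcl_cotransport(ck, ca, p[I_CKO], p[I_CAO], p[I_KCL])
    out[13] = jkcl
    out[14] = jkcl
    return out


@njit(cache=False)
def net_current(s, p, piezo_open, amp, em):
    """Net transmembrane charge influx (mEq/Loch) at potential ``em``.

    Electrodiffusive pathways (ground + PIEZO1 + Gardos) plus the electrogenic
    pumps (3Na:2K, so 1/3 of the pump Na flux; PMCA exports 2+ per cycle).
    The Jacobs-Stewart shunt and K:Cl cotransport are electroneutral.
    """
    vw = s[S_VW]
    cna = s[S_QNA] / vw
    ck = s[S_QK] / vw
    ca = s[S_QA] / vw
    caf = s[S_CAF]
    mgf = s[S_MGF]

    pna = p[I_PNA]
    pk = p[I_PK] + gardos_pk(caf, p)
    pa = p[I_PA]
    pca = p[I_PCA]
    pmg = 0.0
    if piezo_open:
        pna += amp * p[I_PZNA]
        pk += amp * p[I_PZK]
        pa += amp * p[I_PZA]
        pca += amp * p[I_PZCA]
        pmg += amp * p[I_PZMG]

    i = 0.0
    i += -ghk_flux(pna, 1.0, em, cna, p[I_CNAO])
    i += -ghk_flux(pk, 1.0, em, ck, p[I_CKO])
    i -= -ghk_flux(pa, -1.0, em, ca, p[I_CAO])
    i += 2.0 * (-ghk_flux(pca, 2.0, em, caf, p[I_CAFO]))
    if pmg > 0.0:
        i += 2.0 * (-ghk_flux(pmg, 2.0, em, mgf, p[I_MGFO]))

    jnap, jkp = na_pump(cna, ck, mgf, p)
    jcap = pmca(caf, p)
    i += jnap + jkp + 2.0 * jcap
    return i


@njit(cache=False)
def solve_em(s, p, piezo_open, amp):
    """Membrane potential from zero net transmembrane current.

    The current is strictly decreasing in Em, so the root is unique; secant
    iteration warm-started from the stored Em, with bisection fallback.
    """
    em0 = s[S_EM]
    if em0 < -180.0 or em0 > 80.0:
        em0 = -10.0
    e1 = em0
    f1 = net_current(s, p, piezo_open, amp, e1)
    e2 = em0 + (1.0 if f1 > 0.0 else -1.0)
    f2 = net_current(s, p, piezo_open, amp, e2)
    for _ in range(60):
        if abs(f2) < 1e-11:
            return e2
        if abs(f2 - f1) < 1e-300:
            break
        e3 = e2 - f2 * (e2 - e1) / (f2 - f1)
        if e3 < -250.0 or e3 > 150.0:
            break
        e1, f1 = e2, f2
        e2 = e3
        f2 = net_current(s, p, piezo_open, amp, e2)
    # bisection fallback
    lo, hi = -250.0, 150.0
    flo = net_current(s, p, piezo_open, amp, lo)
    if flo < 0.0:
        return lo
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = net_current(s, p, piezo_open, amp, mid)
        if abs(fm) < 1e-11 or hi - lo < 1e-13:
            return mid
        if fm > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@njit(cache=False)
def _record(rec, k, t_h, kind, amp, s, p, fl):
    vw = s[S_VW]
    rec[k, R_T] = t_h
    rec[k, R_KIND] = kind
    rec[k, R_AMP] = amp
    rec[k, R_VW] = vw
    rec[k, R_RELVOL] = (vw + p[I_VS]) / (p[I_VW0] + p[I_VS])
    rec[k, R_PHI] = s[S_PHI]
    rec[k, R_EM] = s[S_EM]
    ra = p[I_CAO] / (s[S_QA] / vw)
    rec[k, R_EA] = -RTF * np.log(ra)
    rec[k, R_CAF] = s[S_CAF]
    rec[k, R_MGF] = s[S_MGF]
    rec[k, R_QNA] = s[S_QNA]
    rec[k, R_QK] = s[S_QK]
    rec[k, R_QA] = s[S_QA]
    rec[k, R_QCAT] = s[S_QCAT]
    rec[k, R_QMGT] = s[S_QMGT]
    rec[k, R_CNA] = s[S_QNA] / vw
    rec[k, R_CK] = s[S_QK] / vw
    rec[k, R_CA] = s[S_QA] / vw
    rec[k, R_MGT] = s[S_QMGT] / vw
    oxy = s[S_OXY] > 0.5
    pi = p[I_PI_OXY] if oxy else p[I_PI_DEOXY]
    rec[k, R_NHB] = p[I_ALPHA] * (s[S_PHI] - pi)
    chb = s[S_QHB] / vw
    rec[k, R_HBOSM] = hb_osmotic_coeff(chb, p[I_B1], p[I_B2]) * chb
    rec[k, R_RA] = ra
    for j in range(15):
        rec[k, R_JNAP + j] = fl[j]


@njit(cache=False)
def run_schedule(s, p, kinds, durs, amps, ev_times, ev_idx, ev_vals,
                 dt_max, rec_dt):
    """Advance the cell through an ordered transit schedule.

    ``kinds``: 0 oxy, 1 deoxy, 2 lingering-deoxy; ``durs`` seconds;
    ``amps`` PIEZO1 amplitude factors (used for deoxy kinds only).
    ``ev_*``: sorted parameter-change events (time h, parameter index, value).

    Returns (records, n_rec, transits, err): full-resolution records at
    ``rec_dt`` cadence plus transit boundaries, and per-transit time-weighted
    summaries. err != 0 flags an integration failure (negative contents at
    the minimum step size or equilibration failure).
    """
    n_tr = kinds.shape[0]
    total_s = 0.0
    for i in range(n_tr):
        total_s += durs[i]
    n_rec_max = int(total_s / rec_dt) + n_tr + 16
    rec = np.zeros((n_rec_max, NREC))
    trs = np.zeros((n_tr, NTR))

    t = 0.0              # seconds
    k = 0                # record counter
    next_rec = 0.0
    ev_ptr = 0
    n_ev = ev_times.shape[0]
    err = 0

    # initial equilibration + potential
    e = equilibrate(s, p)
    if e != 0:
        return rec, 0, trs, 10 + e
    s[S_EM] = solve_em(s, p, False, 0.0)
    fl0 = fluxes(s, p, False, 0.0)
    _record(rec, k, 0.0, 0.0, 0.0, s, p, fl0)
    k += 1
    next_rec = rec_dt

    for i in range(n_tr):
        kind = kinds[i]
        amp = amps[i]
        piezo_open = kind != 0
        oxy_new = 1.0 if kind == 0 else 0.0
        if s[S_OXY] != oxy_new:
            s[S_OXY] = oxy_new
            e = equilibrate(s, p)     # pI / Mg-buffer switch
            if e != 0:
                err = 10 + e
                break
            s[S_EM] = solve_em(s, p, piezo_open, amp)
        t_end = t + durs[i]
        trs[i, T_START] = t / 3600.0
        trs[i, T_END] = t_end / 3600.0
        trs[i, T_KIND] = kind
        trs[i, T_AMP] = amp if piezo_open else 0.0
        w_sum = 0.0
        vw_acc = 0.0
        phi_acc = 0.0
        em_acc = 0.0
        jnap_acc = 0.0
        jcap_acc = 0.0
        mgt_acc = 0.0
        caf_acc = 0.0
        jnap_min = 1e300
        jnap_max = -1e300
        mgf_min = 1e300
        phi_min = 1e300

        while t < t_end - 1e-9:
            dt = dt_max
            if t + dt > t_end:
                dt = t_end - t
            if ev_ptr < n_ev and t / 3600.0 < ev_times[ev_ptr] \
                    and (t + dt) / 3600.0 > ev_times[ev_ptr]:
                dt = ev_times[ev_ptr] * 3600.0 - t
            if ev_ptr < n_ev and t / 3600.0 >= ev_times[ev_ptr] - 1e-12:
                p[ev_idx[ev_ptr]] = ev_vals[ev_ptr]
                ev_ptr += 1

            fl = fluxes(s, p, piezo_open, amp)
            jna = fl[0] + fl[4] + fl[8]
            jk = fl[1] + fl[3] + fl[5] + fl[9] + fl[13]
            ja = fl[6] + fl[10] + fl[14]
            jca = fl[2] + fl[7] + fl[11]
            jmg = fl[12]
            # adaptive halving on loss of positivity
            ok_step = False
            for _ in range(16):
                dtau = dt / 3600.0
                qna = s[S_QNA] + jna * dtau
                qk = s[S_QK] + jk * dtau
                qa = s[S_QA] + ja * dtau
                qcat = s[S_QCAT] + jca * dtau
                qmgt = s[S_QMGT] + jmg * dtau
                if qna > 0.0 and qk > 0.0 and qa > 0.0 and qcat >= 0.0 \
                        and qmgt >= 0.0:
                    ok_step = True
                    break
                dt *= 0.5
                if dt < 1e-3:
                    break
            if not ok_step:
                err = 1
                break
            s[S_QNA] = qna
            s[S_QK] = qk
            s[S_QA] = qa
            s[S_QCAT] = qcat
            s[S_QMGT] = qmgt
            e = equilibrate(s, p)
            if e != 0:
                err = 10 + e
                break
            s[S_EM] = solve_em(s, p, piezo_open, amp)
            t += dt

            w = dt
            w_sum += w
            vw_acc += w * s[S_VW]
            phi_acc += w * s[S_PHI]
            em_acc += w * s[S_EM]
            jnap_acc += w * fl[0]
            jcap_acc += w * fl[2]
            mgt_acc += w * s[S_QMGT]
            caf_acc += w * s[S_CAF]
            if fl[0] < jnap_min:
                jnap_min = fl[0]
            if fl[0] > jnap_max:
                jnap_max = fl[0]
            if s[S_MGF] < mgf_min:
                mgf_min = s[S_MGF]
            if s[S_PHI] < phi_min:
                phi_min = s[S_PHI]

            if t >= next_rec - 1e-9 and k < n_rec_max:
                _record(rec, k, t / 3600.0, kind, amp if piezo_open else 0.0,
                        s, p, fl)
                k += 1
                while next_rec <= t + 1e-9:
                    next_rec += rec_dt
        if err != 0:
            break
        if w_sum > 0.0:
            trs[i, T_VW] = vw_acc / w_sum
            trs[i, T_PHI] = phi_acc / w_sum
            trs[i, T_EM] = em_acc / w_sum
            trs[i, T_RELVOL] = (vw_acc / w_sum + p[I_VS]) / (p[I_VW0] + p[I_VS])
            trs[i, T_JNAP_MIN] = jnap_min
            trs[i, T_JNAP_MAX] = jnap_max
            trs[i, T_JNAP_MEAN] = jnap_acc / w_sum
            trs[i, T_JCAP_MEAN] = jcap_acc / w_sum
            trs[i, T_MGF_MIN] = mgf_min
            trs[i, T_MGT_MEAN] = mgt_acc / w_sum
            trs[i, T_PHI_MIN] = phi_min
            trs[i, T_CAF_MEAN] = caf_acc / w_sum
        # boundary record (skip if a cadence record just landed here)
        if k < n_rec_max and (k == 0 or t / 3600.0 - rec[k - 1, R_T] > 1e-12):
            fl = fluxes(s, p, piezo_open, amp)
            _record(rec, k, t / 3600.0, kind, amp if piezo_open else 0.0,
                    s, p, fl)
            k += 1
    return rec, k, trs, err
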