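# Model and methods

## Scope and structure

`iscsim` simulates the ion and water homeostasis of a single red blood cell —
specifically an ISC-destined stress reticulocyte — against an infinite,
constant plasma reservoir at 37 °C, driven by a stochastic schedule of
oxygenated (arterial) and deoxygenated (venous) inter-capillary transits.
The model separates time scales by operator splitting:

* **Slow contents** Q(Na), Q(K), Q(A), Q(CaT), Q(MgT) (mmol per liter of
  original cells, Loc) change through membrane fluxes, integrated explicitly
  with 1-s steps during transits (halved adaptively if a step would drive a
  content negative).
* **Fast equilibria** relax within fractions of a second and are re-solved
  algebraically after every step: Jacobs-Stewart proton/anion ratio equality,
  osmotic water balance, electroneutrality, cytosolic Ca/Mg buffering, and
  the zero-current membrane potential.

Hemoglobin (QHb) and a lumped impermeant organic/inorganic phosphate pool
(QX) are conserved exactly. The two diffusible anions are lumped,
A⁻ = Cl⁻ + HCO₃⁻.

## Fast equilibria

At fixed cation and divalent contents, the equilibration finds the unique
(pHi, Vw, QA) satisfying simultaneously

1. **Jacobs-Stewart equality** rH = rA, with rH = [H⁺]ᵢ/[H⁺]ₒ and
   rA = CAo/CAi. The anion exchanger plus the CO₂ shunt move H⁺ and A⁻
   together (electroneutrally), so QA shifts while cation contents stay
   fixed; equivalently CAi = CAo·10^(pHi − pHo).
2. **Electroneutrality** CNa + CK + 2[Ca²⁺]ᵢ + 2[Mg²⁺]ᵢ − CA + nHb·CHb +
   nX·CX = 0, with the Dalmark hemoglobin charge nHb = α(pHi − pI),
   α = −8 Eq/(mol·pH) for HbS. The sign convention makes nHb positive below
   the isoelectric point, so the acidified ISC carries a slightly positive
   hemoglobin charge. Deoxygenation switches pI from 7.20 (oxy, a
   calibration default) to 7.40 (deoxy HbS at 37 °C). nX is fitted once at
   the reference state to close electroneutrality and then held fixed
   (X titration is not modeled; [X⁻] varies only through Vw).
3. **Osmotic balance** (ΣQ)/Vw + fHb(CHb)·CHb = plasma osmolarity, with the
   hemoglobin osmotic coefficient fHb = 1 + b1·CHb + b2·CHb²
   (b1 = 0.0645 Lcw/mmol, b2 = 0.0258 (Lcw/mmol)², the standard virial fit).
   This convex term is the colloid-osmotic nonlinearity that dominates the
   late collapse.

The solver is a safeguarded Newton iteration on pHi with an inner Newton
solve for Vw (both warm-started between steps); electroneutrality and osmotic
residuals converge below 1e−10 and rH = rA holds to machine precision. It is
idempotent and, on perturbed states, reaches a smaller joint residual than a
surrounding brute-force grid (tested).

Free Mg²⁺ solves 1:1 mass-action binding to ATP (1.8 mmol/Lcw) and 2,3-BPG
(7.0 mmol/Lcw); deoxygenation raises the effective dissociation constants
(0.08→0.14 and 3.0→5.5 mmol/Lcw), representing deoxy-Hb sequestration of the
nucleotides and releasing Mg²⁺ in deoxy transits. Free Ca²⁺ uses a linear
buffer (free/total 0.2); organelle/vacuolar Ca accumulation is deliberately
out of scope.

**Membrane potential.** Em is the zero of the net transmembrane current:
Goldman currents of Na⁺, K⁺ (ground + Gardos + PIEZO1), A⁻, Ca²⁺, Mg²⁺ plus
the electrogenic pumps — the 3Na:2K pump exports one charge per three Na, and
the PMCA is treated as fully electrogenic (2+ out per cycle). The
electrogenic-PMCA choice is what lets the reference state be simultaneously
a per-species steady state and a zero-current state with a silent
Jacobs-Stewart shunt; with an electroneutral Ca/2H exchanger a standing
proton backflux would preclude a true steady start. With the anion pathway
dominating the membrane conductance, Em tracks EA = −(RT/F)·ln rA to well
under 1 mV near the reference state; the gap widens (up to ~15 mV,
cation-ward) only transiently during the collapse when the Gardos
conductance rivals the anion conductance.

## Membrane transport laws

* **Ground leaks**: constant-field (Goldman) fluxes,
  J = P·u·(Ci − Co·e^(−u))/(1 − e^(−u)), u = zF·Em/RT, with a series
  expansion below |u| = 1e−6. 1 h⁻¹ ≈ 2×10⁻⁸ cm/s.
* **Na/K pump**: JNa = −Fmax·inh·[CNa/(CNa + KmNa(1 + CK/KiK))]³·
  MgF/(MgF + KMg); JK = −(2/3)·JNa exactly. KmNa = 0.25 and KiK = 20
  mmol/Lcw place the reference state (CNa 10, CK 130) at ~53% of the
  Mg-saturated maximum, so that phase 2 — where K depletion has relieved the
  competitive inhibition — runs the pump near saturation at the −45
  mmol/Loch scale needed to balance the hyperpolarization-amplified Na
  influx. KMg = 0.050 mmol/Lcw is the measured half-activation; `inh` is the
  terminal inhibition factor (1 until the phase-3 event).
* **PMCA**: J = −Fmax·CaF/(CaF + KmCa), Fmax = 36 mmol/Loch (the
  stress-reticulocyte scale, ~40-fold the mature value), KmCa = 0.010
  mmol/Lcw. The resting pump-leak balanced Ca turnover is then ~0.2
  mmol/Loch at the 60 nmol/Lcw resting free Ca.
* **Gardos channel**: PK,G = PKmax·CaF^h/(CaF^h + K05^h), fed into the
  Goldman K flux. Defaults PKmax = 32 h⁻¹, K05 = 3.2 µmol/Lcw, h = 3.5: the
  midpoint sits ~5-fold above the deoxy free-Ca plateau of the fresh cell,
  so activation starts near zero and grows steeply as hyperpolarization
  raises the deoxy Ca influx — the feedback that shapes the accelerating
  phase-1 collapse and then holds the K-depleted phase 2 against the pump's
  K backflux. A steeper-than-literature Hill coefficient (3.5 vs the ~2
  usually quoted for KCNN4) is required for that dynamic range; with h ≤ 3
  the model either stalls short of hyperdensity or collapses almost
  instantly.
* **PIEZO1 (deoxy-activated, "Psickle")**: deoxygenation is necessary and
  sufficient to open the channel for the whole transit; reoxygenation closes
  it instantly. Open-state permeabilities: PzA = 50 h⁻¹ (the published
  default deoxy anion permeability; ground PA = 1.3 h⁻¹), PzCa is derived at
  build time so the mean-amplitude deoxy Ca influx is `ca_ratio` (= 10)
  times the resting PMCA flux, PzNa = PzK = 0.02 h⁻¹ and PzMg = 0.02 h⁻¹
  (calibrated; see below). Each deoxy transit scales all five by its random
  amplitude factor.
* **K:Cl cotransport** (off by default): electroneutral, proportional to
  CK·CA − CKo·CAo. At a magnitude that moves ~1 mmol/Loch at reference it
  changes the collapse time by well under 5% — consistent with its
  negligible role in fast ISC dehydration.

## Reference state by pump-leak construction

The builder takes the medium (Na 140, K 5, A 125 mmol/L, pH 7.40, free Ca
1.2, free Mg 0.5, 290 mOsm/L), the intracellular composition (CNa 10, CK 130
mmol/Lcw, CHb 4.107 mmol/Lcw, pHi 7.24, Vw 0.75 Lcw/Loc, solids 0.25 L/Loc,
free Mg 0.40 mmol/Lcw, free Ca 60 nmol/Lcw) and the pump turnovers (Na pump
flux 26 mmol/Loch, PMCA Fmax 36 mmol/Loch), then:

1. fixes CA from the Jacobs-Stewart equality and Em from the vanishing of
   the ground anion flux (= EA when K:Cl is off);
2. closes the osmotic balance with QX and electroneutrality with nX;
3. scales the pump Fmax so the reference Na-pump flux is exactly 26, and
   back-computes PNa, PK, PCa so leaks cancel pumps per species (the K
   budget nets out the resting Gardos leak).

Every net flux is zero to < 1e−8 mmol/Loch and the state is an exact fixed
point of the integrator (zero drift over 24 h with channels closed).
Unsatisfiable requests raise an error naming the failing residual.

The composition defaults are calibration choices for the ISC-destined stress
reticulocyte, which the literature does not pin down: macrocytic (water
volume 0.75 Lcw/Loc), hemoglobin-poor (CHb 4.1 mmol/Lcw ≈ 60% of a normal
cell, chosen with the virials so the reference fHb·CHb ≈ 7 mOsmol/Lcw),
reference pHi 7.24 (slightly above the usual 7.2; together with CHb it sets
the impermeant pool QX ≈ 41 mmol/Loc and nX ≈ −1.0, which in turn set the
depth of the hyperdense collapse — the trough fHb·CHb ≈ 45 mOsmol/Lcw).
All are config fields; none are hard-coded.

## The stochastic circulation (what the generator emulates)

Oxy and deoxy transits alternate with uniform durations (oxy 30-60 s, deoxy
30-90 s) and i.i.d. uniform PIEZO1 amplitudes on [0.25, 1.75] (mean 1,
enforced), drawn from two independent substreams of one seed so either
randomness source can be frozen. Lingering episodes replace the concurrent
deoxy transit with a 40-min deoxy stay. The last transit is truncated so
durations sum exactly to the protocol length. This emulates the *statistics*
of circulatory exposure — binary oxygenation, random channel-fraction
opening, variable transit times. It does not emulate oxygen-tension continua,
vascular geometry, shear-dependent PIEZO1 gating, or cell-to-cell parameter
heterogeneity; passing tests therefore certify the homeostatic machinery
under the assumed exposure statistics, not those statistics themselves.

## The typical 5-day ISC protocol

Reference as above; deoxy-PA 50 h⁻¹; Ca-influx/PMCA ratio 10; lingering at
0.5, 1.1 and 3.5 days; a single sudden Na-pump inhibitory step at day 4 with
factor 0.22, calibrated so the settled phase-3 pump flux lands at −10
mmol/Loch (the event time is the published choice of an "arbitrary" point in
phase 2; the kinetics of pump decline are unknown, and a multi-step ramp is
supported). Phase detection works on transit-averaged traces smoothed over
one oxy+deoxy cycle; the trough is the earliest entry into the band within
0.005 of the minimum cycle-averaged relative volume (an argmin would land
anywhere on the noisy phase-2 plateau), and "collapse" requires relative
volume < 0.7. The phase-2 pump-flux envelope is summarized by the 5th/95th
percentiles of per-transit extrema; the ATP turnover ratio is
time-averaged (|JNa|/3 + |JCa|) over phase 2 against the mature baseline
(reference pump fluxes divided by 10 and 40), computed from per-transit
means so it is independent of the output cadence.

## Numerical choices

dt = 1 s during transits (first-order splitting; halving dt changes
end-of-minute variables by < 1e−4 relative), adaptive halving to 1 ms on
positivity loss, records once per minute plus transit boundaries. CSVs are
written at 17 significant digits and re-read bit-exactly; identical seeds
give byte-identical files. The stepping kernel is numba-compiled; all unit
operations are plain callable functions shared between the kernel and the
public API. Degenerate inputs (zero contents, zero permeabilities,
amplitude 0) fall on analytic branches; the Goldman u→0 limit uses a series
expansion.

## Known limitations

* **Collapse timing.** With the calibrated defaults the hyperdense collapse
  completes within ~3-8 h of circulation rather than ~1 day. The phase-2
  state (pH ≈ 6.65, fHb·CHb ≈ 46, settled −10 mmol/Loch, ATP ratio ≈ 21) is
  reproduced quantitatively, but with Goldman ground leaks the phase-2 Na
  influx — and hence the pump's 2/3 K backflux — is amplified by
  hyperpolarization to ~+30 mmol/Loch, and the only Gardos regimes that can
  both outrun that backflux and finish the K depletion are fast ones.
* **Anion-permeability rate limitation.** For the same reason the model does
  not reproduce the expected slower *dehydration* at deoxy-PA = 1.3 h⁻¹:
  with a low anion permeability the deoxy membrane potential dips a few mV
  below EA, and the cooperative Gardos activation amplifies the resulting
  extra Ca influx more than the anion-flux choke slows KCl loss, so the
  ordering of collapse times inverts. The *rehydration* rate ordering
  (slowest at PA 1.3) is reproduced. This is an intrinsic consequence of the
  threshold-growth Gardos calibration plus constant-field leaks, and is the
  one phase-1 signature we could not recover in any explored regime.
* Phase-2 pump-flux oscillations span roughly −40 to −50 mmol/Loch rather
  than the wider −50…−15 band: with the pump near Na saturation in phase 2,
  per-transit Na and Mg swings modulate it only weakly.
* No HbS polymerization kinetics, no vacuolar calcium, no separate Cl⁻/HCO₃⁻
  speciation, no ATP bookkeeping (metabolic competence is assumed), single
  cell only (ensembles by looping over seeds).
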