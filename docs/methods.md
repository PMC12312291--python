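# Model and methods

## Scope and state variables

`oscifluor` simulates the normalized chlorophyll fluorescence yield
ChlF(t) = F′(t)/F_M of a leaf driven by harmonically oscillating actinic
light, using a deliberately low-dimensional kinetic model of linear
electron transport with two-component qE regulation.  Six ordinary
differential equations track

| variable | meaning | units / range |
|---|---|---|
| `PQ_ox` | oxidized plastoquinone | molecules PSII⁻¹, [0, PQ_tot] |
| `PI_ox` | oxidized fraction of the PSI donor side | [0, 1] |
| `H_L` | lumen free H⁺ concentration | µM, > 0 |
| `ATP` | adenylate in ATP form | molecules PSII⁻¹, [0, A_tot] |
| `Zea` | zeaxanthin fraction of the xanthophyll pool | [0, 1] |
| `PsbS_act` | protonated (active) PsbS fraction | [0, 1] |

The closed fraction of PSII reaction centers, `RCII_closed` (B), is an
algebraic (quasi-steady) dependent variable, not a seventh ODE: the
QA-redox relaxation is orders of magnitude faster than every retained
process.

Out of scope by design: cyclic electron flow, the Calvin–Benson cycle,
photoinhibition, state transitions, stomatal and chloroplast-movement
responses, spectral properties of the actinic and measuring beams, and
any numerical fitting of model parameters to experimental fluorescence
traces.

## Rate laws

**Quencher activation.**  Both qE components are activated by lumen
acidification through Hill functions of the free H⁺ concentration:

    v3 = k3 (1 − Zea)      · 1/(1 + (K_Q,VDE /H_L)^n_VDE),   n_VDE  = 6
    v9 = k9 (1 − PsbS_act) · 1/(1 + (K_Q,PsbS/H_L)^n_PsbS),  n_PsbS = 4

with K_Q = 1 µM for both, k3 = 0.01 s⁻¹, k9 = 0.05 s⁻¹.  Deactivation is
first order (k4 = 0.001 s⁻¹, k10 = 0.004 s⁻¹) — the parsimonious reading
of "effective rate constants"; no other functional form is implied by
the constants alone.  The PsbS response time constant is therefore tens
of seconds and the xanthophyll cycle's is minutes, which is what
separates the fast (constitutive) from the slow (regulatory) loop
regimes.

**ATP synthesis.**  The synthase runs on the proton-motive force with a
c₁₄ rotor ring (14/3 H⁺ per ATP):

    v5 = k5 [(A_tot − ATP) − a · ATP / H_L^(14/3)],   a = 9.202·10⁻²

v5 may be negative (net hydrolysis) but reverse proton pumping by the
synthase is excluded from the proton budget (only max(v5, 0) consumes
lumen H⁺); ATP is consumed first order with k6 = 8 s⁻¹.

**PSII ↔ PQ exchange and closure.**  The lumped forward/backward rate
constants k1⁺ = 250 s⁻¹ and k1⁻ = 100 s⁻¹ are interpreted *per
plastoquinone molecule*; each PQ carries ν_e = 2 electrons.  With
p = PQ_ox/PQ_tot, r = 1 − p and the quenching-modulated excitation rate
kL = σ_II·q·light, the quasi-steady closure balance kL(1−B) = J2 gives

    B  = (kL + ν_e k1⁻ r) / (kL + ν_e k1⁻ r + ν_e k1⁺ p)
    J2 = ν_e (k1⁺ p B − k1⁻ r (1−B))  =  kL (1−B)      [e⁻ PSII⁻¹ s⁻¹]

The per-molecule interpretation matters: reading k1⁺ as an electron rate
caps the chain at 250 e⁻ PSII⁻¹ s⁻¹, and the ≈60 O₂ anchor (240 e⁻ s⁻¹)
would then force a ≥96 % *oxidized* pool in saturating light — making
the pool kinetics millisecond-fast and inverting the fast-loop
orientation.  With the two-electron bookkeeping the anchor is met with a
partly reduced pool (40 % at 1000 µmol photons m⁻² s⁻¹), consistent with
the redox phenomenology the model is meant to reproduce.

**Plastoquinol re-oxidation.**  The PQH₂ → PSI-donor step (cytochrome
b₆f) is carried by a finite enzyme complement and saturates in its
substrate:

    J_bf = k2 · PI_ox · r / (K_PQ + r),   K_PQ = 0.05

This Michaelis form is the model's second load-bearing choice.  A drain
linear in r pins the pool relaxation rate at flux/(r·ν_e·PQ_tot) ≳
30 s⁻¹ for any parameterization meeting the steady-state anchors, which
erases the sub-second redox lag: the T = 1 s loops collapse below the
orientation tolerance and the counter-clockwise→clockwise transition
slides under T = 10 s.  With a saturating drain the reduced pool
*integrates* the rising light flank, producing the observed
counter-clockwise fast loops and placing the orientation transition
between T = 10 and 30 s.

**Assembled right-hand side** (light in µmol photons m⁻² s⁻¹):

    dPQ_ox/dt   = (J_bf − J2)/ν_e
    dPI_ox/dt   = σ_I·light·(1 − PI_ox) − J_bf
    dH_L/dt     = β_H (n_H·J2 − (14/3)·max(v5,0)) − k_leak (H_L − H_0)
    dATP/dt     = v5 − k6·ATP
    dZea/dt     = v3 − k4·Zea
    dPsbS/dt    = v9 − k10·PsbS_act

ATP is carried in molecules per PSII, so no unit-conversion factor
appears in the proton sink; the ½ ATP-synthase-per-PSII stoichiometry
enters only when reporting the per-synthase rate (2·v5).  Lumen
buffering is absorbed into β_H; H_0 = 0.1 µM corresponds to a resting
lumen near pH 7.

**Fluorescence.**  The two quenchers act multiplicatively on both the
excitation rate (via kL) and the fluorescence yield — quenching is
photoprotective, not merely optical:

    q    = (1 − Zea_max·Zea)(1 − PsbS_max·PsbS_act),  Zea_max = PsbS_max = 0.3
    ChlF = q(1−B)(1−Φ)/((1−Φ) + qΦ) + qB,             Φ = F_V/F_M = 0.83

which is algebraically identical to the stepwise computation
F_M′ = q·F_M, F₀′ by the Oxborough–Baker approximation,
F′ = F₀′ + B(F_M′ − F₀′) (verified to 10⁻¹² in the tests).  The NPQ
parameter is (F_M − F_M′)/F_M′ = 1/q − 1.

## Parameters

Constants fixed by the published model description: k1±, k3, k4, k6, k9,
k10, K_Q (both), n_VDE, n_PsbS, Zea_max, PsbS_max, a.  Genotype presets:
*npq1* = wild type with k3/1000 (no de-epoxidation), *npq4* = wild type
with k9/1000 (no PsbS protonation); everything else identical.

The remaining transport and proton constants are effective
reconstruction parameters.  Design constants fixed a priori:

* Φ = 0.83 — canonical dark-adapted F_V/F_M of a healthy leaf.
* PQ_tot = 21 PQ PSII⁻¹ — within the published span of pool sizes;
  together with K_PQ = 0.05 it sets the pool time constant
  (~0.1–0.5 s at mid-range light) that governs the fast-loop lag.
* σ_I = 6 (µmol photons m⁻² s⁻¹)⁻¹ s⁻¹ — keeps the PSI donor side
  largely oxidized across the studied range so the b₆f step, not PSI
  photochemistry, limits the drain.
* A_tot = 10 ATP PSII⁻¹, n_H = 1 H⁺/e⁻, H_0 = 0.1 µM, k_leak = 1 s⁻¹ —
  a proton budget that closes at the anchors without a thermodynamically
  dominant leak (leak carries ~10 % of the influx at 1000 µmol).

The four remaining constants (σ_II, k2, k5, β_H) are set by
`calibrate()`: a deterministic, bounded trust-region least squares in
log-space with four residuals — O₂ rate = 60 PSII⁻¹ s⁻¹ and ATP rate =
93 synthase⁻¹ s⁻¹ at 1000 µmol photons m⁻² s⁻¹, steady lumen H⁺ = 2 µM
at 1000 (quenchers active in saturating light), and a 40 % reduced pool
at 1000 (the redox operating point above).  The bounds keep the
optimizer at this operating point; the anchor system also has distant
roots with a fully oxidized pool that meet the rates but not the
physiology.  The steady H⁺ at 100 µmol (growth light) is not targeted
but checked: it lands at 0.60 µM, just below the 1 µM half-activation
concentration, so the steep Hill activations swing across each
oscillation cycle.  The shipped defaults and the three preset files are
the exact calibration output; re-running `calibrate()` on them is a
no-op.  (With both quenching depths at 0.3, the attainable NPQ ceiling
is 1/0.49 − 1 ≈ 1.04.)

## Light protocols and numerics

The standard schedule mirrors the measurement protocol: 10 min constant
pre-illumination at the oscillation mean, then sine segments starting at
the minimum (u(t) = u₀ − u₁·cos 2πt/T) with 3 cycles of T = 8 min,
5 cycles each of 4, 2, 1 min, 30 s, 10 s, and 10 cycles each of 5 s and
1 s.  The instrument's 8-bit light control is emulated by rounding the
ideal sine to the *reported step count* per range (8 levels for 100–200,
22 for 100–400, 49 for 100–800 µmol photons m⁻² s⁻¹) — the printed
counts are not consistent with one uniform DAC step, so the count is
taken as given rather than guessing the converter's mapping.  Segment
transitions are phase-continuous because every segment starts and ends
at u_min.

Integration uses LSODA with rtol 10⁻⁸ / atol 10⁻¹⁰ and output on the
0.1 s grid of the instrument's effective sampling.  Quantized waveforms
are piecewise constant; the integrator is restarted at every analytic
level-crossing time, so the solver never steps across a discontinuity.
Unquantized sines are integrated continuously with max_step = T/32.
Steady states are found by relaxation integration followed by hybrid
root polishing to a units-scaled residual norm < 10⁻⁸; in darkness the
electron-transport subsystem is degenerate (zero flux through a reduced
donor side), so the canonical dark-adapted state imposes PQ fully
oxidized and PI_ox = 0 and solves the (H_L, ATP, Zea, PsbS) subsystem —
the quenchers retain a Hill-tail residual of < 2·10⁻³ rather than exact
zero.  Everything downstream of parameters is deterministic; identical
inputs give bitwise-identical traces.

## Analysis

**Harmonic decomposition.**  Steady-state cycles are fitted with
A0 + Σₖ Aₖ sin(k·2π(t − τₖ)/T), k ≤ 4, via the linear reparameterization
aₖ sin(kωt) + bₖ cos(kωt) — an exact, global, initialization-free least
squares.  Amplitudes are reported non-negative; the phase fraction τₖ/T
is only identifiable modulo 1/k and is canonicalized into [0, 1/k).
Replicate fits are averaged with SE = SD/√n; phases are averaged as
resultant vectors on the k-fold circle to avoid wrap-around artifacts.

**Hysteresis loops.**  Transient cycles are discarded (the first cycle
of the 8-min segment, the first two of every other segment) and the
retained cycles phase-averaged.  The loop's signed area (shoelace
formula on the (light, ChlF) polygon) is normalized by the bounding-box
area; positive = counter-clockwise = constitutive, negative = clockwise
= regulatory, |index| < 0.02 = negligible (below the plotting resolution
at which orientations are discernible; configurable).  Ascending and
descending branches are split at the light extremes, the ascending
branch owning the maximum.

**Synthetic traces.**  The fixture generator evaluates the harmonic
model on the 0.1 s grid and adds i.i.d. Gaussian noise (the instrument
averages 20 raw points per sample, which Gaussianizes the noise), with
n = 3 replicates by default and full reproducibility from the seed.  It
emulates the *statistics* of steady-state periodic measurements only —
no saturation-pulse artifacts, drift, heteroscedasticity, or aperiodic
transients — so tests passing on synthetic data validate the estimators,
not the model.

## Verified behavior at the shipped defaults

The test suite re-simulates the full standard schedule for all three
genotypes and light ranges and checks: counter-clockwise T = 1 s loops
in all nine genotype × range combinations with both quenchers frozen
within a cycle (per-cycle peak-to-peak < 10⁻³); clockwise loops at T =
60 s and 4 min in the wild type with the fluorescence maximum preceding
the light maximum; an orientation transition between T = 10 and 60 s
(measured: between 10 and 30 s); a much weaker regulatory loop in *npq4*
than in the wild type; and higher cycle-mean fluorescence in both
mutants than in the wild type at T = 1 s.  First-harmonic amplitudes
decrease from T = 10 s to T = 1 s (low-pass behavior) and higher
harmonics vanish quadratically as the oscillation amplitude shrinks.

## Known limitations

* The electron/proton transport fluxes other than the quencher and ATP
  rate laws are reconstructions constrained by two scalar anchors and
  qualitative loop phenomenology; they are not transcriptions of a
  published parameterization, and absolute pool redox states or lumen
  pH values should not be over-interpreted.
* The model's light response between the anchors is smooth but its P–I
  curvature was not fitted to gas-exchange data.
* The 8-min segment retains a small periodicity residual (~10⁻⁴ ChlF
  units between consecutive cycles) from the slowly equilibrating
  xanthophyll pool; all shorter-period segments settle below 10⁻⁴ after
  the standard two-cycle discard.
* Very low light (< ~20 µmol photons m⁻² s⁻¹) drives the lumen toward
  its resting H⁺ where the ATP back-pressure term is numerically stiff;
  the integrator handles this, but steady-state NPQ there is essentially
  zero by construction.
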