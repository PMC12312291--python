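# oscifluor

Kinetic simulation and frequency-domain analysis of chlorophyll
fluorescence responses of *Arabidopsis thaliana* leaves to harmonically
oscillating light.

## The problem

Steady-state light-response (P–I) curves cannot describe how
photosynthesis behaves in the fluctuating light of real canopies.  When
the actinic light oscillates sinusoidally between a sub-saturating and a
saturating intensity, the normalized chlorophyll fluorescence yield
ChlF(t) = F′(t)/F_M traces a *hysteresis loop* against light intensity,
and the loop's shape and orientation report on the dynamics of the
electron-transport chain and of non-photochemical quenching (NPQ):

* **Constitutive hysteresis** — at short periods (T < ~30 s) the
  fluorescence lags the light because the primary reactant pools
  (plastoquinone, lumen H⁺) cannot fill and empty fast enough.  The loop
  runs **counter-clockwise** and appears in the wild type and in qE
  mutants alike.
* **Regulatory hysteresis** — at longer periods the delayed response of
  the energy-dependent quenching (qE) dominates: fluorescence starts to
  fall before the light peaks and the loop runs **clockwise**.  It
  requires the PsbS protein (absent in *npq4*) and is modulated by the
  xanthophyll cycle (inactive in *npq1*).

`oscifluor` implements a six-variable kinetic model of this system —
oxidized plastoquinone PQ_ox, oxidized PSI donors PI_ox, lumen free H⁺,
ATP, zeaxanthin fraction Zea, and active PsbS fraction PsbS_act — with
two independently H⁺-activated quenchers

    v3 = k3 (1 − Zea)      / (1 + (K_Q/H_L)^n_VDE),
    v9 = k9 (1 − PsbS_act) / (1 + (K_Q/H_L)^n_PsbS),

an ATP synthase with the c₁₄-ring stoichiometry

    v5 = k5 [(A_tot − ATP) − a·ATP / H_L^(14/3)],

and the fluorescence observable (Oxborough–Baker F₀′ correction)

    ChlF = q(1−B)(1−Φ) / ((1−Φ) + qΦ) + qB,
    q = (1 − Zea_max·Zea)(1 − PsbS_max·PsbS_act),

where B is the quasi-steady closed fraction of PSII reaction centers and
Φ = F_V/F_M.  The shipped wild-type parameter set is calibrated so that
the fixed point under constant 1000 µmol photons m⁻² s⁻¹ produces
≈60 O₂ PSII⁻¹ s⁻¹ and ≈93 ATP synthase⁻¹ s⁻¹.  The *npq1* and *npq4*
mutants are the same parameter set with k3 (respectively k9) divided by
1000.

On the analysis side the package provides the experimental protocol
generator (sine periods 8 min → 1 s with DAC-quantized intensities, 10
min pre-illumination at the oscillation mean), the offset+four-harmonic
least-squares decomposition

    Fit(t) = A0 + Σₖ Aₖ sin(k·2π(t − τₖ)/T),   k = 1..4,

replicate aggregation with standard errors, hysteresis-loop extraction
with signed-area orientation (shoelace), and a synthetic-trace generator
with known ground truth for validating the fitting pipeline.

## Worked example

Simulate a wild-type leaf, dark-adapted, pre-illuminated 10 min at
450 µmol photons m⁻² s⁻¹, then driven through five 60-s and ten 1-s
light cycles between 100 and 800 µmol photons m⁻² s⁻¹, and analyze the
steady-state cycles:

```sh
oscifluor simulate --genotype WT --range 100-800 \
    --schedule "60:5,1:10" --pre-illum 600 --out demo --tag wt
oscifluor analyze demo/wt.csv --out demo
```

`demo/wt.loops.csv` then contains one row per oscillation segment:

```
segment,T,orientation,area_index,classification,chlf_mean,...
T60,60,CW,-0.04453688178,regulatory,0.3980574259,...
T1,1,CCW,0.08545382923,constitutive,0.4013392477,...
```

The 60-s loop is clockwise (area index −0.045): quenching lags the
light, so fluorescence is higher while light ascends — regulatory
hysteresis.  The 1-s loop is counter-clockwise (+0.085): the quenchers
are frozen within a cycle and the lag of the plastoquinone pool redox
state dominates — constitutive hysteresis.  `demo/wt.fits.csv` holds the
matching harmonic decompositions, e.g. for T = 60 s a fundamental
amplitude A1 ≈ 0.103 ChlF units at phase τ1/T ≈ 0.24 with a 4-harmonic
residual RMS of 1.6·10⁻⁴.

The same can be done from Python:

```python
import oscifluor as osc

params = osc.genotype_preset("WT")
trace = osc.simulate(osc.standard_schedule(100, 800), params)
loop = osc.extract_loop(trace, "T60")
print(osc.orientation_and_area(loop))   # ('CW', -0.044)
```

## Layout

- `src/oscifluor/parameters.py` — parameter sets, genotype presets, YAML I/O
- `src/oscifluor/model.py` — state, rate laws, ODE right-hand side
- `src/oscifluor/light.py` — oscillating-light protocols and quantization
- `src/oscifluor/simulate.py` — integration, steady states, calibration
- `src/oscifluor/fluorescence.py` — ChlF observable and NPQ parameter
- `src/oscifluor/harmonics.py` — four-harmonic fitting and aggregation
- `src/oscifluor/hysteresis.py` — loop extraction, orientation, classification
- `src/oscifluor/synthetic.py` — ground-truth noisy trace generator
- `src/oscifluor/cli.py` — `oscifluor simulate` / `oscifluor analyze`
- `docs/methods.md` — model derivation, assumptions and numerical choices
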