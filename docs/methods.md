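# Methods

## Model structure and assumptions

The animal is partitioned into four perfused compartments — brain, fat
(including bone), central circulation (heart/kidney/liver) and muscle
(muscle, skin, connective tissue, alimentary tract) — plus one blood
compartment split into an arterial pool (1/3 of blood volume by default)
and a mixed-venous pool (2/3), and a homogeneous lung gas store. Soft
tissue and blood are taken at unit density (1 kg ≈ 1 l).

Assumptions, in decreasing order of consequence:

* **Perfusion-limited exchange.** Each tissue equilibrates its outflowing
  blood with its own gas tension; there is no diffusion limitation either
  at the tissue or (while ventilated) at the alveolus. Tissue tensions
  therefore relax toward arterial with time constant
  `V_c β_c / (f_c Q̇tot β_blood)`.
* **Homogeneous lung.** Lung gas is one well-mixed pool; dead-space gas is
  not tracked separately for composition. Alveolar partial pressures are
  dry-gas fractions times `(P_amb − 0.062 ATA)`, with water vapor fixed at
  0.062 ATA (saturation at 37 °C). Temperature is fixed; there are no
  Bohr/Haldane or pH effects.
* **Instantaneous surface breathing.** At the surface the alveolar
  composition is pinned to {N2 0.74, O2 0.133, CO2 0.065, H2O 0.062} ATA
  and arterial blood is pinned to the corresponding contents (no surface
  diffusion resistance). There is no tidal-breath model; recovery dynamics
  at the surface are carried entirely by venous and tissue pools.
* **Memoryless mechanics.** Respiratory geometry depends only on ambient
  pressure and current lung gas amount, so alveolar collapse and
  recruitment occur at the same ambient pressure on descent and ascent.
* **No cardiovascular dynamics** beyond the two-state (surface/dive)
  schedule: no heart-rate model, no anticipatory tachycardia, no stress
  scenarios, no active ventilation–perfusion management.

## Respiratory mechanics

Total lung capacity follows `TLC = 0.135 M_b^0.92` l (M_b in kg); dead
space is 7% of TLC. Dives start at TLC by default (`diving_lung_volume_
fraction` config). At ambient pressure P the total lung gas volume follows
Boyle's law; a single structural (collapsing) pressure is solved (1-D root
finding, tolerance 1e-9 l; a 6000-point grid serves the inner ODE loop) so
that the alveolar and dead-space structural curves jointly hold that
volume:

* alveolar: `v_A(p) = (1 + a·p/b)^(−c)` (normalized),
* dead space: `v_D(p) = exp(−(p/|Kp|)^n)`.

The exact functional forms in the compliance literature are not restated
here; these two survival-type laws were chosen so that the published
parameter sets — dolphin-fit `(a, b, c, Kp, n) = (1.05, 0.90, 2.51, −31.0,
2.4)` and legacy `(1.1, 1.2, 1.3, −12.8, 0.91)` — reproduce the documented
orderings at *every* pressure: the dolphin fit gives a stiffer upper
airway (larger |Kp|, larger n) and a more compliant alveolar space, hence
a larger shunt and earlier collapse. Both curves are monotone
non-increasing and bounded in [0, 1], and either can be swapped out behind
`RespiratoryModel` without touching the engine.

The pulmonary shunt is `s = 1 − (v_A/V_A,max)^γ`, clamped to [0, 1]. The
default exponent γ = 0.1 is convex: the shunt stays small under the
moderate Boyle compression of shallow dives (s ≈ 0.05 at 5 m) and rises
steeply as the alveoli approach collapse. This reproduces the observed
phenomenology — no meaningful shunt on coastal shallow dives, arterial
hyperoxia during deep descent, a second, lower arterial PO2 peak at
recruitment on ascent — which a linear exponent (γ = 1, also available)
suppresses by mixing venous blood into the arterial side from the first
few meters. Collapse is declared below a normalized alveolar volume of
1e-3, forcing s = 1 (atelectasis); with the dolphin-fit parameters this
occurs at ≈ 124 m on a 300-m dive.

## Gas carriage

Contents are ml STPD per liter; tensions kPa (1 ATA = 98.07 kPa).

| constant | default | note |
|---|---|---|
| O2 capacity of Hb and Mb | 1.34 ml/g | standard Hüfner value |
| Hb P50 / Hill n | 3.7 kPa / 2.7 | cetacean whole-blood range |
| Mb P50 (hyperbolic) | 0.32 kPa | high-affinity muscle pigment |
| CO2 capacitance (blood/lean/fat) | 40 / 45 / 20 ml l⁻¹ kPa⁻¹ | effective linear slope incl. bicarbonate |
| Ostwald N2 (aqueous/fat) | 0.15 / 0.68 ml l⁻¹ kPa⁻¹ | fat ≫ aqueous |
| Ostwald O2 | 0.225 ml l⁻¹ kPa⁻¹ | dissolved fraction |

None of these is printed in the source material for this model family
(they are deferred to prior work); the defaults above are
literature-typical values, are exposed in `data/gas_constants.yaml`, and
the package's quantitative store/cADL results do not depend on them. CO2
carriage is linear by design (a nonlinear dissociation curve can be
plugged in); CO2 results should be read as directional only.

## Physiology presets

Compartment sizes, metabolic rates (200 kg reference), [Hb], [Mb], Hct and
perfusion schedules ship in `data/sarasota.yaml` and `data/bermuda.yaml`.
Notable choices:

* The muscle row "57 (35)" / "57 (50)" is read as: 57% of body mass is the
  muscle *compartment*; the parenthetical is the myoglobin-bearing
  locomotor fraction used for the Mb store. Both are stored separately.
* Compartment mass fractions plus blood do not sum exactly to 1 (99.93%
  coastal); the residual is documented and *not* renormalized. Perfusion
  fractions must sum to exactly 1 per state and do.
* Whole-animal resting V̇O2 is carried both as per-compartment rates
  (summing to 0.668 / 0.535 l min⁻¹) and as the printed totals (0.67 /
  0.54); cADL reporting uses the printed totals, which is what the 2×
  field rates (1.34 / 1.08 l min⁻¹) imply.
* Mass scaling: mass-specific rates scale as `(M/200)^(−0.25)` (exponent
  configurable); at 200 kg every printed value is recovered exactly.
* The offshore brain fraction of 0.2% (vs 1.0% coastal) is shipped as
  printed.
* Dive response: cardiac output at the surface is 3× resting (coastal) or
  7× (offshore), falling to resting during the dive response, which
  engages on any submergence for the coastal preset and only below 20 m
  offshore. The switch is instantaneous by default; a depth-ramp blend is
  available (`dive_response_ramp_m`).
* Simulations run at a field metabolic rate of 2× resting in every
  compartment (`metabolic_multiplier`), respiratory quotient 0.9.

## O2 stores and cADL

* **Lung**: dive-start gas volume × 0.133 ATA O2. The default volume
  convention is TLC corrected for water vapor (2.205 l at 200 kg, printed
  2.21); plain-TLC and alveolar-volume conventions are selectable since
  the exact convention behind the printed value is ambiguous at the third
  digit.
* **Blood**: arterial third at 95% saturation, venous two-thirds 5
  saturation points lower. This reproduces the printed blood stores to
  0.1% (offshore) and 4% (coastal); an alternative "5 vol% content
  deficit" convention is selectable but deviates 13% on the offshore side.
* **Tissue**: locomotor muscle mass × [Mb] × 1.34 ml/g (9.78 l offshore vs
  10.00 printed). The printed coastal tissue store (3.82 l) is not
  recoverable from this product (2.81 l) and the missing term is not
  stated; the printed value is used for totals, and the formula path is
  validated on the offshore side only.
* cADL = total store / metabolic rate, reported at resting, 2× resting,
  and the measured coastal field-rate range 11.7–23.4 ml O2 min⁻¹ kg⁻¹.

## Numerics

Fixed-step classical RK4, default dt = 0.1 s, over the linearly
interpolated 1-Hz depth profile; tissue O2 amounts are floored at zero
(an exhausted compartment stops consuming and the dive is flagged
anaerobic). Blood O2 inversion uses a dense precomputed tension grid
(≤ 2.5 Pa spacing in the physiological range); muscle O2 inverts in closed
form. At dt = 0.1 the engine agrees with a from-scratch explicit-Euler
integration (dt = 1 ms) to ≤ 0.35 kPa on an extreme 150-m square dive and
to ≤ 0.015 kPa at dt = 0.01, which is the step the equivalence test uses.
The O2 mass-balance audit (uptake = consumption + store change) closes to
~0.01% over surface-to-surface cycles; with metabolism disabled, total
lung+blood+tissue gas is conserved to machine precision while submerged.

## Synthetic dive generator

The generator defines the study conditions for all tests: trapezoidal
dives at constant vertical speed interleaved with lognormal surface
intervals, one seeded random stream per record.

* **Coastal**: durations lognormal (mean 35 s, sd 19) truncated to
  [12, 129] s; depths lognormal (2.5 ± 1.2 m) truncated to [1.7, 10] m;
  surface intervals 80 ± 100 s.
* **Offshore**: a two-mode mixture — shallow mode (85%): depths 8 ± 10 m
  truncated to ≤ 70 m with weakly depth-dependent durations (55 ± 35 s,
  ≤ 250 s); deep mode (15%): depths 180 ± 80 m truncated to [100, 482] m,
  duration = transit + bottom time (60 ± 40 s), capped at 539 s. Surface
  intervals 44 ± 50 s.
* Vertical speed defaults to 2.0 m s⁻¹: the deepest generated dive
  (482 m) is then feasible within the 539-s duration cap, which a slower
  default would violate geometrically.

The generator emulates the two populations' duration/depth envelopes and
the offshore two-cluster structure. It does not emulate: bottom-phase
wiggles or foraging structure, irregular ascent/descent rates, sensor
noise, tidal/temperature artifacts, or any behavioral response to
physiological state. Passing tests therefore demonstrate correct model
mechanics under realistic dive geometry, not agreement with any individual
animal's record.

## Known limitations

* CO2 kinetics are directional only (linear capacitance, no Haldane
  effect).
* The shunt exponent and the structural-curve forms are stand-ins
  constrained by published parameter values and qualitative behavior, not
  refits to compliance data.
* Dissolved-only O2 in brain/fat/central circulation makes those
  compartments fast and shallow O2 buffers; their exhaustion flags are
  sensitive to the perfusion schedule.
* No decompression-sickness risk scoring is attempted; venous N2 is
  reported as a tension, not a risk.
* Mass scaling of metabolic rate uses a single allometric exponent for all
  compartments.
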