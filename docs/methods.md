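# Methods

## Gas–liquid partitioning

Equilibrium between the 50 mL liquid phase and the ~70 mL He headspace is
assumed at every sampling time; no gas-transfer kinetics are modelled. The
dimensionless Henry constant (solubility convention, H = C_aq/C_g, so
CO₂ > N₂O > N₂) is

    H(T) = Hcp,ref · exp(d · (1/T − 1/298.15)) · R · T

with R = 0.082057 L atm mol⁻¹ K⁻¹. Defaults (literature compilation values,
overridable through the shipped `gas_species.csv` table):

| gas | Hcp,ref (mol L⁻¹ atm⁻¹) | d (K) |
|-----|------------------------|-------|
| CO₂ | 0.0334 | 2400 |
| N₂O | 0.0245 | 2600 |
| N₂  | 6.4×10⁻⁴ | 1300 |

At 303.15 K these give 0.728 / 0.528 / 0.0148. Different solubility
compilations differ in the third decimal; agreement beyond ~2% is not
claimed. Salting-out follows the Schumpe ion-specific model,
log₁₀(H₀/H) = Σᵢ (hᵢ + h_G)·cᵢ, with a bundled coefficient table for the
dominant ions of a CSBK-like minimal medium; the correction defaults ON for
mass-balance work on real media and OFF when reproducing the zero-ionic-
strength constants. Ideal-gas behaviour is assumed at 0.9 atm.

## Carbonate system

Freshwater dissociation constants come from standard temperature
polynomials (pK₁ 6.35, pK₂ 10.33, pKw 14.00 at 25 °C; 6.33 / 10.29 / 13.83
at 30 °C). Alkalinity is carbonate alkalinity,
TA = DIC·(α₁ + 2α₂) + [OH⁻] − [H⁺] in meq/L; an optional titration-style
estimator adds the acetate contribution at a pH 3.5 endpoint (~0.95 eq per
mol acetate) because bench titrations to that endpoint also consume titrant
on acetate. TA is strictly increasing in pH at fixed DIC, so the inverse
pH(TA, DIC) is found by bracketed Brent iteration on pH ∈ [2, 13]
(residual < 10⁻⁹ meq/L). A Davies activity correction is available but off
by default; at the medium's ionic strength (~0.05 M) it shifts the predicted
endpoint by less than the model tolerance.

The denitrification stoichiometry is the balanced form

    0.625 CH₃COO⁻ + NO₃⁻ + 0.375 H⁺ → 0.5 N₂ + 1.25 HCO₃⁻ + 0.5 H₂O

whose electron accounting (8 e⁻ per acetate; 5, 3 and 2 e⁻ per N for the
NO₃⁻-, NO₂⁻- and N₂O-fed cases) is asserted at construction time. Each mmol
of NO₃⁻ fully reduced adds 1.25 mmol DIC and 1.625 meq TA per litre.
Biomass assimilation (default 25% of total acetate consumption) is assumed
to produce neither bicarbonate nor alkalinity — a deliberate simplification;
its main effect is on the acetate budget, not the pH trajectory.

## Nitrogen recovery statistics

The recovery statistic divides twice the N₂ produced by the NO₃-N actually
consumed, subtracting residual NO₂⁻ but not residual N₂O from the
denominator:

    % recovered = 100 · 2[N₂] / ([NO₃]ᵢ − [NO₃]f − [NO₂]f)

This is the only form that reproduces every row of the published batch
tables (the typeset formula omits both the mol-N₂→mol-N factor and the NO₂⁻
term; that literal form remains available behind `literal_printed_form=True`
for comparison). Below-detection entries ("ND", < 0.001 mmol/L) enter the
arithmetic as zero and carry a flag. Fold changes use the signed convention:
ratios ≥ 1 as-is, ratios < 1 reported as −1/ratio.

## Kinetic summaries

The overall denitrification rate is defined operationally as initial NO₃⁻
divided by the first sampling time at which NO₃⁻, NO₂⁻ and N₂O are all below
detection. This is the definition consistent with the published per-strain
rates (0.862/2 d = 0.431; 0.918/13 d = 0.071 — note the 13-day reading of
the slow strain's completion, implied by its printed rate, is adopted over
the "14 days" in running text). Growth rates are least-squares slopes of
ln OD₆₀₀ over an exponential window — by default the maximal strictly
increasing run ending at the OD maximum, always overridable and recorded
explicitly, since automatic window selection under noise is the dominant
error source. Lag times locate the onset of decline by back-extrapolating
the threshold-crossing segment to the initial concentration, which returns
exact onsets for flat-then-linear traces and 0 for immediate decline.
Yield coefficients are plain ratios tagged with their definition (default
mol N₂ per mol NO₃⁻, theoretical maximum 0.5); the published yield column
matches no ratio of printed quantities and is therefore not a target of any
test here.

## qPCR layer

Standard curves are least-squares fits CT = slope·log₁₀(input) + b with
efficiency (10^(−1/slope) − 1)·100. Relative expression is pure 2^(−ΔΔCT):
replicate CTs are arithmetic-mean averaged per (condition, gene), target
minus reference within condition, treatment minus control across conditions.
Efficiency correction (Pfaffl) is intentionally absent — the assays this
layer is built around run at 96.8–102.6% efficiency, where the pure method
is standard. Replicate scatter above 0.5 cycles raises a flag rather than
triggering outlier rejection. Sparse designs (a gene assayed in only some
conditions) are allowed; a missing reference gene in an assayed condition is
an error.

## Simulator

State: whole-bottle pools of NO₃⁻, NO₂⁻, N₂O and N₂ expressed per litre of
liquid. Three Monod steps in series,

    rᵢ = vmaxᵢ · X · Sᵢ/(ksᵢ + Sᵢ) · g_pH(pH) · g_ind,ᵢ(t)

with g_pH = 1/(1 + exp((pH − pH₅₀)/w)) (defaults pH₅₀ = 9.3, w = 0.3 — the
observed rate collapse "above ~9" given a smooth two-parameter form) and a
smoothed step-up gate at each step's induction delay (transition width
0.02 d, to keep the system non-stiff). Nitrite toxicity is modelled as lag
extension, not rate killing: every active delay grows by (initial
NO₂⁻)/kᵢ days with kᵢ = 2 mmol L⁻¹ per day, calibrated to the observed lag
growth from 0.5–3 d to 0.7–5 d as initial NO₂⁻ rises 1→5 mmol/L.

Everything else is algebraic in the electron flow
E = 2s₁ + 2s₂ + s₃ (extents sᵢ in mmol/L): catabolic acetate = E/8, total
acetate drain = E/8/(1−f) with assimilated fraction f = 0.25, biomass
OD = OD₀ + Y_b·f/(1−f)·E/8, DIC = DIC₀ + E/4, TA = TA₀ + 0.325·E, and pH is
re-solved from (TA, DIC) inside the right-hand side. This makes whole-bottle
N conservation structural (verified to < 10⁻⁶ relative) and avoids
integrating stiff chemistry. Integration is LSODA with rtol 10⁻⁸ /
atol 10⁻¹²; negative excursions are clipped only when forming rates.

N₂O and N₂ partition between phases by instantaneous Henry equilibrium at
output times. Headspace CO₂ is reported from DIC·α₀/H but not subtracted
from the DIC budget — above pH 8 the headspace holds < 2% of the inorganic
carbon, consistent with its non-detection in the alkaline cultures.

**Presets.** Half-saturation constants default to 0.05 mmol/L — an
order-of-magnitude convention, not a measured value. vmax values (mmol per
L·d·OD unit) and delays were calibrated once so that noiseless runs at
~0.9 mmol/L NO₃⁻ reproduce the observed phenotypes: K172 (20, 120, 120; no
delays) and TK001 (40, 120, 120) complete within 2 days with < 0.05 mmol/L
transient NO₂⁻; NS1 (29, 1.8, 8; delays 0 / 0.7 / 1.6 d on steps 1–3) peaks
at ~0.84 mmol/L NO₂⁻ near day 2 and completes on day 13. Biomass yields
(0.61 / 0.48 / 0.20 OD per mmol acetate assimilated) reproduce the measured
maximum OD₆₀₀ (0.119 / 0.095 / 0.042). The effective in-simulator growth
rates exceed the published OD-derived exponential rates — with the measured
inoculum (OD 0.005) and yields, the published µ values cannot consume
0.9 mmol/L nitrate in two days, so completion times and maximum ODs were
prioritized in the calibration; growth-rate estimation is validated on
directly planted exponentials instead.

**Observation model.** Sampled observations (concentrations, OD, TA) get
multiplicative log-normal noise with mean 1 (default CV 5%); pH gets
additive noise (sd 0.02). Aqueous species below 0.001 mmol/L and headspace
gases below 0.002 mmol/L are censored to 0 ("ND" on output). Noise applies
only to observations, never to the latent state. All randomness derives
from one master seed via `numpy` SeedSequence spawning; equal seeds give
bitwise-identical tables.

**What the generator does and does not emulate.** It reproduces the study
design (bottle geometry, factorial sets 1–5, sampling cadence, detection
limits, multiplicative noise, sequential-reduction phenotypes, pH feedback).
It does not model NO as a state, transcript dynamics (induction delays are
phenomenological), gas-transfer kinetics, mineral buffering, or
between-replicate biological variability beyond observation noise — so
passing recovery tests demonstrate estimator correctness under the assumed
observation model, not robustness to structural model error in real data.

## Numerical and design choices

- pH root-finding uses guaranteed-bracket Brent on a monotone function
  rather than Newton; degenerate inputs (TA outside the attainable range)
  raise with the bracket values.
- The initial condition for pH-varied designs holds DIC at the
  default-medium value (2.67 mmol/L, implied by pH 7.50 / TA 2.51 meq/L)
  and recomputes TA at the requested pH, mimicking carbonate/bicarbonate
  dosing at roughly constant DIC.
- The initial TA 2.51 meq/L is taken as given; it is not derivable from the
  nominal 0.03 M bicarbonate recipe, and the published computed endpoint TA
  (3.00 meq/L) follows no single reconstructible accounting, so only the pH
  endpoint and the TA direction are treated as checkable.
- Problem sizes in the tests (single bottles over 14–90 simulated days,
  100-seed recovery loops, 1000-seed ΔΔCT Monte Carlo) were chosen to give
  stable statistics at interactive runtimes.

## Known limitations

- The pH-inhibition logistic self-limits near pH ~9.6 (alkalinity and DIC
  additions nearly cancel in the TA balance there), so very high nitrate
  loads slow down but may still complete over 90 days; the observed
  *decline* in recovery at 4–5 mmol/L is reproduced directionally
  (never-increasing), not quantitatively.
- Single-strain, well-mixed batch only; no competition, no chemostat mode.
- The Sechenov coefficient table covers the bundled medium ions; exotic
  media require user-supplied coefficients (missing ions raise a
  configuration error naming the ion).
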