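# denitkin

Quantitative core of a sealed-bottle batch denitrification study: gas–liquid
nitrogen mass balance, closed-system carbonate/pH chemistry coupled to
denitrification stoichiometry, kinetic summaries, 2^(−ΔΔCT) gene-expression
analysis, and a seeded ODE simulator of sequential denitrification that
generates every input the pipeline consumes.

## The problem

Denitrifying bacteria (here, *Thauera* strains) reduce nitrate stepwise,
NO₃⁻ → NO₂⁻ → N₂O → N₂, oxidizing acetate as the electron donor. In sealed
serum bottles (120 mL, 50 mL liquid, ~70 mL He headspace, 0.9 atm, 30 °C)
three couplings dominate the bookkeeping:

1. **Phase partitioning.** CO₂, N₂O and N₂ distribute between liquid and
   headspace according to dimensionless Henry constants H = C_aq/C_g,
   computed from tabulated solubilities with a van't Hoff temperature
   correction: H = Hcp(T)·R·T, Hcp(T) = Hcp,ref·exp(d·(1/T − 1/298.15)).
   At 30 °C the defaults give 0.726 (CO₂), 0.528 (N₂O) and 0.015 (N₂).
2. **Nitrogen recovery.** The headline statistic is the percentage of
   consumed NO₃-N recovered as N₂:
   `% = 100 · 2[N₂] / ([NO₃]ᵢ − [NO₃]f − [NO₂]f)`.
3. **pH feedback.** The balanced catabolic reaction
   `0.625 CH₃COO⁻ + NO₃⁻ + 0.375 H⁺ → 0.5 N₂ + 1.25 HCO₃⁻ + 0.5 H₂O`
   adds 1.25 mmol DIC and 1.625 meq alkalinity per mmol NO₃⁻ reduced. In a
   closed, CO₂-retaining bottle this drives the pH from 7.5 toward ~9, which
   in turn inhibits the later reduction steps — the mechanism behind
   incomplete denitrification at high nitrate loads.

The simulator integrates three Monod steps
`rᵢ = vmaxᵢ·X·Sᵢ/(ksᵢ+Sᵢ)·g_pH(pH)·g_ind,ᵢ(t)` with logistic pH inhibition
and per-step induction delays (progressive-onset strains delay steps 2–3),
with alkalinity, DIC, pH, acetate and biomass closed algebraically over the
electron flow.

## Worked example

```python
from denitkin import carbonate as carb
from denitkin.kinetics import completion_time, denitrification_rate
from denitkin.nbalance import percent_recovered_as_n2
from denitkin.simulate import preset, simulate_bottle

# 14-day bottle, rapid-onset strain, measured nitrate load, no observation noise
run = simulate_bottle(preset("K172"), initial={"no3": 0.862}, t_end=14.0, noise_cv=0.0)
tr = run.trajectory
samp = tr[tr.time_d.isin(range(15))]
done = completion_time(samp.time_d.to_numpy(), samp.no3_mM, samp.no2_mM, samp.n2o_total_mM)
print(done, denitrification_rate(0.862, done))
# 2.0 0.431

last = tr.iloc[-1]
print(round(percent_recovered_as_n2(0.862, last.no3_mM, last.no2_mM, last.n2_total_mM), 1))
# 100.0

# carbonate endpoint after complete reduction of 0.88 mmol/L NO3-
k = carb.equilibrium_constants(303.15)
dic0 = carb.dic_from_ph_ta(7.50, 2.51, k)
state = carb.apply_denitrification_stoichiometry(carb.CarbonateState(dic0, 2.51, 7.50), 0.88, k=k)
print(round(state.ph, 2), round(state.ta, 2))
# 8.94 3.94
```

The rate 0.431 mmol L⁻¹ d⁻¹ is the initial NO₃⁻ divided by the sampled
time-to-completion; the predicted endpoint pH 8.94 sits inside the measured
8.82 ± 0.08 band once the ±0.25 model tolerance is allowed for.

A command-line surface wraps the same functions:

```sh
denitkin simulate --preset NS1 --no3 0.9 --seed 7 --out bottle.csv
denitkin balance --fixture table4
denitkin carbonate --no3-reduced 0.88
```

## Analysis scripts

`analysis/01_simulate_bottles.py` … `05_qpcr_folds.py` are thin narrative
drivers over the library: simulate the triplicate 14-day experiment, audit
the nitrogen balance of both simulated bottles and the packaged printed-table
fixtures, summarize kinetics, sweep the carbonate model over nitrate loads,
and run the ΔΔCT layer on synthetic CT tables. Each writes its tables under
`results/`.

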