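# Transcription of the printed 14-day batch summary for the three strains at
# ~0.9 mmol/L initial NO3- (set 1): initial NO3-, final N2, printed recovery,
# printed yield and rate columns, growth characteristics.  sd columns are the
# printed standard errors.  Provenance: published batch-culture summary table.
strain,no3_initial_mM,no3_initial_sd,n2_final_mM,n2_final_sd,percent_recovered_printed,yield_printed,rate_printed,max_od,max_od_sd,mu_printed,mu_sd
K172,0.862,0.077,0.420,0.008,97.45,0.431,0.431,0.119,0.002,0.697,0.078
NS1,0.918,0.050,0.454,0.034,98.91,0.427,0.071,0.095,0.005,0.592,0.011
TK001,0.859,0.035,0.418,0.004,97.32,0.418,0.429,0.042,0.002,0.321,0.040
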