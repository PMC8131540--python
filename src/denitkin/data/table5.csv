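# Transcription of the printed 90-day NO3- concentration-series table:
# final products of denitrification per strain and initial NO3- level.
# "ND" (below detection) entries are stored as 0.  For the three 14-day
# (~0.9 mmol/L) rows the three-decimal initial/final values from the batch
# summary table are used, since the two-decimal entries printed here are
# roundings of those.  Provenance: published batch-culture product table.
strain,no3_initial_mM,incubation_d,no3_final_mM,max_no2_mM,max_n2o_mM,no2_final_mM,n2o_final_mM,n2_final_mM,percent_recovered_printed
K172,0.862,14,0,0.01,0,0,0,0.420,97.45
K172,1.90,90,0,0.05,0,0,0,0.92,96.64
K172,2.87,90,0,1.20,0,0,0,1.41,98.40
K172,3.62,90,0,2.56,0.23,0.20,0.23,1.41,82.46
K172,4.60,90,0,3.19,0.20,0.34,0.20,1.66,77.93
NS1,0.918,14,0,0.74,0,0,0,0.454,98.91
NS1,1.85,90,0,1.46,0.23,0,0,0.98,105.95
NS1,2.78,90,0,2.05,0.50,0,0.44,0.80,57.84
NS1,3.67,90,0,2.18,0.72,0.06,0.63,1.05,58.17
NS1,4.57,90,0,2.64,0.80,0.43,0.80,0.85,41.06
TK001,0.859,14,0,0.02,0,0,0,0.418,97.32
TK001,1.88,90,0,0.70,0,0,0,1.04,110.90
TK001,2.77,90,0,1.55,0,0,0,1.49,107.20
TK001,3.64,90,0,2.06,0.01,0,0.01,1.52,83.60
TK001,4.49,90,0,2.62,0.05,0,0.05,1.75,78.06
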