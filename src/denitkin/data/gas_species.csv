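# Default gas solubility parameters: Hcp at 298.15 K (mol L-1 atm-1),
# van't Hoff temperature coefficient d (K), Schumpe gas-specific salting-out
# coefficient h_G (L mol-1).  Literature compilation values; override by
# passing a custom table.
species,hcp_ref,vant_hoff_d,sechenov_gas
CO2,0.0334,2400,-0.0172
N2O,0.0245,2600,-0.0085
N2,0.00064,1300,-0.0010
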