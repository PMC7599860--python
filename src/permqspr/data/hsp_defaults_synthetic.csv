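# Synthetic default Hansen solubility parameter table (MPa^0.5).
# These are plausible round-number values for running the pipeline end to
# end; they are NOT measured study data.
label,role,dD,dP,dH
IPM,vehicle,16.2,3.9,3.7
OA,vehicle,16.0,2.8,6.2
HD,vehicle,16.3,0.0,0.0
IHD,vehicle,15.7,0.0,0.0
silicone,membrane,15.9,0.1,4.7
HDPE,membrane,16.9,0.8,2.8
PU,membrane,18.1,9.3,4.5
CF,permeant,19.5,10.1,13.0
MP,permeant,18.7,9.5,11.0
BP,permeant,18.1,8.4,9.4
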