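vehicle,permeant,Js_mean,Js_sd,Kp_mean,Kp_sd
Buffer,CF,4.22,0.69,0.02,0.002
Buffer,MP,26.28,0.42,1.09,0.02
Buffer,BP,17.60,0.57,7.04,0.22
IHD,CF,36.60,1.41,49.47,1.90
IHD,MP,115.6,10.54,152.61,13.9
IHD,BP,86.02,3.80,11.03,0.49
IPM,CF,14.56,1.11,1.75,0.13
IPM,MP,67.82,2.49,0.19,0.007
IPM,BP,56.11,2.27,0.06,0.002
OA,CF,11.23,0.53,0.21,0.010
OA,MP,56.27,1.06,0.86,0.02
OA,BP,54.05,1.49,0.09,0.002
HD,CF,9.43,0.53,12.74,0.71
HD,MP,47.78,2.51,60.47,3.17
HD,BP,44.61,4.61,5.95,0.61
LP,CF,9.66,0.46,12.54,0.60
LP,MP,43.24,2.94,61.77,4.19
LP,BP,26.98,1.20,3.70,0.16
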