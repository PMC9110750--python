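pft_code,eps_msh,eps_msh_sd,eps_msu,eps_msu_sd,vpd_max,vpd_min,t_opt,albedo,clumping
DBF,3.75,0.52,0.92,0.29,4.1,0.93,23.1,0.18,0.8
EBF,3.26,0.93,1.44,0.64,4.1,0.93,25.8,0.18,0.8
ENF,3.40,1.19,0.89,0.49,4.1,0.93,19.7,0.15,0.6
MF,3.00,0.66,0.80,0.41,4.1,0.93,24.5,0.17,0.7
CRO,4.80,1.94,1.43,0.75,4.1,0.93,23.5,0.23,0.9
GRA,4.57,1.67,1.16,0.45,4.1,0.93,20.9,0.23,0.9
OSH,3.10,0.42,0.65,0.07,4.1,0.93,22.3,0.16,0.8
SAV,4.65,0.64,3.45,0.64,4.1,0.93,25.8,0.18,0.8
WET,2.53,1.02,1.23,0.92,4.1,0.93,24.2,0.23,0.9
WSA,2.70,,2.60,,4.1,0.93,26.2,0.23,0.8
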