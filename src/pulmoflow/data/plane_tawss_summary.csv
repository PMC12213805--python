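region,cfd_mean_pa,cfd_min_pa,cfd_max_pa,flow4d_mean_pa,flow4d_min_pa,flow4d_max_pa
MPA,1.72,0.78,3.59,0.11,0.07,0.15
RPA,1.52,0.60,2.66,0.11,0.06,0.19
LPA,1.43,0.45,3.01,0.08,0.04,0.13
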