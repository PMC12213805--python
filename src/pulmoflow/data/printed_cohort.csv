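patient,period_s,stroke_volume_ml,rpa_fraction,mean_pap_mmhg,rpa_r1_pa_s_m3,rpa_r2_pa_s_m3,rpa_c_m3_pa,lpa_r1_pa_s_m3,lpa_r2_pa_s_m3,lpa_c_m3_pa,rpa_fraction_4dflow,rpa_fraction_cfd,lpa_fraction_4dflow,lpa_fraction_cfd,mpa_peak_velocity_4dflow_m_s,mpa_peak_velocity_cfd_m_s,tawss_whole_pa,tawss_mpa_pa
P1,0.95,95,0.62,44,1.15e7,0.71e8,9.12e-9,1.16e7,0.88e8,7.53e-9,0.62,0.62,0.38,0.38,0.327,0.349,1.62,1.25
P2,0.75,41,0.44,55,0.94e7,2.26e8,3.18e-9,0.90e7,2.27e8,3.18e-9,0.44,0.45,0.56,0.55,0.207,0.185,0.76,0.63
P3,0.92,184,0.51,27,0.44e7,0.17e8,35.04e-9,0.81e7,0.31e8,19.36e-9,0.51,0.52,0.49,0.48,0.690,0.582,3.62,2.56
P4,0.65,45,0.51,68,1.23e7,2.42e8,2.95e-9,1.25e7,2.52e8,2.83e-9,0.51,0.51,0.49,0.49,0.174,0.207,0.71,0.67
P5,0.83,84,0.61,52,0.70e7,1.84e8,3.93e-9,1.09e7,2.71e8,2.66e-9,0.61,0.63,0.39,0.37,0.266,0.278,1.77,1.60
P6,0.64,76,0.52,45,1.34e7,0.88e8,7.36e-9,1.21e7,1.35e8,5.10e-9,0.52,0.51,0.48,0.49,0.317,0.353,2.01,1.61
P7,0.69,36,0.69,49,1.59e7,1.70e8,4.03e-9,1.88e7,2.14e8,3.22e-9,0.69,0.70,0.31,0.30,0.255,0.267,1.34,1.03
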