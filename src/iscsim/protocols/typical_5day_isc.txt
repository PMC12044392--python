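# iscsim protocol file
name typical_5day_isc
duration_h 120.0
seed 1234

reference.medium.CNao 140.0
reference.medium.CKo 5.0
reference.medium.CAo 125.0
reference.medium.pHo 7.4
reference.medium.CaO 1.2
reference.medium.MgO 0.5
reference.medium.Osmo 290.0
reference.medium.temperature 37.0
reference.hb.pI_oxy 7.2
reference.hb.pI_deoxy 7.4
reference.hb.alpha -8.0
reference.hb.b1 0.0645
reference.hb.b2 0.0258
reference.buffers.ATP_total 1.8
reference.buffers.BPG_total 7.0
reference.buffers.Kd_ATP_oxy 0.08
reference.buffers.Kd_ATP_deoxy 0.14
reference.buffers.Kd_BPG_oxy 3.0
reference.buffers.Kd_BPG_deoxy 5.5
reference.buffers.ca_buffer_ratio 0.2
reference.CNa 10.0
reference.CK 130.0
reference.CHb 4.107
reference.pHi 7.24
reference.Vw 0.75
reference.Vs 0.25
reference.MgF 0.4
reference.CaF 6e-05
reference.na_pump_flux 26.0
reference.pmca_Fmax 36.0
reference.KmNa 0.25
reference.KiK 20.0
reference.KMg 0.05
reference.KmCa 0.01
reference.gardos_PKmax 32.0
reference.K05Ca 0.0032
reference.hill 3.5
reference.PA_ground 1.3
reference.PzA 50.0
reference.PzNa 0.02
reference.PzK 0.02
reference.PzMg 0.02
reference.ca_ratio 10.0
reference.kcl_rate 0.0

circulation.oxy_duration_s 30.0 60.0
circulation.deoxy_duration_s 30.0 90.0
circulation.amplitude_range 0.25 1.75
circulation.lingering_duration_s 2400.0

stage 12.0 lingering
stage 26.4 lingering
stage 84.0 lingering
stage 96.0 pump-inhibition factor=0.22
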