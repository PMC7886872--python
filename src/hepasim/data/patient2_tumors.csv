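tumor,volume_ml,k2_ml_min_100ml,k1_ml_min_100ml,segments,injection_velocity_m_s
2a,2.53,36.7,3.1,S7,0.52
2b,4.47,42.7,5.2,S8,0.45
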