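tumor,volume_ml,k2_ml_min_100ml,k1_ml_min_100ml,segments,injection_velocity_m_s
3a,63.87,96.7,12.0,S5;S6;S7,1.85
3b,8.92,129.4,11.4,S8,1.85
3c,6.21,103.4,11.9,S7;S8,1.85
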