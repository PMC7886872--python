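tumor,volume_ml,k2_ml_min_100ml,k1_ml_min_100ml,segments,injection_velocity_m_s
1a,11.64,54.7,6.9,S2;S3,0.684
1b,2.81,40.2,6.2,S8,2.01
1c,2.67,39.3,4.2,S7;S8,2.01
1d,6.22,38.3,2.3,S7,2.01
1e,15.65,41.4,5.0,S7,2.01
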