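patient,segment,tumoral_volume_ml,healthy_volume_ml
patient1,S1,0.0,62.0
patient1,S2,0.8,127.2
patient1,S3,10.8,170.2
patient1,S4a,0.0,73.0
patient1,S4b,0.0,11.0
patient1,S5,0.0,124.0
patient1,S6,0.0,169.0
patient1,S7,23.4,349.6
patient1,S8,4.0,200.0
patient2,S1,0.0,0.0
patient2,S2,0.0,119.7
patient2,S3,0.0,213.6
patient2,S4,0.0,70.0
patient2,S5,0.0,130.7
patient2,S6,0.0,119.0
patient2,S7,2.5,327.3
patient2,S8,4.5,156.8
patient3,S1,0.0,16.0
patient3,S2,0.0,204.0
patient3,S3,0.0,188.0
patient3,S4,0.0,0.0
patient3,S5,30.7,122.3
patient3,S6,0.0,82.0
patient3,S7,38.1,389.9
patient3,S8,10.2,219.8
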