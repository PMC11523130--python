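observation,pH,EC,SOC,N,P,K,Fe,Mn,Zn,Cu,earthworm_count
T1,7.34,0.12,8.62,212.9,23.5,128.5,155.6,31.1,10.40,7.10,343
T2,7.42,0.10,8.81,204.3,27.2,129.8,142.1,29.3,8.27,6.82,625
T3,7.24,0.13,9.45,227.4,26.0,144.1,156.1,38.3,9.40,8.03,766
T4,7.34,0.11,8.90,237.1,28.0,169.4,156.4,31.0,9.80,9.63,1024
T5,7.49,0.25,9.65,243.8,29.1,156.4,147.1,35.2,9.93,9.20,1130
T6,7.13,0.15,9.05,236.5,28.7,161.9,157.7,36.5,8.53,9.21,802
T7,7.24,0.30,9.36,247.4,29.7,182.2,155.6,38.7,10.87,9.90,660
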