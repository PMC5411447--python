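site,crop,solar_mj_m2,temp_c,rain_mm,rh_pct,wind_kmh
F718,napiergrass,22.8,24.5,169.9,74,15.7
F609,napiergrass,19.8,22.2,485.4,75,14.5
F410,napiergrass,22.5,23.4,305.1,75,9.7
Kula,napiergrass,16.0,19.1,426.0,80,4.4
F718,energycane,19.6,23.7,542.5,75,15
F609,energycane,21.2,23.6,613.4,73,16.5
F410,energycane,20.4,22.6,683.8,75,10.1
Kula,energycane,14.7,18.1,859.8,78,4.8
F718,sugarcane,19.6,23.6,1113.8,75,13.8
F609,sugarcane,20.2,23.6,1027.4,75,13.4
F410,sugarcane,19.6,22.9,1285.0,75,9.9
Kula,sugarcane,15.1,18.2,1585.7,78,5.2
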