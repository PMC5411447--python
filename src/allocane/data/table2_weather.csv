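site,crop,solar_mj_m2,temp_c,rain_mm,rh_pct,wind_kmh
F718,napiergrass,25.0,23.4,21.1,69,17.8
F718,energycane,20.7,22.7,157.2,71,16.1
F718,sugarcane,21.2,22.7,236.2,71,16.0
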