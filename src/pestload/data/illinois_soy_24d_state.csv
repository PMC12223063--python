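year,region,soybean_area_km2,use_kg
2017,Illinois,42896.72,482621.89
2020,Illinois,41682.66,987016.19
2023,Illinois,41885.00,2111470.76
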