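code,name,fahp_weight,entropy,ewm_weight,integrated_weight
1.1,"Reproductive, Maternal, New-born, and Child Health",20.63,1.47,17.37,19.0
1.2,Infectious Diseases,19.53,1.54,19.99,19.76
1.3,Non-communicable Diseases and Mental Health,15.88,1.49,18.16,17.02
1.4,Injuries and Violence,13.49,1.27,9.95,11.72
1.5,Universal Health Coverage and Health Systems,17.47,1.51,19.01,18.24
1.6,Health Risk,13.01,1.42,15.52,14.27
2.1,Animal Epidemic Disease,31.87,2.01,46.69,39.28
2.2,"Animal Welfare, Relevant Regulations, and Policy Support",24.66,1.13,5.77,15.22
2.3,Animal Nutritional Status,17.36,1.13,5.81,11.59
2.4,Animal Biodiversity,26.11,1.9,41.72,33.91
3.1,Air Quality and Climate Change,23.82,1.66,21.44,22.63
3.2,Land Resources,19.55,1.58,18.95,19.25
3.3,Sanitation and Water Resources,20.68,1.68,22.24,21.46
3.4,Hazardous Chemicals,17.52,1.56,18.12,17.82
3.5,Environmental Biodiversity,18.42,1.59,19.25,18.83
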