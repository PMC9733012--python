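code,name,level,category,weight_percent
1,Human Health,1,none,33.33
1.1,"Reproductive, Maternal, New-born, and Child Health",2,none,19.0
1.1.1,Maternal Health,3,none,25.0
1.1.2,Neonatal Health,3,none,25.0
1.1.3,Child Health,3,none,25.0
1.1.4,Adolescent Fertility,3,none,25.0
1.2,Infectious Diseases,2,none,19.76
1.2.1,Tuberculosis,3,none,20.0
1.2.2,HIV,3,none,20.0
1.2.3,Malaria,3,none,20.0
1.2.4,Neglected Tropical Diseases,3,none,20.0
1.2.5,COVID-19,3,none,20.0
1.3,Non-communicable Diseases and Mental Health,2,none,17.02
1.3.1,Cardiovascular Disease,3,none,20.0
1.3.2,Neoplasms,3,none,20.0
1.3.3,Diabetes Mellitus,3,none,20.0
1.3.4,Chronic Respiratory Disease,3,none,20.0
1.3.5,Suicide,3,none,20.0
1.4,Injuries and Violence,2,none,11.72
1.4.1,Road Traffic,3,none,33.33
1.4.2,Unintentional Poisoning,3,none,33.33
1.4.3,Homicide,3,none,33.33
1.5,Universal Health Coverage and Health Systems,2,none,18.24
1.5.1,Health Coverage,3,none,25.0
1.5.2,Research and Development Expenditures on Health Issues,3,none,25.0
1.5.3,Domestic Health Expenditures,3,none,25.0
1.5.4,Infant Vaccination,3,none,25.0
1.6,Health Risk,2,none,14.27
1.6.1,"Unsafe or Unimproved Water, Sanitation and Hygiene",3,none,33.33
1.6.2,Household Air Pollution,3,none,33.33
1.6.3,Occupational Risks,3,none,33.33
2,Animal Health,1,none,33.33
2.1,Animal Epidemic Disease,2,none,39.28
2.1.1,Diseases of Domestic Animals,3,none,50.0
2.1.2,Diseases of Wild Animals,3,none,50.0
2.2,"Animal Welfare, Relevant Regulations, and Policy Support",2,none,15.22
2.2.1,Overexploited or Collapsed Stocks Fish,3,none,50.0
2.2.2,Trawling or Dredging Fish,3,none,50.0
2.3,Animal Nutritional Status,2,none,11.59
2.3.1,Chicken Meat Production Efficiency,3,none,25.0
2.3.2,Pig Meat Production Efficiency,3,none,25.0
2.3.3,Cattle Production Efficiency,3,none,25.0
2.3.4,Cattle Milk Production Efficiency,3,none,25.0
2.4,Animal Biodiversity,2,none,33.91
2.4.1,Endemic Mammal Species,3,none,16.67
2.4.2,Endemic Bird Species,3,none,16.67
2.4.3,Endemic Amphibian Species,3,none,16.67
2.4.4,Endemic Reef-forming Coral Species,3,none,16.67
2.4.5,Endemic Freshwater Crab Species,3,none,16.67
2.4.6,Endemic Shark and Ray Species,3,none,16.67
3,Environmental Health,1,none,33.33
3.1,Air Quality and Climate Change,2,none,22.63
3.1.1,Ambient Particulate Matter Pollution,3,none,20.0
3.1.2,Household Solid Fuels,3,none,20.0
3.1.3,Ambient Ozone Pollution,3,none,20.0
3.1.4,Climate Risk,3,none,20.0
3.1.5,Greenhouse Gas,3,none,20.0
3.2,Land Resources,2,none,19.25
3.2.1,Area at Risk Elevation,3,none,20.0
3.2.2,Tree Cover Loss,3,none,20.0
3.2.3,Grassland Loss,3,none,20.0
3.2.4,Wetland Loss,3,none,20.0
3.2.5,Mineral Depletion,3,none,20.0
3.3,Sanitation and Water Resources,2,none,21.46
3.3.1,Freshwater,3,none,33.33
3.3.2,Clean Drinking Water,3,none,33.33
3.3.3,Renewable Internal Freshwater Resources,3,none,33.33
3.4,Hazardous Chemicals,2,none,17.82
3.4.1,Fertilizer Consumption,3,none,14.28
3.4.2,Controlled Solid Waste,3,none,14.28
3.4.3,SO2 Growth,3,none,14.28
3.4.4,NOX Growth,3,none,14.28
3.4.5,Wastewater Treatment,3,none,14.28
3.4.6,Electronic Waste,3,none,14.28
3.4.7,Non-recycled Municipal Solid Waste,3,none,14.28
3.5,Environmental Biodiversity,2,none,18.83
3.5.1,Protected Areas Representativeness,3,none,33.33
3.5.2,Species Habitat,3,none,33.33
3.5.3,Biodiversity Habitat,3,none,33.33
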