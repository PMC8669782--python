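subregion,sex,risk_factor,ratio,ratio_lower,ratio_upper
Andean Latin America,men,BMI,80.6,93.13,68.92
Andean Latin America,men,SBP,44.68,48.16,42.23
Andean Latin America,men,TC,59.37,84.25,49.33
Andean Latin America,men,non-HDL,56.81,78.6,47.26
Andean Latin America,women,BMI,76.52,92.02,61.19
Andean Latin America,women,SBP,30.91,32.1,29.88
Andean Latin America,women,TC,44.74,79.54,34.85
Andean Latin America,women,non-HDL,45.45,73.56,35.61
Caribbean,men,BMI,83.16,93.61,74.13
Caribbean,men,SBP,52.09,54.74,49.61
Caribbean,men,TC,61.97,82.8,53.24
Caribbean,men,non-HDL,60.82,78.78,51.96
Caribbean,women,BMI,76.59,90.99,62.47
Caribbean,women,SBP,39.85,41.12,38.13
Caribbean,women,TC,47.95,78.35,38.54
Caribbean,women,non-HDL,48.32,74.04,38.59
Central Latin America,men,BMI,81.38,93.17,70.62
Central Latin America,men,SBP,49.42,53.42,46.58
Central Latin America,men,TC,62.11,85.04,52.1
Central Latin America,men,non-HDL,58.64,78.74,49.75
Central Latin America,women,BMI,73.75,90.36,58.53
Central Latin America,women,SBP,32.09,34.67,30.34
Central Latin America,women,TC,42.6,75.62,32.86
Central Latin America,women,non-HDL,42.35,71.54,32.92
Southern and Tropical Latin America,men,BMI,80.52,92.13,71.23
Southern and Tropical Latin America,men,SBP,53.45,57.38,50.65
Southern and Tropical Latin America,men,TC,65.16,82.14,57.45
Southern and Tropical Latin America,men,non-HDL,62.64,78.71,55.13
Southern and Tropical Latin America,women,BMI,71.96,89.25,56.86
Southern and Tropical Latin America,women,SBP,34.44,38.71,32.06
Southern and Tropical Latin America,women,TC,43.84,74.54,34.4
Southern and Tropical Latin America,women,non-HDL,45.31,72.8,35.75
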