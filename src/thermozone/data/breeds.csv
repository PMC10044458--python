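breed,cover,thi_limit
Rabo Largo,hair,81.93
Morada Nova,hair,80.81
Somali,hair,80.64
Bergamácia,wool,79.40
Cariri,hair,79.34
Santa Inês,hair,78.27
Dorper,hair,78.26
White Dorper,hair,76.96
SAMM,wool,75.92
Suffolk,wool,74.61
Poll Dorset,wool,74.55
East Friesian,wool,74.55
Texel,wool,73.67
Border Leicester,wool,72.77
Lacaune,wool,72.72
Merino,wool,72.66
Corriedale,wool,72.63
Ilê de France,wool,72.63
Karakul,wool,72.40
Crioula,wool,72.10
Hampshire,wool,71.99
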