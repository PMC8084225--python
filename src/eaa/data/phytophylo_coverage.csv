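fdp,species_found,species_not_found,printed_fraction
BCI,266,54,0.8313
Changbaishan,26,26,0.5
Fushan,45,66,0.4054
Gutianshan,117,42,0.7358
Heishiding,132,166,0.443
Korup,117,390,0.2308
Lambir,209,1127,0.1564
Luquillo,130,32,0.8025
Mudumalai,33,50,0.3976
Nonggang,82,135,0.3779
Palanan,49,267,0.1551
Pasoh,190,708,0.2116
Sinharaja,33,206,0.1381
Tiantong,105,51,0.6731
Windriver,17,0,1
Wytham,19,5,0.7917
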