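species,worker_type,surface_area_mm2,applied_load_N,feeding_habit,apical_capable
Acanthognathus brevicornis,Normal,0.116002,0.0343,Specialized predator,False
Acromyrmex aspersus,Normal,0.777902,0.2300,Leaf-cutting,True
Azteca sp.,Normal,0.161742,0.0478,Omnivorous,True
Bothroponera fugax,Normal,0.265897,0.0786,Generalized predator,True
Camponotus zenon,Normal,0.463858,0.1372,Omnivorous,True
Carebara sp.01,Major,1.191900,0.3524,Generalized predator,True
Carebara sp.01,Normal,0.130098,0.0385,Generalized predator,True
Cephalotes pusillus,Normal,0.090715,0.0268,Omnivorous,True
Dorymyrmex sp.,Normal,0.056881,0.0168,Omnivorous,True
Eciton burchellii,Major,3.382100,1.0000,Generalized predator,False
Eciton burchellii,Media,0.444433,0.1314,Generalized predator,False
Ectatomma edentatum,Normal,2.132400,0.6305,Generalized predator,True
Formica fusca,Normal,0.466144,0.1378,Omnivorous,True
Heteroponera dentinodis,Normal,0.244014,0.0721,Omnivorous,True
Holcoponera striatula,Normal,0.300672,0.0889,Generalized predator,True
Lasius niger,Normal,0.234028,0.0692,Omnivorous,True
Lenomyrmex foveolatus,Normal,0.066555,0.0197,Generalized predator,True
Lophomyrmex sp.01,Normal,0.254868,0.0754,Generalized predator,True
Myrmica ruginodis,Normal,0.142068,0.0420,Generalized predator,True
Octostruma petiolata,Normal,0.100413,0.0297,Generalized predator,True
Odontomachus chelifer,Normal,2.821800,0.8343,Specialized predator,False
Parasyscia sp.,Normal,0.149357,0.0442,Generalized predator,True
Pheidole aper,Major,0.409701,0.1211,Omnivorous,True
Pheidole aper,Normal,0.090171,0.0267,Omnivorous,True
Platythyrea cribrinodis,Normal,1.269600,0.3754,Generalized predator,True
Solenopsis sp.04,Normal,0.082008,0.0242,Omnivorous,True
Strumigenys denticulata,Normal,0.086116,0.0255,Specialized predator,False
Wasmannia affinis,Normal,0.024214,0.0072,Omnivorous,True
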