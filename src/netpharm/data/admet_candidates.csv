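compound_id,herb,smiles,hia,caco2,cyp_1a2,cyp_2c9,cyp_2d6,cyp_2c19,cyp_3a4,published_score
Majudin,,,0.9933,0.6835,0.9774,0.8257,0.8931,0.9296,0.7959,3.48407919
Bergapten,,,0.9964,0.5379,0.9107,0.8949,0.8931,0.8994,0.8123,3.47147818
Sesamin,,,1,0.5774,0.9106,0.8949,0.8932,0.8994,0.796,3.46096872
Suchilactone,,,0.9884,0.7833,0.6598,0.9399,0.8096,0.9801,0.9591,3.39143188
Isorhamnetin,,,0.9783,0.8866,0.9218,0.756,0.6993,0.8648,0.7348,3.12557861
Ammidin,,,0.9962,0.5187,0.8503,0.7199,0.7115,0.8977,0.7497,3.08492296
8-Geranoxy-5-methoxypsoralen,,,0.9924,0.5556,0.8058,0.7084,0.788,0.8398,0.7848,3.0808701
Cnidilin,,,0.9925,0.5243,0.8169,0.5477,0.641,0.8984,0.6951,2.82470425
Naringenin,,,0.967,0.7533,0.9106,0.8949,-0.7463,0.8994,0.8988,2.12533827
Genkwanin,,,0.9921,0.929,0.9378,0.9385,-0.8253,0.9012,0.7232,2.00309141
Diosmetin,,,0.9783,0.8866,0.9218,0.756,-0.6993,0.8648,0.7348,1.92963575
Chrysoeriol,,,0.9783,0.8866,0.9218,0.756,-0.6993,0.8648,0.7348,1.92963575
Kaempferide,,,0.9783,0.8866,0.9218,0.756,-0.6993,0.8648,0.7348,1.92963575
Syringetin,,,0.9719,0.8896,0.8668,0.6258,-0.6249,0.8187,0.7817,1.83717389
4'-Methylpinosylvin,,,0.9968,0.9191,0.9614,0.903,-0.8899,0.886,0.5,1.78240889
Dehydrodieugenol,,,0.9721,0.8004,0.744,0.797,-0.7521,0.9261,0.6365,1.75847413
Moracin M,,,0.9964,0.6043,0.9061,0.7842,-0.8215,0.7031,0.804,1.74936332
Kaempferol,,,0.9855,0.7447,0.9108,0.8948,-0.9083,0.6434,0.7241,1.66803093
Morin,,,0.9855,0.7447,0.9108,0.8948,-0.9083,0.6434,0.7241,1.66803093
Notoptol,,,0.9762,0.5537,0.7233,0.7758,-0.6654,0.7588,0.6368,1.66419893
Dihydroresveratrol,,,0.9503,0.8604,0.7749,0.742,-0.8326,0.8434,0.7201,1.65802923
Cis-resveratrol,,,0.9952,0.8915,0.9106,0.7068,-0.9226,0.8052,0.7539,1.65443638
Cis-pinosylvin,,,0.9948,0.9014,0.9177,0.6648,-0.9171,0.8322,0.6678,1.5974595
Oxysanguinarine,,,0.9841,0.7216,0.8373,-0.8557,0.5126,0.7982,0.669,1.50874759
alpha-Viniferin,,,1,0.6216,0.9277,0.9497,-0.7239,0.8042,-0.6358,1.13587144
"1H,3H-Furo[3,4-c]furan-3a(4H)-ol, dihydro-1,4-bis(4-hydroxy-3-methoxyphenyl)-, (1R,3aS,4S,6aR)-",,,0.5176,0.6408,0.6819,0.5427,-0.8266,0.5876,0.542,1.10669817
Isoflavone,,,1,0.8727,0.9662,0.7441,-0.9436,0.9213,-0.6675,0.88838768
"4,7-Dihydroxy-5-methoxyl-6-methyl-8-formyl-flavan",,,0.9889,0.9077,0.7694,0.565,-0.6802,0.7659,-0.6223,0.71368052
"6,8-Dihydroxy-7-methoxyxanthone",,,0.9306,0.9044,0.9724,-0.6549,-0.6476,0.6923,0.6321,0.67863562
(-)-Medioresinol,,,0.9944,0.763,-0.5381,0.6912,-0.8313,0.7443,0.5296,0.34602068
(+)-Medioresinol,,,0.9944,0.763,-0.5381,0.6912,-0.8313,0.7443,0.5296,0.34602068
Torachrysone,,,0.9803,0.92,0.9469,-0.7326,-0.8119,0.5056,0.5459,0.2491008
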