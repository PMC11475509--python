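reference,r1ox_1e4,b0_tesla,temp_celsius,material,temperature_assumed,comments
"Matsumoto et al., 2006",2.17,4.7,37,saline,false,
"Zaharchuk et al., 2005",2.7,1.5,37,saline,false,
"d'Othee et al., 2003",1.38,8.45,21,saline,false,
"d'Othee et al., 2003",1.90,1.5,21,saline,false,
"Kramer et al., 2013",2.82,1.5,37,saline,true,temperature not reported; assumed 37 C
"Kramer et al., 2013",2.21,3,37,saline,true,temperature not reported; assumed 37 C
"Simpson et al., 2013",3.6,1.5,35,saline,false,
"Pilkinton et al., 2012",1.61,3,37,water,false,
"Vatnehol et al., 2020",1.9,3,22,water,false,
"Nestle et al., 2003",4.2,0.5,22,water,false,
"Hausser and Noack, 1965",3.72,0.63,22,water,false,
"Zaharchuk et al., 2006",2.49,1.5,37,water,false,
"Graf et al., 1980",6.60,0.011,25,water,false,
"Graf et al., 1980",6.60,0.031,25,water,false,
"Graf et al., 1980",6.23,0.051,25,water,false,
"Graf et al., 1980",6.60,0.137,25,water,false,
"Graf et al., 1980",6.13,0.259,25,water,false,
"Graf et al., 1980",5.18,0.525,25,water,false,
"Graf et al., 1980",3.68,0.713,25,water,false,
"Graf et al., 1980",3.89,0.159,25,water,false,suspect field strength: breaks the otherwise monotone Graf dispersion series and is out of the series' increasing-field ordering; erratum value 1.059 T applied by load_table1(corrected=True)
"Graf et al., 1980",2.74,2.139,25,water,false,
"Graf et al., 1980",2.51,4.387,25,water,false,
"Muir et al., 2013",2.04,3,34,water,false,
"Muir et al., 2013",2.05,3,37,water,false,
"Muir et al., 2013",2.11,3,40,water,false,
"Simpson et al., 2013",3.47,1.5,35,vitreous,false,
"d'Othee et al., 2003",1.11,8.45,21,plasma,false,
"Hueckel et al., 2000",3.38,1.5,37,plasma,false,
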