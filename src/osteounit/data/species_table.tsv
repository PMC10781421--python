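id	species	habitat	body_mass_kg	thickness_mm	n_histology	n_microct	n_biomech
1	Rat (Rattus sp)	terrestrial	0.26	0.21	4	3	0
2	European Badger (Meles meles)	terrestrial	13.2	0.84	1	1	1
3	Tufted deer (Elaphodus cephalophus)	terrestrial	23	1.30	1	0	0
4	Indian crested porcupine (Hystrix indica)	terrestrial	24.5	0.5	1	1	0
5	Cheetah (Acinonyx jubatus)	terrestrial	25.5	0.48	1	1	2
6	Harbor porpoise (Phocoena phocoena)	aquatic	54.5	1.11	9	9	9
7	Harbor seal (Phoca vitulina)	aquatic	67.5	1.77	2	2	2
8	Shetland pony (Equus ferus caballus)	terrestrial	175	1.17	2	2	0
9	Striped dolphin (Stenella coeruleoalba)	aquatic	180	1.37	1	1	1
10	Onager (Equus hemionus)	terrestrial	203	0.89	1	1	0
8b	Horse (Equus ferus caballus)	terrestrial	550	1.38	2	2	0
11	Rothschild's giraffe (Giraffa camelopardalis)	terrestrial	1070	1.85	2	1	2
12	White rhinoceros (Ceratotherium simum)	terrestrial	1475	2.16	1	1	0
13	Common minke whale (Balaenoptera acutorostrata)	aquatic	5100	5.05	2	0	0
14	Sperm whale (Physeter macrocephalus)	aquatic	47300	6.51	3	3	3
15	Fin whale (Balaenoptera physalus)	aquatic	48000	7.53	1	1	1
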