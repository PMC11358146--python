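index	start_s	end_s	label	title	composer
1	0	29	neutral	Water music - passepied	Handel
2	31	65	sad	Kol Nidrei	Bruch
3	67	109	neutral	Violin romance no.2 in F major	Beethoven
4	111	147	happy	Radetzky march	Strauss
5	149	183	neutral	L'oiseau prophete	Schumann
6	185	225	sad	Suite for violin and orchestra in A minor	Sinding
7	227	259	neutral	Clair de lune	Debussy
8	261	301	happy	A little night music - allegro	Mozart
9	303	337	neutral	Water music menuet	Handel
10	339	381	sad	Concerto de Aranjuez - Adagio	Rodrigo
11	383	425	neutral	The Planets - Venus	Holst
12	427	467	happy	A little night music - Rondo Allegro	Mozart
13	469	507	neutral	La Traviata - Prelude to the 1st scene	Verdi
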