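mutation	p1	p2	p3	p4	p5	p6	p7	p8	p9	p10	total
Ala30Pro	0	0	2	1	1	0	1	0	1	1	7
Gly33Arg	0	0	1	0	1	0	1	1	0	0	4
Tyr40Asn	0	0	2	1	0	1	1	0	1	0	6
Tyr40Ser	1	0	2	1	0	1	1	0	1	0	7
Asn42Lys	1	0	2	0	0	1	1	1	1	0	7
Ala44Thr	0	0	0	0	0	1	0	0	0	0	1
Leu59Phe	1	0	1	1	0	0	1	0	0	0	4
Ser66Trp	0	1	2	0	0	0	1	0	0	0	4
Ser68Arg	0	0	2	0	1	0	1	1	1	0	6
Thr79Pro	0	0	2	0	0	0	1	1	1	0	5
His84Tyr	1	0	2	1	0	0	1	1	0	0	6
His84Arg	1	0	2	1	0	0	1	0	0	0	5
Gln85Arg	0	0	0	1	0	0	1	1	0	0	3
Met88Thr	0	0	1	0	0	0	0	0	1	0	2
Gly90Arg	0	0	2	0	0	0	1	1	0	0	4
Ser106Arg	0	0	2	0	0	0	1	1	1	0	5
Thr118Pro	0	0	2	1	0	0	1	1	1	0	6
Gly122Arg	0	0	2	1	1	0	1	1	1	0	7
Pro128Leu	1	1	2	0	1	0	1	0	0	0	6
Val131Met	0	0	0	0	0	0	0	0	0	0	0
Thr139Met	0	0	2	1	0	0	0	0	0	0	3
Leu146Pro	0	0	0	1	0	1	1	1	0	0	4
Arg150Gln	0	0	2	1	0	1	1	1	0	0	6
Arg150Trp	0	1	2	1	0	1	0	1	0	0	6
Arg150Gly	0	0	2	1	0	1	1	1	0	0	6
Leu163Pro	1	0	2	1	0	0	1	1	0	0	6
Asp179Asn	1	0	2	0	1	0	0	1	0	0	5
Pro180Leu	0	0	2	0	1	0	1	0	0	0	4
Arg182Cys	1	0	2	0	1	0	1	1	0	0	6
Gly191Arg	0	0	2	0	0	0	1	1	0	0	4
Phe193Leu	0	0	0	0	0	0	1	0	0	0	1
Arg206Pro	1	0	0	1	0	0	1	1	0	0	4
Phe225Leu	0	0	1	0	0	0	1	0	0	0	2
Pro227Arg	0	1	1	0	0	0	1	1	0	0	4
Ala234Gly	1	0	0	1	0	0	0	0	0	0	2
Asp235Asn	1	0	0	1	0	0	0	1	0	0	3
Asp235Val	1	1	2	1	0	0	0	1	0	0	6
Arg245His	1	0	2	1	0	0	1	0	0	0	5
Arg245Met	1	1	2	1	0	0	1	1	0	0	7
Asp247His	0	1	2	1	0	0	0	1	1	0	6
Asp247Tyr	0	1	2	1	0	0	1	1	1	0	7
Gly251Ala	0	1	2	1	0	0	0	0	0	0	4
Thr271Met	0	1	0	1	1	0	0	0	1	0	4
Gly275Arg	0	0	2	0	1	0	1	1	1	0	6
Arg282Lys	0	1	0	0	1	0	0	0	0	1	3
Tyr286Ser	1	0	2	0	0	0	1	0	0	0	4
Pro288Ser	0	0	0	1	0	0	1	0	0	0	2
Pro288Leu	1	1	2	1	0	0	1	0	0	0	6
Glu292Lys	0	0	2	1	0	0	1	1	0	0	5
Pro293Ser	0	1	2	1	0	0	1	0	1	0	6
Pro293Thr	0	1	2	1	0	0	1	0	1	0	6
Ser298Pro	0	0	1	0	0	0	1	1	0	0	3
Glu300Val	0	0	0	0	0	0	0	1	0	0	1
Arg304Leu	0	0	2	1	0	0	1	1	0	0	5
Gln307Pro	1	0	0	0	0	0	1	1	0	0	3
Ala311Asp	1	0	0	1	0	0	0	1	0	0	3
Asp317His	0	0	2	1	0	0	0	1	1	0	5
Thr321Ala	0	0	2	1	0	0	0	0	1	0	4
Ile322Ser	1	0	0	1	0	0	0	0	0	0	2
Ser347Phe	1	1	2	0	0	0	1	0	0	0	5
Ser347Tyr	1	1	2	0	0	0	1	0	0	0	5
Ala354Pro	0	0	0	0	0	0	1	1	0	0	2
Glu355Lys	0	0	0	0	0	0	1	1	1	0	3
Ser364Arg	0	0	2	1	0	0	1	1	0	0	5
Glu369Lys	0	0	2	0	1	0	1	1	0	0	5
Tyr374His	0	0	2	1	0	0	1	1	0	0	5
Met376Arg	1	0	2	1	0	0	1	1	0	0	6
Arg377Cys	1	0	2	1	0	0	1	1	0	0	6
Arg377His	1	0	2	1	0	0	1	0	0	0	5
Arg377Leu	0	0	2	1	0	0	1	1	0	0	5
Gln380Arg	0	0	0	1	0	0	1	1	0	0	3
Leu386Arg	0	0	2	1	0	0	1	1	0	0	5
Asn389Lys	1	0	2	1	0	0	1	1	0	0	6
Asn389Ser	1	1	2	1	0	0	0	0	0	0	5
Leu411Arg	0	0	0	1	0	0	1	1	0	0	3
Thr415Pro	0	0	0	1	0	1	1	0	0	0	3
Thr421Arg	1	0	0	0	0	0	1	1	0	0	3
Arg433Gln	0	0	2	0	0	0	1	1	1	0	5
Arg433Trp	0	1	2	0	0	0	0	1	1	0	5
Asp440Gly	0	0	2	1	0	0	0	1	0	0	4
Asp444Gly	0	0	2	0	0	0	1	1	0	0	4
Glu447Lys	0	0	2	0	0	0	1	1	0	0	4
Arg456His	1	0	0	1	0	0	1	0	0	0	3
Gln472His	0	0	1	1	0	0	0	1	0	0	3
Asp477Glu	1	0	2	0	0	0	0	1	0	0	4
Val486Phe	1	0	2	1	0	0	1	0	0	1	6
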