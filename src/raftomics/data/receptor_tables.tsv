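symbol	condition	protein_type	location
Cd4	control	Transmembrane receptor	Plasma membrane
Celsr2	control	G-protein coupled receptor	Plasma membrane
Celsr3	control	G-protein coupled receptor	Plasma membrane
Chrm5	control	G-protein coupled receptor	Plasma membrane
Chrnb3	control	Transmembrane receptor	Plasma membrane
Chrnb4	control	Transmembrane receptor	Plasma membrane
Chrng	control	Transmembrane receptor	Plasma membrane
Cldn4	control	Transmembrane receptor	Plasma membrane
Clecsf6	control	Transmembrane receptor	Plasma membrane
Cnr1	control	G-protein coupled receptor	Plasma membrane
Cntfr	control	Transmembrane receptor	Plasma membrane
Cxadr	control	Transmembrane receptor	Plasma membrane
Dag1	control	Transmembrane receptor	Plasma membrane
Ednrb	control	G-protein coupled receptor	Plasma membrane
Fshr	control	G-protein coupled receptor	Plasma membrane
Fzd9	control	G-protein coupled receptor	Plasma membrane
Gabbr1	control	G-protein coupled receptor	Plasma membrane
Gabrr3	control	Transmembrane receptor	Plasma membrane
Gcgr	control	G-protein coupled receptor	Plasma membrane
Gfra1	control	Transmembrane receptor	Plasma membrane
Gfra3	control	Transmembrane receptor	Plasma membrane
Gpr116	control	G-protein coupled receptor	Plasma membrane
Gpr141	control	G-protein coupled receptor	Plasma membrane
Gprc6a	control	G-protein coupled receptor	Plasma membrane
Grm4	control	G-protein coupled receptor	Plasma membrane
Grm5	control	G-protein coupled receptor	Plasma membrane
Cbp	control	G-protein coupled receptor	Plasma membrane
Oprd1	control	G-protein coupled receptor	Plasma membrane
Osmr	control	Transmembrane receptor	Plasma membrane
Prom2	control	Transmembrane receptor	Plasma membrane
Prph2	control	Transmembrane receptor	Plasma membrane
Ptger2	control	G-protein coupled receptor	Plasma membrane
Pthr2	control	G-protein coupled receptor	Plasma membrane
Sfrp4	control	Transmembrane receptor	Plasma membrane
Smo	control	G-protein coupled receptor	Plasma membrane
Sstr2	control	G-protein coupled receptor	Plasma membrane
Tacr1	control	G-protein coupled receptor	Plasma membrane
Tas2r41	control	G-protein coupled receptor	Plasma membrane
Thbd	control	Transmembrane receptor	Plasma membrane
Tlr3	control	Transmembrane receptor	Plasma membrane
Tlr4	control	Transmembrane receptor	Plasma membrane
Tlr5	control	Transmembrane receptor	Plasma membrane
Tlr6	control	Transmembrane receptor	Plasma membrane
Tlr9	control	Transmembrane receptor	Plasma membrane
Tshr	control	G-protein coupled receptor	Plasma membrane
Unc5b	control	Transmembrane receptor	Plasma membrane
Vipr2	control	G-protein coupled receptor	Plasma membrane
Adcyap1r1	case	G-protein coupled receptor	Plasma membrane
Cd36	case	Transmembrane receptor	Plasma membrane
Cd86	case	Transmembrane receptor	Plasma membrane
Cnr1	case	G-protein coupled receptor	Plasma membrane
Cxadr	case	Transmembrane receptor	Plasma membrane
Gabbr1	case	G-protein coupled receptor	Plasma membrane
Gpr1	case	G-protein coupled receptor	Plasma membrane
Gpr141	case	G-protein coupled receptor	Plasma membrane
Gpr56	case	G-protein coupled receptor	Plasma membrane
Htr2c	case	G-protein coupled receptor	Plasma membrane
Htr4	case	G-protein coupled receptor	Plasma membrane
Igf1r	case	Transmembrane receptor	Plasma membrane
Igf2r	case	Transmembrane receptor	Plasma membrane
Il1r2	case	Transmembrane receptor	Plasma membrane
Il1rapl1	case	Transmembrane receptor	Plasma membrane
Lifr	case	Transmembrane receptor	Plasma membrane
Lphn1	case	G-protein coupled receptor	Plasma membrane
Lphn2	case	G-protein coupled receptor	Plasma membrane
Lrpap1	case	Transmembrane receptor	Plasma membrane
Npr2	case	G-protein coupled receptor	Plasma membrane
Npy5r	case	G-protein coupled receptor	Plasma membrane
Omg	case	G-protein coupled receptor	Plasma membrane
Cbp	case	G-protein coupled receptor	Plasma membrane
Ptch1	case	Transmembrane receptor	Plasma membrane
Pthr2	case	G-protein coupled receptor	Plasma membrane
Robo1	case	Transmembrane receptor	Plasma membrane
Lgr7	case	G-protein coupled receptor	Plasma membrane
Tlr5	case	Transmembrane receptor	Plasma membrane
Tnfrsf14	case	Transmembrane receptor	Plasma membrane
Tshr	case	G-protein coupled receptor	Plasma membrane
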