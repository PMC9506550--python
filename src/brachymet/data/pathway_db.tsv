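node_id	name	formula	pathways	neighbors
c05	Phenylalanine	C9H11NO2	Flavonoid biosynthesis	x_cinnamate
x_cinnamate	Cinnamic acid	C9H8O2	Flavonoid biosynthesis	x_coumarate
x_coumarate	p-Coumaric acid	C9H8O3	Flavonoid biosynthesis	c21
c21	Caffeic acid	C9H8O4	Flavonoid biosynthesis	c38
c38	Ferulic acid	C10H10O4	Flavonoid biosynthesis	x_naringenin
x_naringenin	Naringenin	C15H12O5	Flavonoid biosynthesis	x_eriodictyol;x_apigenin
x_eriodictyol	Eriodictyol	C15H12O6	Flavonoid biosynthesis	x_dihydroquercetin;x_luteolin
x_dihydroquercetin	Dihydroquercetin	C15H12O7	Flavonoid biosynthesis	c33;x_quercetin
c33	(epi)Catechin	C15H14O6	Flavonoid biosynthesis	c32
c32	Procyanidin B-type dimer	C30H26O12	Flavonoid biosynthesis	c15
c15	Prodelphinidin B-type	C30H26O13	Flavonoid biosynthesis	c24
c24	(epi)Gallocatechin O-hydroxybenzoate	C22H18O9	Flavonoid biosynthesis	c25
c25	(epi)Gallocatechin 3-O-gallate	C22H18O11	Flavonoid biosynthesis
x_apigenin	Apigenin	C15H10O5	Flavone and flavonol biosynthesis	c83;c57
c83	Isovitexin	C21H20O10	Flavone and flavonol biosynthesis	c76
c76	Isovitexin 7-O-glucoside	C27H30O15	Flavone and flavonol biosynthesis
c57	Apigenin 6,8-di-C-hexoside	C27H30O15	Flavone and flavonol biosynthesis
x_luteolin	Luteolin	C15H10O6	Flavone and flavonol biosynthesis	c71;c74
c71	Isoorientin	C21H20O11	Flavone and flavonol biosynthesis	c70
c70	Isoorientin 2''-O-glucoside	C27H30O16	Flavone and flavonol biosynthesis
c74	Orientin	C21H20O11	Flavone and flavonol biosynthesis
x_quercetin	Quercetin	C15H10O7	Flavone and flavonol biosynthesis	c28
c28	Quercetin di-O-hexoside	C27H30O17	Flavone and flavonol biosynthesis	c36
c36	Quercetin O-deoxyhexosylhexoside-O-hexoside	C33H40O21	Flavone and flavonol biosynthesis
c92	Tricin	C17H14O7	Flavone and flavonol biosynthesis	c88
c88	Tricin 7-O-glucoside	C23H24O12	Flavone and flavonol biosynthesis	c89
c89	Tricin O-hexosyldeoxyhexoside	C29H34O16	Flavone and flavonol biosynthesis
c02	Tyrosine	C9H11NO3	Tyrosine metabolism	x_dopa
x_dopa	3,4-Dihydroxyphenylalanine	C9H11NO4	Tyrosine metabolism	c01
c01	Dopamine	C8H11NO2	Tyrosine metabolism	x_tyramine
x_tyramine	Tyramine	C8H11NO	Tyrosine metabolism	x_homovanillate
x_homovanillate	Homovanillic acid	C9H10O4	Tyrosine metabolism
x_pyruvate	Pyruvate	C3H4O3	Valine, leucine and isoleucine biosynthesis;2-Oxocarboxylic acid metabolism	x_oxoisovalerate;x_oxaloacetate
x_oxoisovalerate	2-Oxoisovalerate	C5H8O3	Valine, leucine and isoleucine biosynthesis	x_valine;x_isopropylmalate
x_valine	Valine	C5H11NO2	Valine, leucine and isoleucine biosynthesis
x_isopropylmalate	2-Isopropylmalate	C7H12O5	Valine, leucine and isoleucine biosynthesis	c03
c03	Leucine (Isoleucine)	C6H13NO2	Valine, leucine and isoleucine biosynthesis	x_isoleucine
x_isoleucine	Isoleucine	C6H13NO2	Valine, leucine and isoleucine biosynthesis
x_galactose	Galactose	C6H12O6	Galactose metabolism	x_galactinol;x_sucrose
x_galactinol	Galactinol	C12H22O11	Galactose metabolism	x_raffinose
x_raffinose	Raffinose	C18H32O16	Galactose metabolism	x_sucrose
x_sucrose	Sucrose	C12H22O11	Galactose metabolism	x_myoinositol
x_myoinositol	myo-Inositol	C6H12O6	Galactose metabolism	x_galactinol
x_g6p	Glucose 6-phosphate	C6H13O9P	Pentose phosphate pathway	x_6pg
x_6pg	6-Phosphogluconate	C6H13O10P	Pentose phosphate pathway	x_ru5p
x_ru5p	Ribulose 5-phosphate	C5H11O8P	Pentose phosphate pathway	x_r5p
x_r5p	Ribose 5-phosphate	C5H11O8P	Pentose phosphate pathway;Purine metabolism	x_s7p;x_imp
x_s7p	Sedoheptulose 7-phosphate	C7H15O10P	Pentose phosphate pathway
x_imp	Inosine monophosphate	C10H13N4O8P	Purine metabolism	x_amp;x_inosine
x_amp	Adenosine monophosphate	C10H14N5O7P	Purine metabolism	x_adenosine
x_adenosine	Adenosine	C10H13N5O4	Purine metabolism	x_inosine
x_inosine	Inosine	C10H12N4O5	Purine metabolism	x_xanthosine
x_xanthosine	Xanthosine	C10H12N4O6	Purine metabolism	x_urate
x_urate	Urate	C5H4N4O3	Purine metabolism
x_pyridoxine	Pyridoxine	C8H11NO3	Vitamin B6 metabolism	x_pyridoxal
x_pyridoxal	Pyridoxal	C8H9NO3	Vitamin B6 metabolism	x_plp
x_plp	Pyridoxal 5-phosphate	C8H10NO6P	Vitamin B6 metabolism	x_pyridoxamine
x_pyridoxamine	Pyridoxamine	C8H12N2O2	Vitamin B6 metabolism
x_ascorbate	Ascorbate	C6H8O6	Ascorbate and aldarate metabolism	x_dehydroascorbate
x_dehydroascorbate	Dehydroascorbate	C6H6O6	Ascorbate and aldarate metabolism	x_threonate
x_threonate	Threonate	C4H8O5	Ascorbate and aldarate metabolism	x_tartrate
x_tartrate	Tartrate	C4H6O6	Ascorbate and aldarate metabolism
x_glucosamine6p	Glucosamine 6-phosphate	C6H14NO8P	Amino sugar and nucleotide sugar metabolism	x_nacetylglucosamine
x_nacetylglucosamine	N-Acetylglucosamine	C8H15NO6	Amino sugar and nucleotide sugar metabolism	x_udpglucose
x_udpglucose	UDP-glucose	C15H24N2O17P2	Amino sugar and nucleotide sugar metabolism	x_udpgalactose;x_glucuronate
x_udpgalactose	UDP-galactose	C15H24N2O17P2	Amino sugar and nucleotide sugar metabolism
x_glucuronate	Glucuronate	C6H10O7	Pentose and glucuronate interconversions	x_xylose
x_xylose	Xylose	C5H10O5	Pentose and glucuronate interconversions	x_xylitol
x_xylitol	Xylitol	C5H12O5	Pentose and glucuronate interconversions	x_arabinose
x_arabinose	Arabinose	C5H10O5	Pentose and glucuronate interconversions
x_oxaloacetate	Oxaloacetate	C4H4O5	2-Oxocarboxylic acid metabolism	x_2og
x_2og	2-Oxoglutarate	C5H6O5	2-Oxocarboxylic acid metabolism	x_mtpentylmalate
x_mtpentylmalate	2-(5'-Methylthio)pentylmalate	C10H18O5S	2-Oxocarboxylic acid metabolism	x_mthexylmalate
x_mthexylmalate	2-(6'-Methylthio)hexylmalate	C11H20O5S	2-Oxocarboxylic acid metabolism
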