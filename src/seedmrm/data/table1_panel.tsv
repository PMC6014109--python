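accession	protein_name	short_name	category	genome	sequence	start	end	variant_group	detected
AtMg00510	NADH dehydrogenase iron-sulfur protein 2	NAD7	complex I	mitochondrial	LVDIGTVTAQQAK	203	215		good
AtMg00510	NADH dehydrogenase iron-sulfur protein 2	NAD7	complex I	mitochondrial	DIDSFTQQFASR	174	185		good
AtMg00510	NADH dehydrogenase iron-sulfur protein 2	NAD7	complex I	mitochondrial	GEFGVFLVSNGSNRPYR	336	352		none
AtMg00510	NADH dehydrogenase iron-sulfur protein 2	NAD7	complex I	mitochondrial	LLEFYER	141	147		good
At5g37510	NADH dehydrogenase iron-sulfur protein 1	NAD75	complex I	nuclear	FASEVAGVQDLGILGR	227	242		good
At5g37510	NADH dehydrogenase iron-sulfur protein 1	NAD75	complex I	nuclear	NPAIIVGAGLFNR	511	523		good
At5g37510	NADH dehydrogenase iron-sulfur protein 1	NAD75	complex I	nuclear	VHFSNPEDAIEVFVDGYAVK	65	84		none
At5g37510	NADH dehydrogenase iron-sulfur protein 1	NAD75	complex I	nuclear	LNEDINEEWISDK	319	331		none
At1g47260	Gamma carbonic anhydrase 2	CA2	complex I	nuclear	NYINLAQIHASENSK	206	220		good
At1g47260	Gamma carbonic anhydrase 2	CA2	complex I	nuclear	SFEQIEVER	221	229		good
At1g47260	Gamma carbonic anhydrase 2	CA2	complex I	nuclear	AIYTVGNWIR	7	16		good
At1g47260	Gamma carbonic anhydrase 2	CA2	complex I	nuclear	LTDEEIVYISQSAK	192	205		none
At5g66760	Succinate dehydrogenase flavoprotein subunit 1	SDH1-1	complex II	nuclear	AFGGQSLDFGK	160	170		good
At5g66760	Succinate dehydrogenase flavoprotein subunit 1	SDH1-1	complex II	nuclear	SSQTILATGGYGR	238	250		good
At5g66760	Succinate dehydrogenase flavoprotein subunit 1	SDH1-1	complex II	nuclear	NSNGSLPTSTIR	491	502		good
At5g66760	Succinate dehydrogenase flavoprotein subunit 1	SDH1-1	complex II	nuclear	LPGISETAAIFAGVDVTK	369	386		none
At5g40650	Succinate dehydrogenase iron-sulfur subunit 2	SDH2-2	complex II	nuclear	WNPDNPGKPELQDYK	56	70		low
At5g40650	Succinate dehydrogenase iron-sulfur subunit 2	SDH2-2	complex II	nuclear	ETTITPLPHMFVIK	131	144		none
At5g40650	Succinate dehydrogenase iron-sulfur subunit 2	SDH2-2	complex II	nuclear	ASTGGGGASLK	39	49		none
At5g40650	Succinate dehydrogenase iron-sulfur subunit 2	SDH2-2	complex II	nuclear	NPASVPGK	168	175		none
At5g65165	Succinate dehydrogenase iron-sulfur subunit 3	SDH2-3	complex II	nuclear	HLLSDPLVR	297	305		good
At5g65165	Succinate dehydrogenase iron-sulfur subunit 3	SDH2-3	complex II	nuclear	DLVVDLTNFYQQYK	165	178		none
At5g65165	Succinate dehydrogenase iron-sulfur subunit 3	SDH2-3	complex II	nuclear	GLNPASAILK	283	292		good
At5g65165	Succinate dehydrogenase iron-sulfur subunit 3	SDH2-3	complex II	nuclear	LQAITESETK	257	266		good
AtMg00220	Cytochrome b	COB	complex III	mitochondrial	DVEGGWLLR	77	85		none
AtMg00220	Cytochrome b	COB	complex III	mitochondrial	IAFYPYFYVK	225	234		none
AtMg00220	Cytochrome b	COB	complex III	mitochondrial	GLYYASYSSPR	106	116	COB_106_116	none
AtMg00220	Cytochrome b	COB	complex III	mitochondrial	GLYHASYSSPR	106	116	COB_106_116	none
At5g13440	Cytochrome b-c1 complex subunit Rieske-2	RIESKE	complex III	nuclear	AFAYFVLSGGR	112	122		none
At5g13440	Cytochrome b-c1 complex subunit Rieske-2	RIESKE	complex III	nuclear	IVYDDHNHER	93	102		none
At5g13440	Cytochrome b-c1 complex subunit Rieske-2	RIESKE	complex III	nuclear	GPAPYNLEVPTYSFLEENK	252	270		good
At5g13440	Cytochrome b-c1 complex subunit Rieske-2	RIESKE	complex III	nuclear	FVYASVLR	123	130		good
AtMg00160	Cytochrome c oxidase subunit 2	COX2	complex IV	mitochondrial	LNQISILVQR	205	214		good
AtMg00160	Cytochrome c oxidase subunit 2	COX2	complex IV	mitochondrial	LLEVDNR	161	167		good
AtMg00160	Cytochrome c oxidase subunit 2	COX2	complex IV	mitochondrial	IIVTSADVLHSWAVPSLGVK	178	197	COX2_178_197	good
AtMg00160	Cytochrome c oxidase subunit 2	COX2	complex IV	mitochondrial	IIVTSADVPHSWAVPSSGVK	178	197	COX2_178_197	none
At2g47380	Cytochrome c oxidase subunit 5C-1	COX5C-1	complex IV	nuclear	TFYDLLER	47	54		good
At2g47380	Cytochrome c oxidase subunit 5C-1	COX5C-1	complex IV	nuclear	ELFIGLALGLAAGGLWK	19	35		none
At2g47380	Cytochrome c oxidase subunit 5C-1	COX5C-1	complex IV	nuclear	VAHATLK	6	12		none
AtMg01190	ATP synthase subunit alpha	ATP1	ATP synthase	mitochondrial	AVDSLVPIGR	154	163		good
AtMg01190	ATP synthase subunit alpha	ATP1	ATP synthase	mitochondrial	TTIAIDTILNQK	178	189		good
AtMg01190	ATP synthase subunit alpha	ATP1	ATP synthase	mitochondrial	EAFPGDVFYLHSR	295	307		good
AtMg01190	ATP synthase subunit alpha	ATP1	ATP synthase	mitochondrial	GIRPAINVGLSVSR	363	376		good
At5g08670	ATP synthase subunit beta-1	ATP2-1	ATP synthase	nuclear	DAEGQDVLLFIDNIFR	322	337		none
At5g08670	ATP synthase subunit beta-1	ATP2-1	ATP synthase	nuclear	FTQANSEVSALLGR	338	351		good
At5g08670	ATP synthase subunit beta-1	ATP2-1	ATP synthase	nuclear	DAPALVDLATGQEILATGIK	194	213		good
At5g08670	ATP synthase subunit beta-1	ATP2-1	ATP synthase	nuclear	VGLTGLTVAEYFR	309	321		good
At3g22370	Alternative oxidase 1a	AOX1A	energy dissipation	nuclear	DVNHFASDIHYQGR	329	342		good
At3g22370	Alternative oxidase 1a	AOX1A	energy dissipation	nuclear	GIASYWGVEPNK	103	114		good
At3g22370	Alternative oxidase 1a	AOX1A	energy dissipation	nuclear	GNIENVPAPAIAIDYWR	290	306		none
At3g22370	Alternative oxidase 1a	AOX1A	energy dissipation	nuclear	LPADATLR	307	314		good
At5g64210	Alternative oxidase 2	AOX2	energy dissipation	nuclear	IENVAAPAIAIDYWR	291	305		none
At5g64210	Alternative oxidase 2	AOX2	energy dissipation	nuclear	VVGYLEEEAIHSYTEFLK	267	284		none
At5g64210	Alternative oxidase 2	AOX2	energy dissipation	nuclear	DVNHFASDIR	328	337		none
At5g64210	Alternative oxidase 2	AOX2	energy dissipation	nuclear	IPTDIFFQR	164	172		none
At4g04870	Cardiolipin synthase	CLS	membrane biogenesis	nuclear	DLLHPGLVGIVLLR	222	235		none
At4g04870	Cardiolipin synthase	CLS	membrane biogenesis	nuclear	DVALVGGAVYLR	236	247		none
At4g04870	Cardiolipin synthase	CLS	membrane biogenesis	nuclear	LLQSATPLHWR	73	83		none
At4g04870	Cardiolipin synthase	CLS	membrane biogenesis	nuclear	VEPLFISK	272	279		none
At5g40770	Prohibitin 3	PHB3	scaffold	nuclear	TKPHTFSSISGTK	76	88		none
At5g40770	Prohibitin 3	PHB3	scaffold	nuclear	EIASTLAR	251	258		good
At5g40770	Prohibitin 3	PHB3	scaffold	nuclear	VLSRPEVSR	99	107		good
At5g40770	Prohibitin 3	PHB3	scaffold	nuclear	AVIFDR	41	46		good
At3g01280	Mitochondrial outer membrane protein porin 1	VDAC1	transport	nuclear	FSITTFSPAGVAITSTGTK	29	47		good
At3g01280	Mitochondrial outer membrane protein porin 1	VDAC1	transport	nuclear	DSTITVGTQHSLDPLTSVK	210	228		good
At3g01280	Mitochondrial outer membrane protein porin 1	VDAC1	transport	nuclear	SFFTISGEVDTK	249	260		good
At3g01280	Mitochondrial outer membrane protein porin 1	VDAC1	transport	nuclear	EDLIASLTVNDK	167	178		none
At5g15090	Mitochondrial outer membrane protein porin 3	VDAC3	transport	nuclear	GSLFLGDVATQVK	49	61		good
At5g15090	Mitochondrial outer membrane protein porin 3	VDAC3	transport	nuclear	DDLTASLILNDK	167	178		none
At5g15090	Mitochondrial outer membrane protein porin 3	VDAC3	transport	nuclear	SFFTVSGEVDSK	247	258		good
At5g15090	Mitochondrial outer membrane protein porin 3	VDAC3	transport	nuclear	HFNAGFNFTK	157	166		good
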