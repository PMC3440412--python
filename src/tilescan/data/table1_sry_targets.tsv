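gene_symbol	accession	location	p_value	sry_motifs	category	gene_title
Higd2a	NM_001106102	chr17:16083944-16084731	2.16E-21	1	Apoptosis	HIG1 hypoxia inducible domain family, member 2A
Pdcd6ip	NM_001029910	chr8:118351413-118352013	1.59E-21	1	Apoptosis	Programmed cell death 6 interacting protein
RGD1560888	NM_001109061	chr8:40571831-40572431	5.07E-08	1	Cell Cycle	Similar to Cell division protein kinase 8
Atn1	NM_017228	chr4:160887462-160888360	1.28E-12	1	Development	Atrophin 1
Crygb	NM_001109875	chr9:63736296-63737096	2.92E-11	1	Development	Crystallin, gamma B
Lrrc68	NM_001107482	chr1:78888269-78888869	1.59E-08	2	Development	Leucine rich repeat containing 68
Lcn11	NM_001135809	chr3:3888687-3889792	8.46E-09	1	Development	Lipocalin 11
RGD1565947	NM_001106780	chr7:30717183-30717983	2.25E-09	3	Development	Similar to netrin 4
Sar1b	NM_001009622	chr10:37281198-37281897	4.60E-10	3	Development	SAR1 homolog B (S. cerevisiae)
Tex10	NM_001106653	chr5:65166327-65167127	4.78E-09	1	Development	Testis expressed 10
Pdcl3	NM_001025709	chr9:38002255-38002855	8.65E-09	3	Electron Transport	Phosducin-like 3
Cd24	NM_012752	chr20:47499009-47499609	2.95E-20	2	Immune Response	CD24 molecule
Sec1	NM_001135584	chr1:96149778-96150598	4.18E-08	1	Immune Response	Secretory blood group 1
Afg3l2	NM_001134864	chr18:63975093-63975767	6.73E-16	2	Metabolism & Transport	AFG3(ATPase family gene 3)-like 2
Exoc4	NM_053875	chr4:60405518-60406118	8.64E-09	1	Metabolism & Transport	Exocyst complex component 4
Gltp	NM_001134413	chr12:43194112-43195012	8.14E-32	1	Metabolism & Transport	Glycolipid transfer protein
Hpgds	NM_031644	chr4:94639300-94639900	2.34E-09	1	Metabolism & Transport	hematopoietic prostaglandin D synthase
Hyal1	NM_207616	chr8:112828762-112829362	4.39E-14	1	Metabolism & Transport	Hyaluronoglucosaminidase 1
Hyal3	NM_207599	chr8:112828762-112829362	4.39E-14	1	Metabolism & Transport	Hyaluronoglucosaminidase 3
Sdha	NM_130428	chr1:29738109-29738709	1.53E-10	1	Metabolism & Transport	Succinate dehydrogenase complex, A
Sdhd	NM_198788	chr8:53967070-53967670	4.44E-08	1	Metabolism & Transport	Succinate dehydrogenase complex, subunit D
Sec24a	NM_001105780	chr10:37281198-37281897	4.60E-10	3	Metabolism & Transport	SEC24 family, member A (S. cerevisiae)
Timm8b	NM_022541	chr8:53967070-53967670	4.44E-08	1	Metabolism & Transport	Translocase of inner mitochondrial membrane 8
Tmed4	NM_001107238	chr14:87002671-87003360	5.63E-08	1	Metabolism & Transport	Transmembrane emp24 protein transport 4
Tpi1	NM_022922	chr4:160936834-160937434	4.38E-11	1	Metabolism & Transport	Triosephosphate isomerase 1
Cpa2	NM_001013083	chr4:57449368-57449968	6.76E-08	1	Proteolysis	Carboxypeptidase A2 (pancreatic)
Cul2	NM_001108417	chr17:62742775-62743470	1.46E-08	2	Proteolysis	Cullin 2
LOC689226	BC167074	chr7:18614322-18614922	9.65E-11	2	Proteolysis	Similar to ubiquitin-conjugating enzyme E2R 2
Tmprss6	NM_001130556	chr7:116422114-116422899	2.30E-12	1	Proteolysis	Transmembrane protease, serine 6
Grm2	NM_001105711	chr8:111851299-111852092	5.01E-09	2	Receptors & Binding Proteins	Glutamate receptor, metabotropic 2
Il1rapl1	NM_177935	chrX:74472070-74472768	2.96E-14	4	Receptors & Binding Proteins	interleukin 1 receptor accessory protein-like 1
Olr122	NM_001000156	chr1:161468724-161469324	4.12E-08	3	Receptors & Binding Proteins	Olfactory receptor 122
Olr1553	NM_001000051	chr11:42266451-42267051	1.33E-10	1	Receptors & Binding Proteins	Olfactory receptor 553
Olr1657	NM_001000536	chr17:50544822-50545500	2.98E-08	1	Receptors & Binding Proteins	Olfactory receptor 1657
Olr463	NM_001000934	chr3:69098160-69098859	5.02E-08	1	Receptors & Binding Proteins	Olfactory receptor 463
Olr669	NM_001000349	chr3:73187159-73187759	1.57E-08	2	Receptors & Binding Proteins	Olfactory receptor 669
Olr770	NM_001000372	chr3:97220204-97221208	2.48E-09	1	Receptors & Binding Proteins	Olfactory receptor 770
Olr853	NM_001000398	chr5:70398861-70399461	9.49E-08	1	Receptors & Binding Proteins	Olfactory receptor 853
Vom1r59	AY510282	chr1:73592390-73592990	1.52E-10	1	Receptors & Binding Proteins	vomeronasal 1 receptor, 59
Vom2r11	NM_001099470	chr1:57382648-57383341	7.39E-08	2	Receptors & Binding Proteins	Vomeronasal 2 receptor 11
Vom2r8	NM_001099464	chr1:49588680-49589280	1.60E-08	2	Receptors & Binding Proteins	Vomeronasal 21 receptor 8
Jkamp	NM_001106738	chr6:94284244-94284963	1.46E-23	1	Signaling	JNK1/MAPK8-associated membrane protein
RGD1562638	NM_001100944	chr16:68750676-68751465	6.94E-22	1	Signaling	MAP/microtubule affinity-regulating kinase 3
Armc7	BC166454	chr10:105554314-105555129	5.38E-08	3	Transcription	armadillo repeat containing 7
Btbd4	NM_001107808	chr3:170570362-170570962	3.04E-09	1	Transcription	Zinc finger and BTB domain containing 46
Ccdc127	NM_198766	chr1:29738109-29738709	1.53E-10	1	Transcription	Coiled-coil domain containing 127
Gata1	NM_012764	chrX:26564683-26565464	7.55E-08	1	Transcription	GATA binding protein 1
Maff	NM_001130573	chr7:117329082-117329787	3.55E-08	1	Transcription	V-maf musculoaponeurotic fibrosarcoma F
Meis1	NM_001134702	chr14:99835529-99836129	4.65E-15	2	Transcription	Meis homeobox 1
Nop16	NM_001047095	chr17:16083944-16084731	2.16E-21	1	Transcription	NOP16 nucleolar protein homolog (yeast)
Nsfl1c	NM_031981	chr3:141798504-141799104	2.81E-08	2	Transcription	NSFL1 (p97) cofactor (p47)
Phox2a	NM_053869	chr1:159272192-159273082	4.67E-14	1	Transcription	Paired-like homeobox 2a
Rag1	NM_053468	chr3:86795336-86796015	1.34E-11	2	Transcription	Recombination activating gene 1
Rai14	NM_001011947	chr2:60062344-60063029	1.37E-09	1	Transcription	Retinoic acid induced 14
Zfp354a	NM_052798	chr10:36652409-36653009	1.28E-08	1	Transcription	Zinc finger protein 354A
Znf507	NM_001106248	chr1:88364838-88365940	3.47E-12	4	Transcription	Zinc finger protein 507
Ddx46	NM_139098	chr17:15030355-15030955	1.78E-13	3	Transcription	DEAD (Asp-Glu-Ala-Asp) box polypeptide 46
Tcf21	NM_001032397	chr1:23209070-23210356	1.76E-10	3	Transcription	Transcription factor 21/Pod1/Capsulin/Epicardin
Tsen2	NM_001014057	chr4:151669335-151669935	4.91E-08	1	Translation & Protein Modification	tRNA splicing endonuclease 2 homolog
Arfgef2	NM_181083	chr3:157964936-157965536	1.30E-10	1	Translation & Protein Modification	ADP-ribosylation factor guanine factor 2
Mrpl51	NM_001106621	chr4:161309657-161310257	4.88E-09	2	Translation & Protein Modification	Mitochondrial ribosomal protein L51
Rpl24	NM_022515	chr11:45636727-45637615	1.07E-10	1	Translation & Protein Modification	Ribosomal protein L24
Rtf1	NM_001108958	chr3:106189897-106190688	4.05E-09	1	Translation & Protein Modification	Rtf1, Paf1/RNA polymerase II complex
Cytsa	NM_001039455	chr20:13946693-13947489	1.35E-09	1	Miscellaneous & Unknown	Cytospin A
Dcaf7	NM_001107057	chr10:95425513-95426318	6.60E-12	1	Miscellaneous & Unknown	DDB1 and CUL4 associated factor 7
Fam12b	NM_178103	chr15:27107548-27108246	1.48E-11	1	Miscellaneous & Unknown	Epididymal protein 3B
LOC308990	NM_001025001	chr1:186339810-186340908	7.02E-10	3	Miscellaneous & Unknown	Hypothetical protein LOC308990
RGD1303127	NM_001004244	chr7:137280915-137281694	3.89E-12	1	Miscellaneous & Unknown	Similar to hypothetical protein FLJ20436
RGD1562533	BC127538	chr12:7302557-7303157	1.79E-08	1	Miscellaneous & Unknown	Similar to mKIAA0774 protein
RGD1305721	NM_001108031	chr6:94284244-94284963	1.46E-23	1	ESTs	Similar to RIKEN cDNA 2810055F11
LOC298139	NM_001013930	chr5:91664056-91664656	1.57E-09	1	ESTs	Similar to RIKEN cDNA 2310003M01
RGD1307325	BC082052	chr16:49407004-49407724	6.84E-08	1	ESTs	Similar to RIKEN cDNA 4933411K20
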