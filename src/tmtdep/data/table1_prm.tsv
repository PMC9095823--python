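protein_id	protein_name	gene_name	peptides	prm_ratio	tmt_ratio	regulated_type
P97864	Caspase-7	Casp7	VPTYLYR DLTAHFR	0.43	0.66	Down
Q9CPT0	Apoptosis facilitator Bcl-2-like protein 14	Bcl2l14	AQGPQGPFPVER TITDLFLR	0.43	0.65	Down
P70677	Caspase-3	Casp3	SVDSGIYLDSSYK SGTDVDAANLR	0.22	0.36	Down
Q9QZL0	Receptor-interacting serine/threonine-protein kinase 3	Ripk3	LHLEEPSGPVPGK GTTPGPVFTETPGPHPQR	0.20	0.51	Down
E9PVX6	Proliferation marker protein Ki-67	Mki67	SSGSTPVTAASSPK LPSSSPPLEPTDTSVTSR	0.29	0.76	Down
P42225	Signal transducer and activator of transcription 1	Stat1	DQQPGTFLLR ELSAVTFPDIIR	0.24	0.56	Down
P14246	Solute carrier family 2, facilitated glucose transporter member 2	Slc2a2	HVLGVPLDDR VSVIQLFTDANYR	0.67	0.74	Down
P16858	Glyceraldehyde-3-phosphate dehydrogenase	Gapdh	IVSNASCTTNCLAPLAK LISWYDNEYGYSNR	0.58	0.73	Down
P14094	Sodium/potassium-transporting ATPase subunit beta-1	Atp1b1	VAPPGLTQIPQIQK YNPNVLPVQCTGK	0.50	0.69	Down
Q9R0H0	Peroxisomal acyl-coenzyme A oxidase 1	Acox1	TQEFILNSPTVTSIK AFTTWTANAGIEECR	0.44	0.68	Down
Pnlip	Pancreatic triacylglycerol lipase	Pnlip	TTYTQATQNVR ITGLDPAEPYFQGTPEEVR	0.05	0.25	Down
Q8CGA3	Large neutral amino acids transporter small subunit 4	Slc43a2	FSWLGFDHK	0.42	0.67	Down
P14483	H-2 class II histocompatibility antigen, A beta chain	H2-Ab1	AELDTVCR TEALNHHNTLVCSVTDFYPAK	0.41	0.65	Down
P36371	Antigen peptide transporter 2	Tap2	VEFQDVSFSYPR LVEHDQLR	0.31	0.61	Down
O70570	Polymeric immunoglobulin receptor	Pigr	NVDLQVLAPEPELLYK GVTGGSVAIACPYNPK	0.34	0.54	Down
Q9R233	Tapasin	Tapbp	VYHSSLPASGR ATAASLTIPR	0.20	0.48	Down
Q64374	Regucalcin	Rgn	TTSCCFGGK DGLNAEGLLR	3.21	2.93	Up
P03958	Adenosine deaminase	Ada	ANYSLNTDDPLIFK LNINAAK	1.81	1.98	Up
Q9DCG6	Phenazine biosynthesis-like domain-containing protein 1	Pbld1	LQPTDSFTQSSR GEPGGQTAPYDFYSR	2.83	2.13	Up
Q5BKQ4	Inactive pancreatic lipase-related protein 1	Pnliprp1	GSQTTYTQAANNVR NALSQIVDIDGIWSGTR	16.17	4.74	Up
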