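trait_phrase	codes
bladder	BLCA
bladder cancer	BLCA
breast	BRCA
breast cancer	BRCA
glioma	GBM
glioblastoma	GBM
gbm	GBM
lung adenocarcinoma	LUAD
lung squamous cell carcinoma	LUSC
non-small cell lung cancer	LUAD,LUSC
lung cancer	LUAD,LUSC
crc	CRC
colorectal	CRC
colorectal cancer	CRC
endometrial	UCEC
endometrial cancer	UCEC
ovarian	OV
ovarian cancer	OV
renal cell carcinoma	KIRC
kidney renal cell carcinoma	KIRC
head and neck squamous cell carcinoma	HNSC
melanoma	SKCM
multiple myeloma	MM
basal cell carcinoma	BCC
prostate	PRAD
prostate cancer	PRAD
testicular germ cell	TGCT
cll	CLL
chronic lymphocytic leukemia	CLL
all	ALL
acute lymphoblastic leukemia	ALL
acute myeloid leukemia	LAML
nasopharyngeal carcinoma	NPC
gallbladder	GBC
hodgkin's lymphoma	HL
wilms tumor	WT
pancreatic	PAAD
pancreatic cancer	PAAD
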