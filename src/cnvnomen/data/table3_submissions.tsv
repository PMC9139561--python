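hospital_id	manufacturer	platform	wet_lab_outsourced	bioinfo_outsourced	text_dgs	text_cmt1
Hospital 1	Thermo Fisher	Ion proton	false	false	seq[GCRh37]del(22)(q11.2)#chr22:g.19009792-21452445del	seq[GCRh37]dup(17)(p12)#chr17:g.14097915-15470903dup
Hospital 2	Illumina	NovaSeq 6000	false	true	seq[GRCh37] 22q11.2(19009792_21452445)X1	seq[GRCh37] 17p12(14097915_15470903)X3
Hospital 3	Illumina	NovaSeq	false	false	There may be 22q11 microdeletion syndrome	There may be duplication on chromosome 17p12
Hospital 4	Illumina	Berry Genomics NextSeq CN500, HiSeq 2000	false	false	seq[hg19]del(22)(q11.2) chr22:g.19009792_21452445del	seq[hg19]dup(17)(p12) chr17:g.14097915_15470903dup
Hospital 5	Thermo Fisher	Ion proton	false	false	del(22)(q11.2).seq[GRCh37](19009792-21452445)×1	dup(17)(p12).seq[GRCh37](14097915-15470903)×3
Hospital 6	Thermo Fisher	Ion proton	false	true	del(22)(q11.2).seq[GRCh37/hg19](19009792-21452445)×1	dup(17)(p12).seq[GRCh37/hg19](14097915-15470903)×3
Hospital 7	Thermo Fisher	Ion proton	false	false	del(22)(q11.2).seq[GRCh37/hg19](19009792-21452445)X1	dup(17)(p12).seq[GRCh37/hg19](14097915-15470903)X3
Hospital 8	Illumina	Berry Genomics NextSeq CN500	false	false	seq[hg19]del(22)(q11.2)#chr22:g.19009792_21452445del	seq[hg19]dup(17)(p12)#chr17:g.14097915_15470903dup
Hospital 9	BGI	MGISEQ-2000	false	true	seq[GRCh37] del(22)(q11.2)chr22:g.19009792_21452445 del	seq[GRCh37] dup(17)(p12)chr17:g.14097915_15470903 dup
Hospital 10	Illumina	MiSeqDx	false	false	del(22)(q11.2).(19009792-21452445)X1	dup(17)(p12).(14097915-15470903)X3
Hospital 11	Illumina	NextSeq 500	false	false	seq[hg19] 22q11.2(19009792-21452445 )x1 CNV type: heterozygous deletion length: 2.3 Mb classification: pathogenic	seq[hg19] 17p12(14097915-15470903)x3 CNV type: duplication length: 1.3Mb classification:pathogenic
Hospital 12	BGI	MGISEQ-2000	false	true	46,XN,del(22q11.2).seq[GRCh37/hg19](19009792-21452445)x1	46,XN,dup(17p12).seq[GRCh37/hg19](14097915-15470903)x3
Hospital 15	Illumina	MiSeq	false	false	seq[GRCh37]del(22)(q11.2)(19009792-21452445)	seq[GRCh37]dup(17)(p12)(14097915-15470903)
Hospital 16	BGI	MGISEQ-2000	false	false	seq[GRCh37] del(22)(q11.21) mat/pat/dn\nchr22:g.19009792_21452445del	seq[GRCh37] dup(17)(p12) mat/pat/dn\nchr17:g.14097915_15470903dup
Hospital 17	Thermo Fisher	Ion proton	false	false	del(22)(q11.2).seq[GRCh37/hg19](19009792-21452445)X1	dup(17)(p12).seq[GRCh37/hg19](14097915-15470903)X3
Hospital 18	Illumina	NextSeq 550AR	false	false	DiGeorge syndrome #band: 22q11.2 #Genomic coordinate (GRCh37) 22:g.19009792-21452445 #type: heterozygous deletion	CMT syndrome type 1 #band: 17p12 #Genomic coordinate (GRCh37) 17:g.1409795-15470903 #type: duplication
Hospital 20	Thermo Fisher	Ion proton	false	false	seq[hg19] 22q11.21(18620001_21820000)X1	seq[hg19] 17p12(14097915_15470903)X3
Hospital 21	Illumina	NextSeq 500	false	false	seq[hg19]del(22)(q11.2) chr22:g.19009792_21452445del	seq[hg19]dup(17)(p12) chr17:g.14097915_15470903dup
Hospital 22	Illumina	Berry Genomics NextSeq CN500	false	true	DGS seq(hg19)del(22)(q11.2) chr22:g.19009792_21452445dup	CMT seq(hg19)dup(17)(p12) chr17:g.14097915_15470903dup
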