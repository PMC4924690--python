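antigen	analyses	direction
DPPA4	Differential & Venn	High
CEACAM1 Isoform 1	Differential	High
NY-ESO-1	Differential & Top 20	High
FGFR2	Differential, Venn & Shotgun	High
RAF	Differential	High
ZNF165	Differential	High
TKTL1 (Isoform a)	Differential	High
MAPK3	Differential & Top 20	High
CAMEL	Differential & Top 20	High
LDHC	Differential, Venn & Top 20	High
BORIS BO	Venn	High
SPANXA1	Linear & Venn	High
ROPN1A	Linear & Top 20	High
p53 S392A	Venn	High
p53 L344P	Differential	High
p53 C141Y	Top 20	High
p53 K328R	Differential	High
p53 S15A	Linear & Top 20	Low
p53 T18A	Top 20	High
CDK2	Differential	High
MAGEA11	Differential	High
FES	Differential & Top 20	High
OIP5	Differential & Top 20	High
SSX2A	Differential	High
GAGE5	Differential	Low
MAGEB5	Differential & Top 20	Low
EGFR	Differential	Low
CCDC33	Differential	Low
CSAG2	Differential & Venn	Low
DDX53	Differential & Venn	Low
CT47.11	Differential & Venn	Low
p53	Differential & Venn	Low
p53 Q136X	Differential & Venn	Low
MAGEB6	Differential	Low
PBK	Differential	Low
CAML1	Shotgun	High
COL6A1	Shotgun	High
GAGE1	Linear & Top 20	High
PRKCZ	Linear & Top 20	High
p53 S46A	Linear & Top 20	low
MAGEB1	Linear & Top 20	Low
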