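##gff-version 3
# Synthetic rDNA transcription-unit annotation (fission-yeast style 35S
# pre-rRNA gene). Total length 7800 nt with the 5'ETS spanning the first
# 1300 nt; the remaining subregion boundaries are plausible S. pombe
# subunit lengths, not published coordinates.
rDNA	ribopause	rRNA_primary_transcript	1	7800	.	+	.	ID=rdna_unit;Name=rdna_35S
rDNA	ribopause	region	1	1300	.	+	.	ID=r5ETS;Parent=rdna_unit;Name=5ETS
rDNA	ribopause	region	1301	3100	.	+	.	ID=r18S;Parent=rdna_unit;Name=18S
rDNA	ribopause	region	3101	3460	.	+	.	ID=rITS1;Parent=rdna_unit;Name=ITS1
rDNA	ribopause	region	3461	3620	.	+	.	ID=r5.8S;Parent=rdna_unit;Name=5.8S
rDNA	ribopause	region	3621	3860	.	+	.	ID=rITS2;Parent=rdna_unit;Name=ITS2
rDNA	ribopause	region	3861	7360	.	+	.	ID=r25S;Parent=rdna_unit;Name=25S
rDNA	ribopause	region	7361	7800	.	+	.	ID=r3ETS;Parent=rdna_unit;Name=3ETS
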