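id	substrate	product	substrate_comp	product_comp	kind	genes
PE->PC	PE	PC			headgroup_transfer	PEMT
DG->PC	DG	PC			headgroup_transfer	CHPT1
PC->PS	PC	PS			headgroup_transfer	PTDSS1
PS->LPS	PS	LPS			deacylation	PLA2G2E;PLA2G2A;PLA2G2F
PC->LPC	PC	LPC			deacylation	PLA2G2E;PLA2G2A;PLA2G2D;PLA2G2F;PLA2G1B
LPA->PA	LPA	PA			acylation	AGPAT1;AGPAT2;AGPAT3;AGPAT4;AGPAT5
PA->PG	PA	PG			headgroup_transfer	CDS1;CDS2;PTPMT1
PG->LPG	PG	LPG			deacylation	PLA2G4D;PLA2G4F;CRLS1
PC->PA	PC	PA			headgroup_transfer	PLD1;PLD2
PA->PS	PA	PS			headgroup_transfer	CDS1;PTDSS1
DG->PE	DG	PE			headgroup_transfer	CEPT1
PE->LPE	PE	LPE			deacylation	PLA2G4C
PE->PS	PE	PS			headgroup_transfer	PTDSS2
DG->PA	DG	PA			headgroup_transfer	DGKA;DGKB;DGKD;DGKE;DGKG;DGKH;DGKI;DGKK;DGKQ;DGKZ
PA->PI	PA	PI			headgroup_transfer	CDS1;CDS2;CDIPT
PC->CL	PC	CL			headgroup_transfer	TAZ
PC->DG	PC	DG			headgroup_transfer	PLCB1;PLCB2;PLCB3;PLCB4;PLCD1;PLCG1;PLCG2
PA->DG	PA	DG			headgroup_transfer	LPIN1;LPIN2;LPIN3
LPC->PC	LPC	PC			acylation	LPCAT1;LPCAT2;LPCAT3;LPCAT4
LPE->PE	LPE	PE			acylation	MBOAT1;MBOAT2
LPS->PS	LPS	PS			acylation	LPCAT3;LPCAT4
LPI->PI	LPI	PI			acylation	MBOAT7
LPG->PG	LPG	PG			acylation	LPGAT1
PI->LPI	PI	LPI			deacylation	PLA2G4A;PLA2G6
PA->LPA	PA	LPA			deacylation	PLA2G4A
PS->PE	PS	PE			headgroup_transfer	PISD
PE->PA	PE	PA			headgroup_transfer	PLD1;PLD2
CL->MLCL	CL	MLCL			deacylation	PLA2G6
MLCL->CL	MLCL	CL			acylation	LCLAT1;TAZ
PG->CL	PG	CL			headgroup_transfer	CRLS1
LPC->LPA	LPC	LPA			headgroup_transfer	ENPP2
LPE->LPA	LPE	LPA			headgroup_transfer	ENPP2
MG->DG	MG	DG			acylation	MOGAT1;MOGAT2;MOGAT3
TG->DG	TG	DG			deacylation	PNPLA2;LIPE
DG->MG	DG	MG			deacylation	PNPLA2;PNPLA3
DG->TG	DG	TG			acylation	DGAT2
O-PC->O-LPC	O-PC	O-LPC			deacylation	PLA2G4A;PLA2G7
O-LPC->O-PC	O-LPC	O-PC			acylation	LPCAT1;LPCAT2
O-PE->O-LPE	O-PE	O-LPE			deacylation	PLA2G4A
O-LPE->O-PE	O-LPE	O-PE			acylation	MBOAT2
O-DG->O-PC	O-DG	O-PC			headgroup_transfer	CHPT1
O-DG->O-PE	O-DG	O-PE			headgroup_transfer	CEPT1
O-DG->O-TG	O-DG	O-TG			acylation	DGAT1;DGAT2
O-TG->O-DG	O-TG	O-DG			deacylation	PNPLA2;LIPE
O-DG->O-MG	O-DG	O-MG			deacylation	PNPLA2
O-MG->O-DG	O-MG	O-DG			acylation	MOGAT1;MOGAT2
dhSph->dhCer	dhSph	dhCer			acylation	CERS1;CERS2;CERS3;CERS4;CERS5;CERS6
dhCer->dhSph	dhCer	dhSph			deacylation	ASAH1;ASAH2
dhCer->Cer	dhCer	Cer			sphingoid_step	DEGS1;DEGS2
dhCer->dhSM	dhCer	dhSM			sphingoid_step	SGMS1;SGMS2
dhSM->dhCer	dhSM	dhCer			sphingoid_step	SGMS1;SGMS2
Cer->SM	Cer	SM			sphingoid_step	SGMS1;SGMS2
SM->Cer	SM	Cer			sphingoid_step	SMPD1;SMPD2;SMPD3;SMPD4
Cer->Sph	Cer	Sph			deacylation	ASAH1;ASAH2
Sph->Cer	Sph	Cer			acylation	CERS1;CERS2;CERS3;CERS4;CERS5;CERS6
Cer->Cer1P	Cer	Cer1P			sphingoid_step	CERK
Cer1P->Cer	Cer1P	Cer			sphingoid_step	PLPP1;PLPP2;PLPP3
dhCer->dhCer1P	dhCer	dhCer1P			sphingoid_step	CERK
dhCer1P->dhCer	dhCer1P	dhCer			sphingoid_step	PLPP1;PLPP2;PLPP3
Sph->S1P	Sph	S1P			sphingoid_step	SPHK1;SPHK2
S1P->Sph	S1P	Sph			sphingoid_step	SGPP1;SGPP2
dhSph->dhS1P	dhSph	dhS1P			sphingoid_step	SPHK1;SPHK2
dhS1P->dhSph	dhS1P	dhSph			sphingoid_step	SGPP1;SGPP2
FA->CoA	FA	CoA			headgroup_transfer	ACSL1;ACSL3;ACSL4;ACSL5;ACSL6
CoA->FA	CoA	FA			headgroup_transfer	ACOT1;ACOT2;ACOT7
CoA->CAR	CoA	CAR			headgroup_transfer	CPT1A;CPT1B;CPT1C
CAR->CoA	CAR	CoA			headgroup_transfer	CPT2
NAE->FA	NAE	FA			headgroup_transfer	FAAH;FAAH2
FA(14:0)->FA(16:0)	FA	FA	14:0	16:0	fa_elongation	ELOVL6
FA(16:0)->FA(18:0)	FA	FA	16:0	18:0	fa_elongation	ELOVL6
FA(18:0)->FA(20:0)	FA	FA	18:0	20:0	fa_elongation	ELOVL1;ELOVL3
FA(20:0)->FA(22:0)	FA	FA	20:0	22:0	fa_elongation	ELOVL1;ELOVL3
FA(22:0)->FA(24:0)	FA	FA	22:0	24:0	fa_elongation	ELOVL1
FA(24:0)->FA(26:0)	FA	FA	24:0	26:0	fa_elongation	ELOVL1;ELOVL4
FA(16:1)->FA(18:1)	FA	FA	16:1	18:1	fa_elongation	ELOVL6
FA(18:1)->FA(20:1)	FA	FA	18:1	20:1	fa_elongation	ELOVL1;ELOVL3
FA(20:1)->FA(22:1)	FA	FA	20:1	22:1	fa_elongation	ELOVL1;ELOVL3
FA(22:1)->FA(24:1)	FA	FA	22:1	24:1	fa_elongation	ELOVL1
FA(18:2)->FA(20:2)	FA	FA	18:2	20:2	fa_elongation	ELOVL5
FA(18:3)->FA(20:3)	FA	FA	18:3	20:3	fa_elongation	ELOVL5;ELOVL7
FA(18:4)->FA(20:4)	FA	FA	18:4	20:4	fa_elongation	ELOVL5
FA(20:4)->FA(22:4)	FA	FA	20:4	22:4	fa_elongation	ELOVL2;ELOVL5
FA(22:4)->FA(24:4)	FA	FA	22:4	24:4	fa_elongation	ELOVL2;ELOVL4
FA(20:5)->FA(22:5)	FA	FA	20:5	22:5	fa_elongation	ELOVL2;ELOVL5
FA(22:5)->FA(24:5)	FA	FA	22:5	24:5	fa_elongation	ELOVL2
FA(22:6)->FA(24:6)	FA	FA	22:6	24:6	fa_elongation	ELOVL2;ELOVL4
FA(16:0)->FA(16:1)	FA	FA	16:0	16:1	fa_desaturation	SCD;SCD5
FA(18:0)->FA(18:1)	FA	FA	18:0	18:1	fa_desaturation	SCD;SCD5
FA(18:2)->FA(18:3)	FA	FA	18:2	18:3	fa_desaturation	FADS2
FA(18:3)->FA(18:4)	FA	FA	18:3	18:4	fa_desaturation	FADS2
FA(20:3)->FA(20:4)	FA	FA	20:3	20:4	fa_desaturation	FADS1
FA(20:4)->FA(20:5)	FA	FA	20:4	20:5	fa_desaturation	FADS1
FA(22:5)->FA(22:6)	FA	FA	22:5	22:6	fa_desaturation	FADS2
FA(24:5)->FA(24:6)	FA	FA	24:5	24:6	fa_desaturation	FADS2
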