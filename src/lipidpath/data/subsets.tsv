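name	reactions
Biosynthesis of Sphingomyelin	dhSph->dhCer;dhCer->Cer;Cer->SM;dhCer->dhSM
De novo lipogenesis	FA(14:0)->FA(16:0);FA(16:0)->FA(18:0);FA(16:0)->FA(16:1);FA(18:0)->FA(18:1);LPA->PA;PA->DG;DG->TG
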