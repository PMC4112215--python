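# SYNTHETIC metacrangonyctid-style gene order template.
# Constructed to satisfy the qualitative features described for the family:
# the conserved +cox1,+trnL2,+cox2,+trnK,+trnD,+atp8,+atp6,+cox3 string; the
# -nad5,-trnH,-nad4,-nad4L block; the trnA,trnS1,trnN,trnE,trnR tRNA string;
# trnS2 and cob reverse-transposed to the (-) strand beside the control
# region (which sits between rrnS and trnS2 and is excluded here); rrnL
# between trnL1 and trnV; inverted trnT; 21 genes on (+) / 16 on (-).
# It is a stand-in template, not a deposited annotation.
metacrangonyctid_synthetic	+cox1,+trnL2,+cox2,+trnK,+trnD,+atp8,+atp6,+cox3,+nad3,+trnA,+trnS1,+trnN,+trnE,+trnR,-trnF,-nad5,-trnH,-nad4,-nad4L,-trnT,-trnP,+nad6,+trnG,-nad1,-trnL1,-rrnL,-trnV,-rrnS,-trnS2,-cob,+trnC,+trnI,-trnQ,+trnM,+trnW,-trnY,+nad2
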