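# Hypothetical pancrustacean (hexapod + crustacean) ancestral mitochondrial
# gene order (the Drosophila-like arrangement), signed by coding strand.
# Control region excluded from the permutation (it sits between rrnS and trnI).
# One order per line: name<TAB>±gene,±gene,...
pancrustacean	+cox1,+trnL2,+cox2,+trnK,+trnD,+atp8,+atp6,+cox3,+trnG,+nad3,+trnA,+trnR,+trnN,+trnS1,+trnE,-trnF,-nad5,-trnH,-nad4,-nad4L,+trnT,-trnP,+nad6,+cob,+trnS2,-nad1,-trnL1,-rrnL,-trnV,-rrnS,+trnI,-trnQ,+trnM,+nad2,+trnW,-trnC,-trnY
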