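# SYNTHETIC reconstruction of the two barklouse (Psocoptera) mitochondrial
# gene orders of the EqualTDRL case study, 38 markers (37 genes + control
# region CR).  These sequences were NOT taken from the GenBank/RefSeq
# records; they are the unique pair of circular orders consistent with the
# published constraints: the source is the ancestral Pancrustacea mt gene
# order, the pair is at TDRL distance 1, shares exactly the six published
# conserved segments, and the target carries the trnQ-nad2 and cob-nad1
# adjacencies that frame the two intergenic regions.
>Prionoglaris_stygia_ancestral_pancrustacea
trnI trnQ trnM nad2 trnW trnC trnY cox1 trnL2 cox2
trnK trnD atp8 atp6 cox3 trnG nad3 trnA trnR trnN
trnS1 trnE trnF nad5 trnH nad4 nad4l trnT trnP nad6
cob trnS2 nad1 trnL1 rrnL trnV rrnS CR
>Lepidopsocidae_sp_trogiomorpha
trnI trnM trnW cox2 trnG nad3 trnA trnN trnF nad5
trnH nad4 nad4l trnT trnP nad6 cob nad1 trnL1 rrnL
trnV rrnS CR trnQ nad2 trnC trnY cox1 trnL2 trnK
trnD atp8 atp6 cox3 trnR trnS1 trnE trnS2
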