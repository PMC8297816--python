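family,duplicated_lineage,lso_a,lso_b,singleton,pathway
myod,Ostariophysi,myod1,myod2,myod,myogenesis
trim63,Ostariophysi,trim63a,trim63b,trim63,igf_akt_mtor
igfbp3,Ostariophysi,igfbp3a,igfbp3b,igfbp3,igf_akt_mtor
tgfb3,Ostariophysi,tgfb3a,tgfb3b,tgfb3,myogenesis
atf4,Ostariophysi,atf4a,atf4b,atf4,igf_akt_mtor
igf2bp2,Ostariophysi,igf2bp2a,igf2bp2b,igf2bp2,igf_akt_mtor
igf2,Ostariophysi,igf2a,igf2b,igf2,igf_akt_mtor
mef2d,Ostariophysi,mef2da,mef2db,mef2d,myogenesis
pik3ca,Ostariophysi,pik3caa,pik3cab,pik3ca,igf_akt_mtor
pip4k2a,Ostariophysi,pip4k2aa,pip4k2ab,pip4k2a,igf_akt_mtor
raf1,Ostariophysi,raf1a,raf1b,raf1,igf_akt_mtor
rictor,Acanthopterygii,rictora,rictorb,rictor,igf_akt_mtor
rragc,Acanthopterygii,rragca,rragcb,rragc,igf_akt_mtor
tgfb1,Acanthopterygii,tgfb1a,tgfb1b,tgfb1,myogenesis
fst,Acanthopterygii,fsta,fstb,fst,myogenesis
grb2,Acanthopterygii,grb2a,grb2b,grb2,igf_akt_mtor
eif3j,Acanthopterygii,eif3ja,eif3jb,eif3j,igf_akt_mtor
akt2,Acanthopterygii,akt2a,akt2b,akt2,igf_akt_mtor
chuk,Acanthopterygii,chuka,chukb,chuk,igf_akt_mtor
cdc42bpa,Acanthopterygii,cdc42bpaa,cdc42bpab,cdc42bpa,igf_akt_mtor
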