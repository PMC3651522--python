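(((Marmota_monax,(Tamiasciurus_hudsonicus,(Sciurus_carolinensis,Sciurus_niger))),(Castor_canadensis,(Nannospalax_ehrenbergi,((Peromyscus_maniculatus,Mesocricetus_auratus),(Meriones_unguiculatus,(Mus_musculus,Rattus_norvegicus)))))),(Heterocephalus_glaber,(Chinchilla_lanigera,(Agouti_paca,(Cavia_porcellus,Hydrochaeris_hydrochaeris)))));
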