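species,common_name,max_lifespan_yr,body_mass_g,brain,lung,heart,kidney
Mus_musculus,House Mouse,4,30,3,3,3,2
Rattus_norvegicus,Norway Rat,5,400,2,2,2,2
Tamiasciurus_hudsonicus,Red Squirrel,10,200,2,3,2,2
Castor_canadensis,American Beaver,24,20250,3,2,3,2
Marmota_monax,Woodchuck,14,5000,2,2,3,2
Nannospalax_ehrenbergi,Blind Mole-Rat,15,160,3,3,2,2
Sciurus_carolinensis,Eastern Grey Squirrel,24,533,2,2,3,2
Mesocricetus_auratus,Golden Hamster,4,105,2,2,2,2
Heterocephalus_glaber,Naked mole-rat,31,35,2,2,2,2
Chinchilla_lanigera,Chinchilla,17,642,3,2,3,2
Hydrochaeris_hydrochaeris,Capybara,15,55000,2,2,2,2
Agouti_paca,Paca,16,9000,2,2,2,2
Cavia_porcellus,Guinea Pig,12,738,4,2,2,2
Sciurus_niger,Fox Squirrel,16,800,3,2,2,2
Meriones_unguiculatus,Mongolian Gerbil,6,53,2,0,0,0
Peromyscus_maniculatus,Deer Mouse,8,20,2,2,2,2
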