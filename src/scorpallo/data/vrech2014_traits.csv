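species,body_mass_g,body_mass_sd,n_males,testes_mass_mg,testes_mass_sd,spermatophore_volume_mm3,sperm_length_um,sperm_length_sd,polyandry
Timogenes dorbignyi,0.43,0.17,9,1.60,1.10,1.27,229.35,12.49,2.0
Timogenes elegans,1.55,0.40,19,7.40,3.70,4.41,240.74,16.37,1.5
Urophonius brachycentrus,0.15,0.03,9,3.20,1.40,1.86,301.30,9.10,1.0
Brachistosternus pentheri,0.71,0.17,6,16.30,4.50,6.23,207.73,15.02,3.0
Bothriurus rochensis,0.33,0.03,10,7.60,4.80,3.37,269.39,15.24,2.5
Bothriurus bonariensis,0.61,0.13,11,14.60,7.00,5.66,233.07,12.68,4.0
Brachistosternus ferrugineus,0.27,0.07,18,8.40,3.60,3.49,233.04,8.02,2.5
Bothriurus cordubensis,0.17,0.01,6,8.20,1.80,3.23,302.39,3.44,2.5
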