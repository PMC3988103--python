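(((Bothriurus_bonariensis:1,Bothriurus_cordubensis:1,Bothriurus_rochensis:1):1,(Brachistosternus_ferrugineus:1,Brachistosternus_pentheri:1):1):1,((Timogenes_dorbignyi:1,Timogenes_elegans:1):1,Urophonius_brachycentrus:1):1);
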