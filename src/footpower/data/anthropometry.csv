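table,segment,mass_fraction,com_fraction,rg_sagittal,rg_transverse,rg_longitudinal
de_leva_male,foot,0.0137,0.4415,0.257,0.245,0.124
de_leva_male,shank,0.0433,0.4459,0.251,0.246,0.102
de_leva_female,foot,0.0129,0.4014,0.299,0.279,0.139
de_leva_female,shank,0.0481,0.4416,0.271,0.267,0.093
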