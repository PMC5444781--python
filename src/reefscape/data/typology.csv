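class_id,level3,level2,level1,depth_stratum,density_mean,density_sd
fringing_s,Fringing reef of continental island,Shallow reefs,Reef,shallow,256,272
intermediate_s,Intermediate reef of continental island,Shallow reefs,Reef,shallow,200,84
outer_barrier_s,Outer barrier reef of continental island,Shallow reefs,Reef,shallow,329,269
oceanic_patch_s,Oceanic patch reef of continental island,Shallow reefs,Reef,shallow,104,42
oceanic_island_s,Oceanic island,Shallow reefs,Reef,shallow,109,93
atoll_bank_s,Atoll/Bank reef,Shallow reefs,Reef,shallow,234,0
fringing_v,Fringing reef of continental island,Variable depth reef,Reef,variable_depth,,
intermediate_v,Intermediate reef of continental island,Variable depth reef,Reef,variable_depth,,
outer_barrier_v,Outer barrier reef of continental island,Variable depth reef,Reef,variable_depth,,
oceanic_patch_v,Oceanic patch reef of continental island,Variable depth reef,Reef,variable_depth,,
oceanic_island_v,Oceanic island,Variable depth reef,Reef,variable_depth,,
atoll_bank_v,Atoll/Bank reef,Variable depth reef,Reef,variable_depth,,
shallow_reefs,,Shallow reefs,Reef,shallow,224,193
variable_reefs,,Variable depth reef,Reef,variable_depth,,
reef,,,Reef,shallow,224,193
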