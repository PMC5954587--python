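experiment,treatment,year,et_obs,et_sim,yoil_obs,yoil_sim
I,FI,2004,*,798,319,255
I,FI,2005,958,862,151,119
I,FI,2006,1016,934,317,343
I,CDI,2004,*,697,247,241
I,CDI,2005,621,612,131,115
I,CDI,2006,709,672,267,243
I,RDI,2004,*,702,285,239
I,RDI,2005,609,617,122,115
I,RDI,2006,679,641,279,238
II,AYI,1997,822,642,357,254
II,AYI,1998,576,509,21,91
II,AYI,1999,839,643,244,191
II,CON,1997,814,724,298,358
II,CON,1998,778,641,154,121
II,CON,1999,899,654,262,235
II,DRY,1997,550,573,129,252
II,DRY,1998,582,505,186,91
II,DRY,1999,393,519,13,161
II,RDI,1997,582,658,268,303
II,RDI,1998,589,572,173,106
II,RDI,1999,526,594,171,196
II,SDI,1997,649,685,221,302
II,SDI,1998,636,601,150,106
II,SDI,1999,562,641,173,201
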