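areal_type,affinity,canonical
north temperate,temperate,1
east asia and north america,temperate,1
old world temperate,temperate,1
temperate asia,temperate,1
mediterranean west asia to central asia,temperate,1
central asia,temperate,1
east asia,temperate,1
east and north asia,temperate,0
america,temperate,0
old world temperate regions,temperate,0
mediterranean,temperate,0
west to central asia,temperate,0
west asia to central asia,temperate,0
northern temperate,temperate,0
north temperate regions,temperate,0
tropical asia and tropical america,tropical,1
old world tropical,tropical,1
tropical asia to tropical australia,tropical,1
tropical asia to tropical africa,tropical,1
tropical asia,tropical,1
tropical asia to tropical america,tropical,0
old world tropic regions,tropical,0
old world tropical regions,tropical,0
pantropic,tropical,0
pantropical,tropical,0
tropical america,tropical,0
cosmopolitan,cosmopolitan,1
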