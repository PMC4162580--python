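dataset	data_type
Holstege1	replicates
Holstege2	replicates
Gresham	environment_time
Gasch	environment_time
Smith	environment_time
Yeung	environment_time
M3D	compendium
GPL90	compendium
Hughes1	perturbation
Hughes2	perturbation
Hu	perturbation
Holstege3	perturbation
Holstege4	perturbation
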