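# Canonical catabolic route registry.  Stoichiometry is in MOLES (the loader
# renormalizes to one carbon-mole of substrate and converts carbon species to
# C-mol units).  Every record is validated at load: full elemental balance
# and degree-of-reduction electron balance.  `products` lists the observable
# catabolic products; the FIRST entry is the lookup key used by
# build_product_route(substrate, product).
name	substrate	products	stoichiometry
glucose_to_acetate	glucose	acetate	glucose:-1;O2:-2;acetate:2;CO2:2;H2O:2
glucose_to_ethanol	glucose	ethanol	glucose:-1;ethanol:2;CO2:2
glucose_to_lactate	glucose	lactate	glucose:-1;lactate:2
glucose_mixed_acid	glucose	formate,acetate,ethanol	glucose:-1;H2O:-1;acetate:1;ethanol:1;formate:2
glucose_to_glycerol	glucose	glycerol	glucose:-7;H2O:-6;glycerol:12;CO2:6
glucose_to_succinate	glucose	succinate	glucose:-7;CO2:-6;succinate:12;H2O:6
glucose_to_pyruvate	glucose	pyruvate	glucose:-1;O2:-1;pyruvate:2;H2O:2
ethanol_to_acetate	ethanol	acetate	ethanol:-1;O2:-1;acetate:1;H2O:1
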