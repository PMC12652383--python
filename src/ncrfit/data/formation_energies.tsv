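# Standard transformed formation energies (kJ/mol) of the pH-7 pseudoisomer
# groups, eQuilibrator-convention biochemical standard state:
# T = 298.15 K, pH 7.0, ionic strength 0.25 mol/L, pMg 3.0 (Mg2+ 1 mM).
# Only differences along elementally balanced reactions are physically
# meaningful; the absolute values carry a gauge fixed by the H2O, O2 and CO2
# entries.  Provenance: transcribed component-contribution estimates,
# cross-checked for internal thermodynamic consistency (per-electron
# combustion energies, redox couples) by the test suite.
species	dfG_prime_kJ_mol	provenance
H2O	-157.6	gauge anchor (activity 1; no concentration term)
O2	16.4	gauge anchor, aqueous O2
CO2	-386.0	gauge anchor, aqueous CO2 (not total carbonate)
glucose	-429.5	combustion anchor: glc + 6 O2 -> 6 CO2 + 6 H2O = -2930.5
ethanol	58.8	fermentation anchor: glc -> 2 eth + 2 CO2 = -224.9
lactate	-309.5	fermentation anchor: glc -> 2 lac = -189.5
acetate	-252.25	overflow anchor: glc + 2 O2 -> 2 ace + 2 CO2 + 2 H2O = -1195.0
formate	-302.8	mixed-acid anchor: glc + H2O -> ace + eth + 2 for = -212.0
glycerol	-133.8	combustion anchor: glyc + 3.5 O2 -> 3 CO2 + 4 H2O = -1712.0
succinate	-583.2	combustion anchor: succ + 3.5 O2 -> 4 CO2 + 3 H2O = -1491.0
pyruvate	-337.8	redox-couple anchor: lac + 0.5 O2 -> pyr + H2O = -194.1
mannitol	-350.8	combustion anchor: mann + 6.5 O2 -> 6 CO2 + 7 H2O = -3175.0
oxoglutarate	-678.4	combustion anchor: akg + 4 O2 -> 5 CO2 + 3 H2O = -1790.0
ammonia	-26.6	low-confidence transcription (unused by bundled routes)
ATP	-2295.9	hydrolysis anchor: ATP + H2O -> ADP + Pi = -26.5 (split gauge-fixed)
ADP	-1424.0	hydrolysis anchor (see ATP)
phosphate	-1056.0	hydrolysis anchor (see ATP)
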