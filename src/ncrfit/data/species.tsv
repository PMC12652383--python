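# Species table: name, Hill formula (neutral form), charge, phase_role.
# Routes are written in neutral form (acetic acid as C2H4O2, etc.); the
# formation-energy table refers to the pH-7 pseudoisomer group regardless.
name	formula	charge	phase_role
glucose	C6H12O6	0	solute
O2	O2	0	solute
CO2	CO2	0	solute
H2O	H2O	0	water
acetate	C2H4O2	0	solute
ethanol	C2H6O	0	solute
lactate	C3H6O3	0	solute
formate	CH2O2	0	solute
glycerol	C3H8O3	0	solute
succinate	C4H6O4	0	solute
pyruvate	C3H4O3	0	solute
mannitol	C6H14O6	0	solute
oxoglutarate	C5H6O5	0	solute
ammonia	NH3	0	solute
ATP	C10H16N5O13P3	0	solute
ADP	C10H15N5O10P2	0	solute
phosphate	H3PO4	0	solute
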