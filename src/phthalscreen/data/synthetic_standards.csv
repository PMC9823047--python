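name,neutral_formula,rt_min,labelled,n_carbon13,chain_carbons,n_hydroxyl,n_oxo,n_carboxy,logp_proxy
monomethyl phthalate,C9H8O4,2.9,False,0,1,0,0,0,1.0
monoethyl phthalate,C10H10O4,3.8,False,0,2,0,0,0,2.0
monoisopropyl phthalate,C11H12O4,4.4,False,0,3,0,0,0,2.667
monopropyl phthalate,C11H12O4,4.7,False,0,3,0,0,0,3.0
monoisobutyl phthalate,C12H14O4,5.3,False,0,4,0,0,0,3.667
monobutyl phthalate,C12H14O4,5.75,False,0,4,0,0,0,4.167
monopentyl phthalate,C13H16O4,6.3,False,0,5,0,0,0,4.778
mono-5-hydroxyhexyl phthalate,C14H18O5,6.5,False,0,6,1,0,0,5.0
monohexyl phthalate,C14H18O4,7.4,False,0,6,0,0,0,6.0
mono-5-oxohexyl phthalate,C14H16O5,7.85,False,0,6,0,1,0,6.5
mono-2-ethyl-5-hydroxyhexyl phthalate,C16H22O5,7.6,False,0,8,1,0,0,6.222
monocyclohexyl phthalate,C14H18O4,8.0,False,0,6,0,0,0,6.667
mono-2-ethyl-5-oxohexyl phthalate,C16H20O5,8.45,False,0,8,0,1,0,7.167
monoheptyl phthalate,C15H20O4,9.2,False,0,7,0,0,0,8.0
monobenzyl phthalate,C15H12O4,9.8,False,0,7,0,0,0,8.667
mono-2-ethylhexyl phthalate,C16H22O4,10.4,False,0,8,0,0,0,9.333
monooctyl phthalate,C16H22O4,11.3,False,0,8,0,0,0,10.333
monoisononyl phthalate,C17H24O4,11.85,False,0,9,0,0,0,10.944
monononyl phthalate,C17H24O4,12.1,False,0,9,0,0,0,11.222
mono-3-carboxypropyl phthalate,C12H12O6,3.1,False,0,4,0,0,1,1.222
mono-5-carboxypentyl phthalate,C14H16O6,4.9,False,0,6,0,0,1,3.222
mono-2-ethyl-5-carboxypentyl phthalate,C16H20O6,6.9,False,0,8,0,0,1,5.444
mono-7-hydroxyheptyl phthalate,C15H20O5,8.3,False,0,7,1,0,0,7.0
mono-4-methylheptyl phthalate,C16H22O4,10.9,False,0,8,0,0,0,9.889
13C4-monomethyl phthalate,C9H8O4,2.9,True,4,1,0,0,0,1.0
13C4-monoethyl phthalate,C10H10O4,3.8,True,4,2,0,0,0,2.0
13C4-monopropyl phthalate,C11H12O4,4.7,True,4,3,0,0,0,3.0
13C4-monoisobutyl phthalate,C12H14O4,5.3,True,4,4,0,0,0,3.667
13C4-monobutyl phthalate,C12H14O4,5.75,True,4,4,0,0,0,4.167
13C4-monopentyl phthalate,C13H16O4,6.3,True,4,5,0,0,0,4.778
13C4-mono-5-hydroxyhexyl phthalate,C14H18O5,6.5,True,4,6,1,0,0,5.0
13C4-monohexyl phthalate,C14H18O4,7.4,True,4,6,0,0,0,6.0
13C4-mono-5-oxohexyl phthalate,C14H16O5,7.85,True,4,6,0,1,0,6.5
13C4-mono-2-ethyl-5-oxohexyl phthalate,C16H20O5,8.45,True,4,8,0,1,0,7.167
13C4-monoheptyl phthalate,C15H20O4,9.2,True,4,7,0,0,0,8.0
13C4-monobenzyl phthalate,C15H12O4,9.8,True,4,7,0,0,0,8.667
13C4-mono-2-ethylhexyl phthalate,C16H22O4,10.4,True,4,8,0,0,0,9.333
13C4-monooctyl phthalate,C16H22O4,11.3,True,4,8,0,0,0,10.333
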