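name,neutral_formula,neutral_monoisotopic_mass,chain_carbons,n_hydroxyl,n_oxo,n_carboxy,logp_proxy
monomethyl phthalate,C9H8O4,180.04226,1,0,0,0,1.0
monoethyl phthalate,C10H10O4,194.05791,2,0,0,0,2.0
monoisopropyl phthalate,C11H12O4,208.07356,3,0,0,0,2.667
monopropyl phthalate,C11H12O4,208.07356,3,0,0,0,3.0
monoisobutyl phthalate,C12H14O4,222.08921,4,0,0,0,3.667
monobutyl phthalate,C12H14O4,222.08921,4,0,0,0,4.167
monopentyl phthalate,C13H16O4,236.10486,5,0,0,0,4.778
mono-5-hydroxyhexyl phthalate,C14H18O5,266.11542,6,1,0,0,5.0
monohexyl phthalate,C14H18O4,250.12051,6,0,0,0,6.0
mono-5-oxohexyl phthalate,C14H16O5,264.09977,6,0,1,0,6.5
mono-2-ethyl-5-hydroxyhexyl phthalate,C16H22O5,294.14672,8,1,0,0,6.222
monocyclohexyl phthalate,C14H18O4,250.12051,6,0,0,0,6.667
mono-2-ethyl-5-oxohexyl phthalate,C16H20O5,292.13107,8,0,1,0,7.167
monoheptyl phthalate,C15H20O4,264.13616,7,0,0,0,8.0
monobenzyl phthalate,C15H12O4,256.07356,7,0,0,0,8.667
mono-2-ethylhexyl phthalate,C16H22O4,278.15181,8,0,0,0,9.333
monooctyl phthalate,C16H22O4,278.15181,8,0,0,0,10.333
monoisononyl phthalate,C17H24O4,292.16746,9,0,0,0,10.944
monononyl phthalate,C17H24O4,292.16746,9,0,0,0,11.222
mono-3-carboxypropyl phthalate,C12H12O6,252.06339,4,0,0,1,1.222
mono-5-carboxypentyl phthalate,C14H16O6,280.09469,6,0,0,1,3.222
mono-2-ethyl-5-carboxypentyl phthalate,C16H20O6,308.12599,8,0,0,1,5.444
mono-7-hydroxyheptyl phthalate,C15H20O5,280.13107,7,1,0,0,7.0
mono-4-methylheptyl phthalate,C16H22O4,278.15181,8,0,0,0,9.889
mono-3-hydroxypropyl phthalate,C11H12O5,224.06847,3,1,0,0,1.9
mono-4-hydroxybutyl phthalate,C12H14O5,238.08412,4,1,0,0,2.9
mono-4-hydroxy-pentyl phthalate,C13H16O5,252.09977,5,1,0,0,3.9
mono-5-hydroxypentyl phthalate,C13H16O5,252.09977,5,1,0,0,3.9
mono-6-hydroxyhexyl phthalate,C14H18O5,266.11542,6,1,0,0,4.9
mono-6-hydroxy-heptyl phthalate,C15H20O5,280.13107,7,1,0,0,5.9
mono-2-ethyl-6-hydroxyhexyl phthalate,C16H22O5,294.14672,8,1,0,0,6.9
mono-8-hydroxyoctyl phthalate,C16H22O5,294.14672,8,1,0,0,6.9
mono-hydroxyisononyl phthalate,C17H24O5,308.16237,9,1,0,0,7.9
mono-9-hydroxynonyl phthalate,C17H24O5,308.16237,9,1,0,0,7.9
mono-6-methyl-7-hydroxynonyl phthalate,C18H26O5,322.17802,10,1,0,0,8.9
mono-2-propyl-6-hydroxyheptyl phthalate,C18H26O5,322.17802,10,1,0,0,8.9
mono-7-hydroxy-4-methyloctyl phthalate,C17H24O5,308.16237,9,1,0,0,7.9
"mono-3,4-dimethyl-5-ethyl-6-hydroxyhexyl phthalate",C18H26O5,322.17802,10,1,0,0,8.9
mono-3-oxobutyl phthalate,C12H12O5,236.06847,4,0,1,0,3.1
mono-4-oxopentyl phthalate,C13H14O5,250.08412,5,0,1,0,4.1
mono-6-oxohexyl phthalate,C14H16O5,264.09977,6,0,1,0,5.1
mono-6-oxoheptyl phthalate,C15H18O5,278.11542,7,0,1,0,6.1
mono-3-propyl-4-oxo-hexyl phthalate,C17H22O5,306.14672,9,0,1,0,8.1
mono-4-methyl-7-oxooctyl phthalate,C17H22O5,306.14672,9,0,1,0,8.1
"mono-3,4-dimethyl-5-ethyl-6-oxohexyl phthalate",C18H24O5,320.16237,10,0,1,0,9.1
mono-8-oxooctyl phthalate,C16H20O5,292.13107,8,0,1,0,7.1
mono-2-carboxyethyl phthalate,C11H10O6,238.04774,3,0,0,1,1.2
mono-4-carboxybutyl phthalate,C13H14O6,266.07904,5,0,0,1,3.2
mono-6-carboxyhexyl phthalate,C15H18O6,294.11034,7,0,0,1,5.2
mono-2-carboxymethylhexyl phthalate,C16H20O6,308.12599,8,0,0,1,6.2
mono-7-carboxyheptyl phthalate,C16H20O6,308.12599,8,0,0,1,6.2
mono-1-hydroxy-2-oxo-5ethylhexyl phthalate,C16H20O6,308.12599,8,1,1,0,6.0
mono-5-hydroxy-6-oxohexyl phthalate,C14H16O6,280.09469,6,1,1,0,4.0
mono-3-hydroxy-4-oxoheptyl phthalate,C15H18O6,294.11034,7,1,1,0,5.0
monodecyl phthalate,C18H26O4,306.18311,10,0,0,0,10.0
mono-2-methylpropyl phthalate,C12H14O4,222.08921,4,0,0,0,4.0
mono-3-methylbutyl phthalate,C13H16O4,236.10486,5,0,0,0,5.0
mono-2-methylhexyl phthalate,C15H20O4,264.13616,7,0,0,0,7.0
mono-6-methylheptyl phthalate,C16H22O4,278.15181,8,0,0,0,8.0
mono-7-methyloctyl phthalate,C17H24O4,292.16746,9,0,0,0,9.0
mono-2-propylheptyl phthalate,C18H26O4,306.18311,10,0,0,0,10.0
mono-2-ethylpentyl phthalate,C15H20O4,264.13616,7,0,0,0,7.0
"mono-2,4-dimethylpentyl phthalate",C15H20O4,264.13616,7,0,0,0,7.0
mono-2-phenylethyl phthalate,C16H14O4,270.08921,8,0,0,0,7.7
mono-4-methylbenzyl phthalate,C16H14O4,270.08921,8,0,0,0,7.7
mono-cyclopentyl phthalate,C13H16O4,236.10486,5,0,0,0,5.0
mono-2-ethyl-5-carboxyhexyl phthalate,C17H22O6,322.14164,9,0,0,1,7.2
mono-2-ethyl-4-hydroxyhexyl phthalate,C16H22O5,294.14672,8,1,0,0,6.9
mono-2-ethyl-4-oxohexyl phthalate,C16H20O5,292.13107,8,0,1,0,7.1
mono-2-ethyl-3-hydroxyhexyl phthalate,C16H22O5,294.14672,8,1,0,0,6.9
mono-5-carboxy-2-ethylpentyl phthalate,C16H20O6,308.12599,8,0,0,1,6.2
mono-4-hydroxyheptyl phthalate,C15H20O5,280.13107,7,1,0,0,5.9
mono-5-oxoheptyl phthalate,C15H18O5,278.11542,7,0,1,0,6.1
mono-5-hydroxy-4-methylhexyl phthalate,C15H20O5,280.13107,7,1,0,0,5.9
mono-oxoisononyl phthalate,C17H22O5,306.14672,9,0,1,0,8.1
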