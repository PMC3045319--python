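# Local (gene, organism) -> additional gene name table.
# Stands in for a live protein-database lookup so builds are hermetic.
# gene<TAB>organism<TAB>additional_name
IL2	mouse	Interleukin
Copg1	mouse	gamma-COP
Tp53	mouse	p53
Adh	fly	Alcohol-dehydrogenase
w	fly	white
rosy	fly	Xanthine-dehydrogenase
CDC28	yeast	Cyclin-dependent-kinase
GAL4	yeast	Galactose-regulon-activator
ACT1	yeast	Actin
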