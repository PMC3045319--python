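# Default organism lexicon: surface<TAB>label
# Labels: fly (Drosophila melanogaster), mouse (Mus musculus),
# yeast (Saccharomyces cerevisiae).  Matching is case-insensitive.
fly	fly
flies	fly
drosophila	fly
drosophila melanogaster	fly
d. melanogaster	fly
fruit fly	fly
fruit flies	fly
mouse	mouse
mice	mouse
murine	mouse
mus musculus	mouse
m. musculus	mouse
yeast	yeast
yeasts	yeast
saccharomyces	yeast
saccharomyces cerevisiae	yeast
s. cerevisiae	yeast
budding yeast	yeast
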