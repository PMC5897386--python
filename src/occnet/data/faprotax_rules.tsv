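rank	pattern	category
genus	g__Bradyrhizobium	nitrogen_fixation
genus	g__Azotobacter	nitrogen_fixation
genus	g__Rhizobium	nitrogen_fixation
genus	g__Mesorhizobium	nitrogen_fixation
genus	g__Frankia	nitrogen_fixation
genus	g__Azospirillum	nitrogen_fixation
genus	g__Beijerinckia	nitrogen_fixation
genus	g__Nitrospira	nitrification
genus	g__Nitrospira	aerobic_nitrite_oxidation
genus	g__Nitrosomonas	nitrification
genus	g__Nitrosomonas	aerobic_ammonia_oxidation
genus	g__Nitrobacter	nitrification
genus	g__Nitrobacter	aerobic_nitrite_oxidation
genus	g__Pseudomonas	nitrate_reduction
genus	g__Paracoccus	nitrate_reduction
genus	g__Bacillus	fermentation
genus	g__Clostridium	fermentation
genus	g__Lactobacillus	fermentation
genus	g__Methylobacter	methanotrophy
genus	g__Methylocystis	methanotrophy
genus	g__Methylobacterium	methanol_oxidation
genus	g__Alcanivorax	hydrocarbon_degradation
genus	g__Thiobacillus	dark_oxidation_of_sulfur_compounds
genus	g__Sulfurimonas	dark_oxidation_of_sulfur_compounds
genus	g__Geobacter	dissimilatory_arsenate_reduction
phylum	p__Actinobacteria	chemoheterotrophy
phylum	p__Bacteroidetes	chemoheterotrophy
phylum	p__Firmicutes	chemoheterotrophy
class	c__Alphaproteobacteria	chemoheterotrophy
class	c__Gammaproteobacteria	chemoheterotrophy
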