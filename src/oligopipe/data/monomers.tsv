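# Monomer registry: token, kind, description. Extend by adding rows.
token	kind	description
dR	sugar	2'-deoxyribose (DNA)
R	sugar	ribose (RNA)
LR	sugar	locked nucleic acid (LNA)
mR	sugar	2'-O-methyl ribose
A	base	adenine
C	base	cytosine
G	base	guanine
T	base	thymine
U	base	uracil
5mC	base	5-methylcytosine
P	linker	phosphodiester
sP	linker	phosphorothioate
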