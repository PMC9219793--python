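# Template species panel for conservation classification: one row per
# (species, molecule) pairwise FASTA (ancestor chain + species chain,
# pre-aligned with '-' gaps or raw).  Fill in the path column.
# Any species/kingdom table is accepted; this panel covers six kingdoms.
species_id	kingdom	molecule	path
P_abyssi	archaea	16S
P_abyssi	archaea	5S
P_abyssi	archaea	23S
E_coli	bacteria	16S
E_coli	bacteria	5S
E_coli	bacteria	23S
P_solitarium	protists	16S
P_solitarium	protists	5S
P_solitarium	protists	23S
S_cerevisiae	fungi	16S
S_cerevisiae	fungi	5S
S_cerevisiae	fungi	23S
A_thaliana	plants	16S
A_thaliana	plants	5S
A_thaliana	plants	23S
D_melanogaster	animals	16S
D_melanogaster	animals	5S
D_melanogaster	animals	23S
H_sapiens	animals	16S
H_sapiens	animals	5S
H_sapiens	animals	23S
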