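# Triad sites of engineered E. coli PETase variants (full-length UniProt /
# AlphaFold model numbering). Columns: protein, UniProt accession, Ser/His/
# acid positions, acid kind, and the wild-type residue identity (one-letter)
# at each triad position. FliD (P24216) is omitted: its published triad and
# substitution numbering are mutually inconsistent and cannot be placed on a
# single numbering scheme.
CysP	P16700	65	72	31	ASP	S	Q	S
OmpA	P0A910	92	81	94	GLU	A	R	K
EfeO	P0AB24	199	204	210	ASP	A	Y	D
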