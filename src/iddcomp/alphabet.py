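"""The 20-letter standard amino-acid alphabet, in fixed alphabetical order.

All 20-component composition vectors in this package are indexed by this
order. Ambiguity codes (B, J, Z), non-standard residues (O, U), unknowns (X),
stops (*) and gap characters are outside the alphabet and are stripped at I/O
time; the composition math is defined only over these 20 symbols.
"""

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

# characters accepted in input but removed during sanitization
NON_STANDARD = set("BJOUXZ*-.")
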