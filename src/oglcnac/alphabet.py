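"""Residue alphabets shared across the package.

Peptide windows are strings over the 20 standard amino-acid letters plus
``X`` (unknown residue, produced on FASTA ingest for any non-standard
character) and ``-`` (terminal padding so every window has the full
length even at protein termini).
"""

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
PAD: str = "-"
UNKNOWN: str = "X"

#: Symbols a profile HMM can emit: 20 letters + the padding symbol.
HMM_ALPHABET: str = AMINO_ACIDS + PAD

#: Everything a window string may contain.
WINDOW_ALPHABET: frozenset = frozenset(AMINO_ACIDS + PAD + UNKNOWN)

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
HMM_INDEX = {a: i for i, a in enumerate(HMM_ALPHABET)}
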