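"""Standard genetic code tables used throughout the package.

Everything is derived from the NCBI standard code (translation table 1),
the nuclear code shared by all species this pipeline compares. Codons are
DNA triplets (T, not U), always uppercase.
"""

from Bio.Data import CodonTable

_STD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, for the 61 sense codons
CODON_TO_AA: dict[str, str] = dict(_STD.forward_table)

#: the three stop codons, keyed under '*'
STOP_CODONS: tuple[str, ...] = tuple(sorted(_STD.stop_codons))

for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"

#: all 64 codons in lexicographic order
ALL_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: the 61 sense codons in lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if CODON_TO_AA[c] != "*")

#: amino acid (or '*') -> sorted tuple of its synonymous codons
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon in ALL_CODONS:
    AA_TO_CODONS.setdefault(CODON_TO_AA[_codon], ())
for _aa in AA_TO_CODONS:
    AA_TO_CODONS[_aa] = tuple(c for c in ALL_CODONS if CODON_TO_AA[c] == _aa)

#: the 20 amino acids in alphabetical one-letter order
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(a for a in AA_TO_CODONS if a != "*"))

#: amino acids encoded by a single codon (M, W): RSCU is trivially 1 there
SINGLE_CODON_AAS: tuple[str, ...] = tuple(
    a for a in AMINO_ACIDS if len(AA_TO_CODONS[a]) == 1
)
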