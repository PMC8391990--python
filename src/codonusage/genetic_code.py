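"""Standard genetic code tables and synonymous-family structure.

Everything here is derived programmatically from Biopython's standard
codon table (NCBI table 1) so that codon/amino-acid assignments are never
hand-typed. The module exposes the family decomposition used throughout:
61 sense codons, of which ATG (Met) and TGG (Trp) are non-degenerate,
leaving 59 codons in 18 synonymous families of degeneracy 2, 3, 4 or 6.
"""

from __future__ import annotations

from Bio.Data import CodonTable

BASES = "ACGT"

_standard = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, for the 61 sense codons
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: amino acid -> tuple of synonymous codons (alphabetical)
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] += (_codon,)

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(AA_TO_CODONS))

#: amino acid -> family degeneracy (number of synonymous codons)
DEGENERACY: dict[str, int] = {aa: len(cs) for aa, cs in AA_TO_CODONS.items()}

#: the 18 amino acids with two or more synonymous codons
DEGENERATE_AAS: tuple[str, ...] = tuple(
    aa for aa in AMINO_ACIDS if DEGENERACY[aa] >= 2
)

#: the 59 codons belonging to degenerate families (sense minus ATG, TGG)
DEGENERATE_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if DEGENERACY[CODON_TO_AA[c]] >= 2
)

#: degeneracy class -> amino acids in it (classes 2, 3, 4, 6)
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {}
for _aa in DEGENERATE_AAS:
    _k = DEGENERACY[_aa]
    DEGENERACY_CLASSES.setdefault(_k, ())
    DEGENERACY_CLASSES[_k] += (_aa,)

DINUCLEOTIDES: tuple[str, ...] = tuple(a + b for a in BASES for b in BASES)

assert len(SENSE_CODONS) == 61
assert len(DEGENERATE_CODONS) == 59
assert len(DEGENERATE_AAS) == 18
assert sorted(DEGENERACY_CLASSES) == [2, 3, 4, 6]


def is_gc(base: str) -> bool:
    return base in "GC"
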