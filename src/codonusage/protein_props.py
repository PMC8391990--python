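"""Translation and protein-level indices of each gene product.

The nine indices reported per protein are GRAVY (grand average of
Kyte–Doolittle hydropathy), aromaticity (mole fraction of Phe/Tyr/Trp),
isoelectric point (Bjellqvist pKa set, solved by bisection), aliphatic
index, hydrophobicity percent, Guruprasad instability index, and counts
of acidic (D, E), basic (K, R, H) and neutral residues.

GRAVY, aromaticity, instability and pI are delegated to Biopython's
ProtParam machinery, which carries the published Kyte–Doolittle, DIWV
and Bjellqvist tables. The aliphatic index uses Ikai's coefficients,

    AI = 100 * (x_Ala + 2.9 * x_Val + 3.9 * (x_Ile + x_Leu)),

with x the mole fractions. The "hydrophobicity percent" is the percent
of residues in the hydrophobic set {A, C, F, I, L, M, V}; web tools
compute this index under several unnamed scales, so the residue set is
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Iterable

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .sequence_io import CodingSequence

__all__ = [
    "INSTABILITY_THRESHOLD",
    "HYDROPHOBIC_RESIDUES",
    "ProteinIndices",
    "translate",
    "protein_indices",
    "indices_frame",
]

STANDARD_AAS = frozenset("ACDEFGHIKLMNPQRSTVWY")
ACIDIC = frozenset("DE")
BASIC = frozenset("KRH")  # His counted as basic
HYDROPHOBIC_RESIDUES: FrozenSet[str] = frozenset("ACFILMV")
INSTABILITY_THRESHOLD = 40.0


def translate(cds: CodingSequence) -> str:
    """Standard-code translation; a terminal stop codon is dropped.

    Internal stops cannot occur by the CodingSequence invariant.
    """
    coding = "".join(cds.coding_codons)
    return str(Seq(coding).translate(table=1))


@dataclass(frozen=True)
class ProteinIndices:
    gravy: float
    aroma: float
    pi: float
    aliphatic_index: float
    hydrophobicity_pct: float
    instability_index: float
    n_acidic: int
    n_basic: int
    n_neutral: int
    length_aa: int

    @property
    def is_unstable(self) -> bool:
        return self.instability_index > INSTABILITY_THRESHOLD

    def as_dict(self) -> dict[str, float]:
        return {
            "gravy": self.gravy,
            "aroma": self.aroma,
            "pi": self.pi,
            "aliphatic_index": self.aliphatic_index,
            "hydrophobicity_pct": self.hydrophobicity_pct,
            "instability_index": self.instability_index,
            "n_acidic": self.n_acidic,
            "n_basic": self.n_basic,
            "n_neutral": self.n_neutral,
            "length_aa": self.length_aa,
        }


def protein_indices(
    protein: str,
    hydrophobic_set: FrozenSet[str] = HYDROPHOBIC_RESIDUES,
) -> ProteinIndices:
    """Compute the nine indices for one protein sequence.

    Raises ValueError, naming the first offending position, if the
    sequence is empty or contains a non-standard letter.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    for i, aa in enumerate(protein):
        if aa not in STANDARD_AAS:
            raise ValueError(f"non-standard residue {aa!r} at position {i + 1}")

    pa = ProteinAnalysis(protein)
    length = len(protein)
    frac = {aa: protein.count(aa) / length for aa in STANDARD_AAS}
    aliphatic = 100.0 * (
        frac["A"] + 2.9 * frac["V"] + 3.9 * (frac["I"] + frac["L"])
    )
    n_acidic = sum(protein.count(aa) for aa in ACIDIC)
    n_basic = sum(protein.count(aa) for aa in BASIC)
    # instability is defined on dipeptides; a single residue has none
    instab = pa.instability_index() if length >= 2 else 0.0
    return ProteinIndices(
        gravy=pa.gravy(),
        aroma=pa.aromaticity(),
        pi=pa.isoelectric_point(),
        aliphatic_index=aliphatic,
        hydrophobicity_pct=100.0 * sum(frac[aa] for aa in hydrophobic_set),
        instability_index=instab,
        n_acidic=n_acidic,
        n_basic=n_basic,
        n_neutral=length - n_acidic - n_basic,
        length_aa=length,
    )


def indices_frame(panel: Iterable[CodingSequence]) -> pd.DataFrame:
    """Protein-index table for a panel, one row per gene."""
    rows = {
        cds.gene_id: protein_indices(translate(cds)).as_dict() for cds in panel
    }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene_id")
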