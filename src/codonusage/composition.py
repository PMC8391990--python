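"""Nucleotide composition, overall and by codon position.

Per-gene composition drives the force-attribution analyses: GC3 (third
codon position G+C) is largely synonymous and tracks mutational pressure,
while GC12 — defined here as the arithmetic mean of GC1 and GC2 — sits at
mostly non-synonymous sites and reflects selection on the protein. All
percentages are computed over the full CDS including a terminal stop
codon if present; ``gc3_synonymous`` offers the alternative convention
that skips Met/Trp/stop codons at the third position.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable

import pandas as pd

from .genetic_code import BASES, STOP_CODONS
from .sequence_io import CodingSequence

__all__ = ["CompositionProfile", "composition_profile", "gc3_synonymous", "profile_frame"]


@dataclass(frozen=True)
class CompositionProfile:
    """Percent composition of one CDS, overall and per codon position."""

    pA: float
    pC: float
    pG: float
    pT: float
    pA1: float
    pC1: float
    pG1: float
    pT1: float
    pA2: float
    pC2: float
    pG2: float
    pT2: float
    pA3: float
    pC3: float
    pG3: float
    pT3: float
    GC: float
    GC1: float
    GC2: float
    GC3: float
    GC12: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _percents(s: str) -> dict[str, float]:
    n = len(s)
    return {b: 100.0 * s.count(b) / n for b in BASES}


def composition_profile(cds: CodingSequence) -> CompositionProfile:
    """Overall and position-specific base percentages for one CDS."""
    seq = cds.seq
    overall = _percents(seq)
    by_pos = [_percents(seq[k::3]) for k in range(3)]
    gck = [p["G"] + p["C"] for p in by_pos]
    return CompositionProfile(
        pA=overall["A"],
        pC=overall["C"],
        pG=overall["G"],
        pT=overall["T"],
        pA1=by_pos[0]["A"],
        pC1=by_pos[0]["C"],
        pG1=by_pos[0]["G"],
        pT1=by_pos[0]["T"],
        pA2=by_pos[1]["A"],
        pC2=by_pos[1]["C"],
        pG2=by_pos[1]["G"],
        pT2=by_pos[1]["T"],
        pA3=by_pos[2]["A"],
        pC3=by_pos[2]["C"],
        pG3=by_pos[2]["G"],
        pT3=by_pos[2]["T"],
        GC=overall["G"] + overall["C"],
        GC1=gck[0],
        GC2=gck[1],
        GC3=gck[2],
        GC12=(gck[0] + gck[1]) / 2.0,
    )


def gc3_synonymous(cds: CodingSequence) -> float:
    """Percent G+C at third positions of synonymous codons only.

    Skips ATG, TGG and stop codons, whose third base is fixed by the
    genetic code. Returns NaN for a gene with no synonymous codons.
    """
    thirds = [
        c[2]
        for c in cds.codons
        if c not in ("ATG", "TGG") and c not in STOP_CODONS
    ]
    if not thirds:
        return float("nan")
    return 100.0 * sum(b in "GC" for b in thirds) / len(thirds)


def profile_frame(panel: Iterable[CodingSequence]) -> pd.DataFrame:
    """Composition table for a panel: one row per gene, indexed by gene_id."""
    rows = {cds.gene_id: composition_profile(cds).as_dict() for cds in panel}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene_id")
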