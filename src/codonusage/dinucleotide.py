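"""Dinucleotide odds ratios and representation classes.

The odds ratio of a dinucleotide xy is its observed frequency among all
overlapping adjacent pairs of the sequence divided by the product of the
mononucleotide frequencies, ρ(xy) = f(xy) / (f(x)·f(y)). Ratios below
0.78 mark under-representation and above 1.23 over-representation —
CpG and TpA suppression in vertebrate genes being the classic cases.
Pairs are counted on the given strand only, across codon boundaries,
with no wrap-around.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .genetic_code import BASES, DINUCLEOTIDES
from .sequence_io import CodingSequence

__all__ = [
    "ODDS_UNDER",
    "ODDS_OVER",
    "DinucleotideOdds",
    "dinucleotide_odds",
    "odds_frame",
]

ODDS_UNDER = 0.78
ODDS_OVER = 1.23

OVER = "OVER"
UNDER = "UNDER"
NORMAL = "NORMAL"
MISSING = "MISSING"


@dataclass(frozen=True)
class DinucleotideOdds:
    """The 16 odds ratios of one sequence; NaN/MISSING where a
    mononucleotide frequency is zero and the ratio is undefined."""

    rho: Mapping[str, float]
    classification: Mapping[str, str]

    def __getitem__(self, dinucleotide: str) -> float:
        return self.rho[dinucleotide]


def dinucleotide_odds(cds: CodingSequence | str) -> DinucleotideOdds:
    """Odds ratios for a CDS (or any raw A/C/G/T string)."""
    seq = cds.seq if isinstance(cds, CodingSequence) else cds.upper()
    if len(seq) < 2:
        raise ValueError("sequence shorter than one dinucleotide")
    n_pairs = len(seq) - 1
    mono = {b: seq.count(b) / len(seq) for b in BASES}
    pair_counts = {d: 0 for d in DINUCLEOTIDES}
    for i in range(n_pairs):
        pair_counts[seq[i : i + 2]] += 1

    rho: dict[str, float] = {}
    classes: dict[str, str] = {}
    for d in DINUCLEOTIDES:
        x, y = d
        if mono[x] == 0.0 or mono[y] == 0.0:
            rho[d] = float("nan")
            classes[d] = MISSING
            continue
        r = (pair_counts[d] / n_pairs) / (mono[x] * mono[y])
        rho[d] = r
        classes[d] = UNDER if r < ODDS_UNDER else OVER if r > ODDS_OVER else NORMAL
    return DinucleotideOdds(rho, classes)


def odds_frame(panel: Iterable[CodingSequence]) -> pd.DataFrame:
    """Genes × 16 odds-ratio matrix, columns named rho_AA … rho_TT."""
    rows = {
        cds.gene_id: {f"rho_{d}": v for d, v in dinucleotide_odds(cds).rho.items()}
        for cds in panel
    }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene_id")
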