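"""Codon-level bias statistics: RSCU, Wright's ENc, and CAI.

RSCU (relative synonymous codon usage) is the observed count of a codon
divided by the count expected if its synonymous family were used
uniformly; family values sum to the family degeneracy. A codon is called
over-represented above 1.6 and under-represented below 0.6.

ENc (effective number of codons) is Wright's non-directional bias
statistic. For each amino acid with n >= 2 occurrences the codon
homozygosity is estimated as

    F = (n * sum(p_i^2) - 1) / (n - 1)

with p_i the within-family codon proportions; class means F̄_k over
amino acids of degeneracy k combine into

    ENc = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6

bounded to [20, 61]. Six-fold families (Leu, Ser, Arg) are treated as
single families. If the sole 3-fold family (Ile) is absent, F̄3 is
imputed as (F̄2 + F̄4)/2; if any other class cannot be estimated the
gene's ENc is undefined (``enc is None``).

CAI (codon adaptation index) is the geometric mean of relative
adaptiveness weights w(c) = RSCU_ref(c) / max RSCU_ref in c's family
over a gene's codons. ``cai59`` averages over all codon occurrences in
the 59 degenerate codons; ``cai18`` first takes the geometric mean
within each of the 18 degenerate amino-acid families present and then
averages those 18 family values, damping the contribution of amino-acid
composition to the index. Met, Trp and stop codons never contribute to
any of these statistics.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd

from .genetic_code import (
    AA_TO_CODONS,
    CODON_TO_AA,
    DEGENERACY,
    DEGENERATE_AAS,
    DEGENERATE_CODONS,
)
from .sequence_io import CodingSequence

__all__ = [
    "RSCU_UNDER",
    "RSCU_OVER",
    "RSCUTable",
    "ENcValue",
    "CAIResult",
    "ReferenceWeights",
    "rscu",
    "enc",
    "cai",
    "build_reference_weights",
    "rscu_frame",
]

RSCU_UNDER = 0.6
RSCU_OVER = 1.6

OVER = "OVER"
UNDER = "UNDER"
RANDOM = "RANDOM"
MISSING = "MISSING"


def _degenerate_codon_counts(cds: CodingSequence) -> Counter:
    """Counts over the gene's codons restricted to the 59 degenerate ones.

    The terminal stop is excluded via ``coding_codons``; ATG and TGG are
    dropped because their families have no synonymous choice.
    """
    counts = Counter(cds.coding_codons)
    return Counter({c: counts[c] for c in DEGENERATE_CODONS if counts[c]})


# ---------------------------------------------------------------------------
# RSCU


@dataclass(frozen=True)
class RSCUTable:
    """Per-gene RSCU over the 59 degenerate codons with usage classes.

    ``values[c]`` is NaN and ``classification[c]`` is ``"MISSING"`` when
    the encoding amino acid does not occur in the gene.
    """

    values: Mapping[str, float]
    classification: Mapping[str, str]

    def __getitem__(self, codon: str) -> float:
        return self.values[codon]


def rscu(cds: CodingSequence) -> RSCUTable:
    counts = _degenerate_codon_counts(cds)
    values: dict[str, float] = {}
    classes: dict[str, str] = {}
    for aa in DEGENERATE_AAS:
        family = AA_TO_CODONS[aa]
        total = sum(counts[c] for c in family)
        for c in family:
            if total == 0:
                values[c] = float("nan")
                classes[c] = MISSING
            else:
                v = counts[c] / (total / DEGENERACY[aa])
                values[c] = v
                classes[c] = OVER if v > RSCU_OVER else UNDER if v < RSCU_UNDER else RANDOM
    return RSCUTable(values, classes)


def rscu_frame(panel: Iterable[CodingSequence]) -> pd.DataFrame:
    """Genes × 59 RSCU matrix (NaN where the amino acid is absent)."""
    rows = {cds.gene_id: dict(rscu(cds).values) for cds in panel}
    return pd.DataFrame.from_dict(rows, orient="index", dtype=float)[
        list(DEGENERATE_CODONS)
    ].rename_axis("gene_id")


# ---------------------------------------------------------------------------
# ENc


@dataclass(frozen=True)
class ENcValue:
    """Wright's ENc for one gene; ``enc`` is None when not estimable."""

    enc: float | None
    family_means: Mapping[int, float]


_CLASS_WEIGHT = {2: 9.0, 3: 1.0, 4: 5.0, 6: 3.0}


def enc(cds: CodingSequence) -> ENcValue:
    counts = _degenerate_codon_counts(cds)
    f_by_class: dict[int, list[float]] = {k: [] for k in _CLASS_WEIGHT}
    for aa in DEGENERATE_AAS:
        family = AA_TO_CODONS[aa]
        n = sum(counts[c] for c in family)
        if n < 2:  # F undefined at n <= 1
            continue
        sum_p2 = sum((counts[c] / n) ** 2 for c in family)
        f = (n * sum_p2 - 1.0) / (n - 1.0)
        f_by_class[DEGENERACY[aa]].append(f)

    means: dict[int, float] = {
        k: sum(v) / len(v) for k, v in f_by_class.items() if v
    }
    if 3 not in means and 2 in means and 4 in means:
        means[3] = (means[2] + means[4]) / 2.0  # Ile absent: impute its class
    if set(means) != set(_CLASS_WEIGHT) or any(m <= 0 for m in means.values()):
        return ENcValue(None, means)
    value = 2.0 + sum(w / means[k] for k, w in _CLASS_WEIGHT.items())
    return ENcValue(min(61.0, max(20.0, value)), means)


# ---------------------------------------------------------------------------
# CAI


@dataclass(frozen=True)
class ReferenceWeights:
    """Relative adaptiveness w(c) in (0, 1] for the 59 degenerate codons."""

    w: Mapping[str, float]
    reference_id: str = "panel"

    def __post_init__(self) -> None:
        missing = set(DEGENERATE_CODONS) - set(self.w)
        if missing:
            raise ValueError(f"weights missing for codons: {sorted(missing)}")
        for c, v in self.w.items():
            if not 0.0 < v <= 1.0:
                raise ValueError(f"weight for {c} out of (0, 1]: {v}")

    def to_tsv(self, path: Union[str, Path]) -> None:
        lines = ["codon\tamino_acid\tweight\n"]
        lines += [
            f"{c}\t{CODON_TO_AA[c]}\t{self.w[c]:.6g}\n" for c in DEGENERATE_CODONS
        ]
        Path(path).write_text("".join(lines))

    @classmethod
    def from_tsv(cls, path: Union[str, Path], reference_id: str | None = None) -> "ReferenceWeights":
        df = pd.read_csv(path, sep="\t")
        return cls(
            dict(zip(df["codon"], df["weight"].astype(float))),
            reference_id or str(path),
        )


def build_reference_weights(
    source: Union[Iterable[CodingSequence], Mapping[str, float]],
    reference_id: str = "panel",
) -> ReferenceWeights:
    """Weights from pooled codon counts of a gene set (or a counts mapping).

    w(c) = RSCU_pooled(c) / max RSCU_pooled within c's family. A codon
    unobserved in the reference gets the small pseudo-weight
    0.5 / (family reference total) so geometric means stay positive; a
    family entirely absent from the reference is uninformative and gets
    w = 1 for all its codons.
    """
    if isinstance(source, Mapping):
        counts = Counter({c: float(v) for c, v in source.items()})
    else:
        panel = list(source)
        if not panel:
            raise ValueError("empty reference panel")
        counts = Counter()
        for cds in panel:
            counts.update(_degenerate_codon_counts(cds))

    w: dict[str, float] = {}
    for aa in DEGENERATE_AAS:
        family = AA_TO_CODONS[aa]
        total = sum(counts[c] for c in family)
        if total == 0:
            for c in family:
                w[c] = 1.0
            continue
        expected = total / DEGENERACY[aa]
        rscu_fam = {c: counts[c] / expected for c in family}
        top = max(rscu_fam.values())
        for c in family:
            w[c] = rscu_fam[c] / top if counts[c] > 0 else min(1.0, 0.5 / total)
    return ReferenceWeights(w, reference_id)


@dataclass(frozen=True)
class CAIResult:
    cai59: float
    cai18: float
    reference_id: str


def cai(cds: CodingSequence, ref: ReferenceWeights) -> CAIResult:
    """CAI59 and CAI18 of one gene against a reference weight table.

    Raises ValueError when the gene contains no degenerate-family codon
    (e.g. Met/Trp only), where both indices are undefined.
    """
    counts = _degenerate_codon_counts(cds)
    if not counts:
        raise ValueError(
            f"CAI undefined for {cds.gene_id!r}: no degenerate-family codons"
        )
    total = sum(counts.values())
    log_sum = sum(n * math.log(ref.w[c]) for c, n in counts.items())
    cai59 = math.exp(log_sum / total)

    family_logmeans = []
    for aa in DEGENERATE_AAS:
        family = AA_TO_CODONS[aa]
        n_fam = sum(counts[c] for c in family)
        if n_fam == 0:
            continue
        fam_log = sum(counts[c] * math.log(ref.w[c]) for c in family)
        family_logmeans.append(math.exp(fam_log / n_fam))
    cai18 = sum(family_logmeans) / len(family_logmeans)
    return CAIResult(cai59, cai18, ref.reference_id)
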