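"""Reading, validating and writing panels of coding sequences.

A *panel* is an ordered collection of CDS records, one per gene. On load,
each record is screened with the standard inclusion filters for codon
usage work: length a positive multiple of three, bases restricted to
A/C/G/T, and no internal stop codon. A terminal stop codon is legitimate
and retained (nucleotide-level statistics run over the full sequence);
amino-acid-level computations strip it downstream. Records failing a
filter are collected in a :class:`PanelRejectionReport` rather than
raising, so one bad record never aborts a panel analysis.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import STOP_CODONS

__all__ = [
    "CodingSequence",
    "PanelRejectionReport",
    "load_panel",
    "write_panel",
]

_VALID_BASES = frozenset("ACGT")

# rejection reason codes, checked in this order
EMPTY = "EMPTY"
NOT_MULTIPLE_OF_3 = "NOT_MULTIPLE_OF_3"
AMBIGUOUS_BASE = "AMBIGUOUS_BASE"
INTERNAL_STOP = "INTERNAL_STOP"


@dataclass(frozen=True)
class CodingSequence:
    """A validated CDS: uppercase A/C/G/T, length 3n, no internal stop.

    A terminal stop codon, if present, is part of ``seq`` and counted in
    ``codon_count``; use :attr:`coding_codons` for the stop-free codon list.
    """

    gene_id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        reason = classify_rejection(self.seq)
        if reason is not None:
            raise ValueError(f"invalid CDS {self.gene_id!r}: {reason}")

    @property
    def codon_count(self) -> int:
        return len(self.seq) // 3

    @property
    def codons(self) -> list[str]:
        return [self.seq[i : i + 3] for i in range(0, len(self.seq), 3)]

    @property
    def has_terminal_stop(self) -> bool:
        return self.seq[-3:] in STOP_CODONS

    @property
    def coding_codons(self) -> list[str]:
        """Codons excluding a terminal stop (for translation/RSCU/CAI/ENc)."""
        cs = self.codons
        if cs and cs[-1] in STOP_CODONS:
            cs = cs[:-1]
        return cs


def classify_rejection(seq: str) -> str | None:
    """Return the rejection reason code for a raw sequence, or None if valid.

    Assumes the sequence has already been upper-cased. Checks run in a fixed
    order (EMPTY, NOT_MULTIPLE_OF_3, AMBIGUOUS_BASE, INTERNAL_STOP) and the
    first failure wins, so every rejected record carries exactly one code.
    """
    if len(seq) == 0:
        return EMPTY
    if len(seq) % 3 != 0:
        return NOT_MULTIPLE_OF_3
    if not _VALID_BASES.issuperset(seq):
        return AMBIGUOUS_BASE
    for i in range(0, len(seq) - 3, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return INTERNAL_STOP
    return None


@dataclass
class PanelRejectionReport:
    """Records dropped at load time, as (gene_id, reason-code) pairs."""

    rejected: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rejected)

    def to_tsv(self, path_or_handle: Union[str, Path, TextIO]) -> None:
        lines = ["gene_id\treason\n"]
        lines += [f"{g}\t{r}\n" for g, r in self.rejected]
        if hasattr(path_or_handle, "write"):
            path_or_handle.writelines(lines)
        else:
            Path(path_or_handle).write_text("".join(lines))


def load_panel(
    fasta_source: Union[str, Path, TextIO],
) -> tuple[list[CodingSequence], PanelRejectionReport]:
    """Read a multi-FASTA of CDS records and apply the inclusion filters.

    Parameters
    ----------
    fasta_source
        Path to a FASTA file, or an open text handle, or a string that
        *is* FASTA text (starts with ``>``).

    Returns
    -------
    accepted, report
        Accepted sequences in input order, and the rejection report.
        Every input record appears exactly once across the two.

    Raises
    ------
    ValueError
        On malformed FASTA (no records / leading garbage) or duplicate ids.
    """
    handle: TextIO
    if isinstance(fasta_source, str) and fasta_source.lstrip().startswith(">"):
        handle = io.StringIO(fasta_source)
    elif hasattr(fasta_source, "read"):
        handle = fasta_source  # type: ignore[assignment]
    else:
        handle = open(fasta_source)  # noqa: SIM115 - closed below

    try:
        first = handle.readline()
        if not first.lstrip().startswith(">"):
            snippet = first.strip()[:60] or "<empty input>"
            raise ValueError(f"not FASTA: first line is {snippet!r}")
        handle.seek(0)
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if handle is not fasta_source:
            handle.close()

    if not records:
        raise ValueError("no FASTA records found")

    accepted: list[CodingSequence] = []
    report = PanelRejectionReport()
    seen: set[str] = set()
    for rec in records:
        gene_id = rec.id
        if not gene_id:
            raise ValueError("FASTA record with empty id")
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        seq = str(rec.seq).upper()
        reason = classify_rejection(seq)
        if reason is None:
            accepted.append(CodingSequence(gene_id, seq))
        else:
            report.rejected.append((gene_id, reason))
    return accepted, report


def write_panel(
    panel: Iterable[CodingSequence], path_or_handle: Union[str, Path, TextIO]
) -> None:
    """Write sequences as multi-FASTA (60-column wrap)."""
    records = [
        SeqRecord(Seq(cds.seq), id=cds.gene_id, description="") for cds in panel
    ]
    if hasattr(path_or_handle, "write"):
        SeqIO.write(records, path_or_handle, "fasta")
    else:
        with open(path_or_handle, "w") as fh:
            SeqIO.write(records, fh, "fasta")
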