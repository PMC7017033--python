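"""FASTA input and tabular output.

Sequences are carried as :class:`ProteinSequence`, a validated
one-letter-code string plus optional terminal-blocking flags.  Blocking a
terminus (N-terminal acetylation, C-terminal amidation) removes that
terminal ionizable group from all charge calculations; peptide hormones
such as IAPP and CRF are C-terminally amidated in vivo, which shifts
their isoelectric point.

FASTA records may set the flags through description tags::

    >my_peptide nterm_blocked cterm_blocked

Parsing goes through Bio.SeqIO; this module adds validation policies on
top (``strict`` rejects anything outside the 20 standard codes,
``lenient`` uppercases, strips whitespace and trailing stop characters).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO

from .errors import SequenceError
from .scales import AMINO_ACIDS

__all__ = ["ProteinSequence", "read_fasta", "write_fasta", "write_profile_table"]

_STANDARD = set(AMINO_ACIDS)


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence.

    Attributes
    ----------
    id : str
        Non-empty record identifier.
    residues : str
        Upper-case one-letter codes, all from the 20 standard amino acids.
    n_term_blocked, c_term_blocked : bool
        True if the corresponding terminal ionizable group is absent
        (chemically blocked); defaults model free termini.
    """

    id: str
    residues: str
    n_term_blocked: bool = False
    c_term_blocked: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise SequenceError(f"sequence {self.id!r} is empty")
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in _STANDARD:
                raise SequenceError(
                    f"sequence {self.id!r}: invalid residue {aa!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def with_blocked_termini(self) -> "ProteinSequence":
        return replace(self, n_term_blocked=True, c_term_blocked=True)


def _clean(raw: str, seq_id: str, policy: str) -> str:
    if policy == "lenient":
        raw = "".join(raw.split()).upper().rstrip("*")
    elif policy != "strict":
        raise ValueError(f"unknown policy {policy!r}; use 'strict' or 'lenient'")
    return raw


def read_fasta(
    path: Union[str, Path], policy: str = "strict"
) -> list[ProteinSequence]:
    """Read all records of a FASTA file, preserving order.

    ``strict`` rejects duplicate ids, lowercase letters and any character
    outside the 20 standard codes; ``lenient`` uppercases and strips
    whitespace and trailing ``*`` before validation.  Terminal-blocking
    tags (``nterm_blocked``, ``cterm_blocked``) are read from the record
    description.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    seqs: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in records:
        if policy == "strict" and rec.id in seen:
            raise SequenceError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        tags = set(rec.description.split()[1:])
        residues = _clean(str(rec.seq), rec.id, policy)
        seqs.append(
            ProteinSequence(
                id=rec.id,
                residues=residues,
                n_term_blocked="nterm_blocked" in tags,
                c_term_blocked="cterm_blocked" in tags,
            )
        )
    return seqs


def write_fasta(seqs: Iterable[ProteinSequence], path: Union[str, Path]) -> None:
    """Write sequences as FASTA, encoding blocked termini as description tags."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in seqs:
            tags = []
            if s.n_term_blocked:
                tags.append("nterm_blocked")
            if s.c_term_blocked:
                tags.append("cterm_blocked")
            header = s.id + ((" " + " ".join(tags)) if tags else "")
            fh.write(f">{header}\n")
            for i in range(0, len(s.residues), 60):
                fh.write(s.residues[i : i + 60] + "\n")


def write_profile_table(
    result, path: Union[str, Path], *, float_format: str = "%.6g"
) -> None:
    """Write a per-position profile or a pH curve as CSV.

    Accepts any object exposing ``to_frame()`` (ProfileResult,
    SolubilityCurve, ResidueSolubilityProfile).  Numbers use ``.`` as the
    decimal separator and the given printf-style format.
    """
    frame = result.to_frame()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(frame.columns)
        for row in frame.itertuples(index=False):
            writer.writerow(
                [
                    (float_format % v) if isinstance(v, float) else v
                    for v in row
                ]
            )
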