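"""Protein sequences, the nonstandard-residue policy, and FASTA input.

A *sequence store* is a plain ``dict`` mapping identifier to
:class:`ProteinSequence`; every other module consumes that shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO

from .errors import InvalidSequenceError

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes, alphabetical.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
AA_TO_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}

#: Letters that occur in reference proteomes but are not standard residues:
#: ambiguity codes (B, J, X, Z), selenocysteine/pyrrolysine (U, O) and stops.
NONSTANDARD = set("BJOUXZ*")

#: Fraction of a sequence that may be deleted by the nonstandard-letter
#: policy before the sequence is considered unsalvageable.
MAX_DELETED_FRACTION = 0.05


@dataclass(frozen=True)
class ProteinSequence:
    """An identifier plus an amino-acid string over the 20 standard codes.

    Construct via :func:`make_sequence` when the raw string may contain
    lowercase or nonstandard letters; direct construction validates only.
    """

    id: str
    residues: str
    description: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.residues:
            raise InvalidSequenceError(f"sequence {self.id!r}: empty residue string")
        bad = set(self.residues) - set(STANDARD_AA)
        if bad:
            raise InvalidSequenceError(
                f"sequence {self.id!r}: nonstandard letters {sorted(bad)} "
                "present after handling; use make_sequence() to apply a policy"
            )

    def __len__(self) -> int:
        return len(self.residues)


def sanitize_residues(
    raw: str,
    seq_id: str = "?",
    policy: str = "delete",
    max_deleted_fraction: float = MAX_DELETED_FRACTION,
) -> str:
    """Apply the nonstandard-letter policy to a raw residue string.

    policy='delete' (default) removes nonstandard letters and logs a warning
    with per-letter counts, raising if more than ``max_deleted_fraction`` of
    the sequence would be lost; policy='error' rejects any nonstandard
    letter outright. Input is upper-cased first.
    """
    if policy not in ("delete", "error"):
        raise ValueError(f"unknown nonstandard-residue policy {policy!r}")
    seq = raw.upper().replace("-", "").replace(".", "")
    bad = [c for c in seq if c not in STANDARD_AA]
    if not bad:
        return seq
    unknown = set(bad) - NONSTANDARD
    if unknown:
        raise InvalidSequenceError(
            f"sequence {seq_id!r}: letters {sorted(unknown)} are not amino-acid codes"
        )
    if policy == "error":
        raise InvalidSequenceError(
            f"sequence {seq_id!r}: contains nonstandard residues {sorted(set(bad))}"
        )
    if len(seq) == 0 or len(bad) / len(seq) > max_deleted_fraction:
        raise InvalidSequenceError(
            f"sequence {seq_id!r}: {len(bad)}/{len(seq)} residues are nonstandard "
            f"(> {max_deleted_fraction:.0%}); refusing to encode"
        )
    counts = {c: bad.count(c) for c in sorted(set(bad))}
    logger.warning("sequence %r: deleted nonstandard residues %s", seq_id, counts)
    return "".join(c for c in seq if c in STANDARD_AA)


def make_sequence(
    seq_id: str, raw: str, description: str = "", policy: str = "delete"
) -> ProteinSequence:
    """Build a validated :class:`ProteinSequence` from a raw string."""
    return ProteinSequence(
        id=seq_id,
        residues=sanitize_residues(raw, seq_id=seq_id, policy=policy),
        description=description,
    )


def read_fasta(path, policy: str = "delete") -> dict[str, ProteinSequence]:
    """Read a multi-record FASTA file into a sequence store.

    Handles wrapped lines and case-insensitive residues (delegated to
    Biopython); duplicate identifiers raise.
    """
    store: dict[str, ProteinSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in store:
            raise InvalidSequenceError(f"duplicate FASTA identifier {rec.id!r}")
        store[rec.id] = make_sequence(
            rec.id, str(rec.seq), description=rec.description, policy=policy
        )
    if not store:
        raise InvalidSequenceError(f"no FASTA records found in {path}")
    return store


def write_fasta(store: dict[str, ProteinSequence], path, width: int = 60) -> None:
    """Write a sequence store as wrapped FASTA."""
    with open(path, "w") as fh:
        for seq in store.values():
            header = seq.id if not seq.description or seq.description == seq.id else f"{seq.id} {seq.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")
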