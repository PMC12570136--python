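"""Sequence records, formal-charge accounting, and counter-ion arithmetic.

Charge accounting follows common MD system-preparation practice at pH 7:
Asp/Glu carry -1, Lys/Arg +1, His is neutral, and free zwitterionic
termini net zero.  An RNA with a 5'-OH terminus carries one negative
charge per phosphodiester linkage, i.e. length - 1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from io import StringIO

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "AlphabetError",
    "sequence_from_letters",
    "read_fasta",
    "formal_charge",
    "neutralizing_ion_count",
]

PROTEIN_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")
RNA_LETTERS = set("ACGU")

_DIRECTION_DECORATIONS = ("5'-", "-3'", "5′-", "-3′", "5-", "-3")


class AlphabetError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    polymer_type: str  # "protein" | "rna"
    letters: str

    def __post_init__(self) -> None:
        alphabet = PROTEIN_LETTERS if self.polymer_type == "protein" else RNA_LETTERS
        for ch in self.letters:
            if ch not in alphabet:
                raise AlphabetError(
                    f"letter {ch!r} is not in the {self.polymer_type} alphabet"
                )

    def __len__(self) -> int:
        return len(self.letters)

    @property
    def composition(self) -> dict[str, int]:
        return dict(Counter(self.letters))


def _strip_decorations(letters: str) -> str:
    s = "".join(letters.split())
    for deco in _DIRECTION_DECORATIONS:
        s = s.replace(deco, "")
    # lone prime-style markers left over (e.g. "5'" without dash)
    s = s.replace("′", "'").replace("5'", "").replace("3'", "").replace("-", "")
    return s.upper()


def sequence_from_letters(letters: str, polymer_type: str) -> SequenceRecord:
    """Build a SequenceRecord from a one-letter string.

    Direction decorations (5'-, -3') and whitespace are stripped first, so
    sequences can be pasted verbatim from publications.
    """
    if polymer_type not in ("protein", "rna"):
        raise ValueError(f"unknown polymer type {polymer_type!r}")
    cleaned = _strip_decorations(letters)
    if not cleaned:
        raise ValueError("sequence is empty after stripping decorations")
    return SequenceRecord(polymer_type=polymer_type, letters=cleaned)


def read_fasta(text: str, polymer_type: str) -> SequenceRecord:
    """Read a single-record FASTA string."""
    records = list(SeqIO.parse(StringIO(text), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, found {len(records)}")
    return sequence_from_letters(str(records[0].seq), polymer_type)


def formal_charge(sequence: SequenceRecord, scheme: str = "pH7-standard") -> int:
    """Net formal charge of a chain in elementary charges.

    Protein (pH7-standard): D/E -1, K/R +1, H 0, termini net 0.
    RNA (5'-OH): -(length - 1), one per phosphodiester linkage.
    """
    if scheme != "pH7-standard":
        raise ValueError(f"unknown protonation scheme {scheme!r}")
    if sequence.polymer_type == "rna":
        return -(len(sequence) - 1)
    comp = sequence.composition
    negative = comp.get("D", 0) + comp.get("E", 0)
    positive = comp.get("K", 0) + comp.get("R", 0)
    return positive - negative


def neutralizing_ion_count(charges: list[int]) -> tuple[str, int]:
    """Counter-ion species and count that neutralize the summed charge.

    Returns ("cation", |sum|) for net-negative systems, ("anion", sum) for
    net-positive ones, and ("cation", 0) for an already-neutral system.
    """
    total = sum(charges)
    if total < 0:
        return ("cation", -total)
    if total > 0:
        return ("anion", total)
    return ("cation", 0)
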