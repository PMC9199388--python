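"""Nucleotide sequence primitives: records, reverse complementation, k-mer windows.

Sequences are plain upper-case strings over the DNA alphabet {A, C, G, T, N}.
RNA input (U) is normalized to T at ingestion so rRNA and genomic records
behave identically downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List, Sequence, Tuple

from .errors import InvalidAlphabetError, InvalidInputError, InvalidParameterError

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Allowed roles for a :class:`SequenceRecord`.
ROLES = ("target", "host", "background")


def normalize_sequence(seq: str, *, context: str = "") -> str:
    """Upper-case ``seq`` and map U/u to T, validating the alphabet.

    Raises
    ------
    InvalidAlphabetError
        Naming the first offending character and its 0-based position.
    """
    up = seq.upper().replace("U", "T")
    for i, ch in enumerate(up):
        if ch not in DNA_ALPHABET:
            raise InvalidAlphabetError(ch, i, context)
    return up


def reverse_complement(seq: str) -> str:
    """Return the reverse complement of a DNA sequence (N maps to N).

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    The empty string is rejected: a probe or target of length zero is
    always a caller bug.
    """
    if seq == "":
        raise InvalidInputError("cannot reverse-complement an empty sequence")
    for i, ch in enumerate(seq):
        if ch not in DNA_ALPHABET:
            raise InvalidAlphabetError(ch, i)
    return seq.translate(_COMPLEMENT)[::-1]


def enumerate_kmers(seq: str, k: int) -> List[Tuple[int, str]]:
    """Every k-length window of ``seq`` as ``(position, kmer)``, 0-based.

    Returns exactly ``max(0, len(seq) - k + 1)`` entries with strictly
    increasing positions; a sequence shorter than ``k`` yields an empty
    list rather than an error.
    """
    if k <= 0:
        raise InvalidParameterError(f"k must be positive, got {k}")
    return [(i, seq[i : i + k]) for i in range(len(seq) - k + 1)]


def iter_kmers(seq: str, k: int) -> Iterator[Tuple[int, str]]:
    """Lazy variant of :func:`enumerate_kmers` (same contract)."""
    if k <= 0:
        raise InvalidParameterError(f"k must be positive, got {k}")
    for i in range(len(seq) - k + 1):
        yield i, seq[i : i + k]


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide sequence with a role in probe design.

    Parameters
    ----------
    id : str
        Unique identifier within an input set.
    sequence : str
        Nucleotides over {A, C, G, T, N}; normalized (upper-case, U→T)
        in ``__post_init__``.
    role : str
        One of ``target`` (the taxon the probe must hit), ``host``
        (the organism the probe must avoid) or ``background`` (other
        assembled contigs screened for specificity).
    """

    id: str
    sequence: str
    role: str

    def __post_init__(self):
        if not self.id:
            raise InvalidInputError("record id must be non-empty")
        if self.role not in ROLES:
            raise InvalidInputError(
                f"role must be one of {ROLES}, got {self.role!r}"
            )
        norm = normalize_sequence(self.sequence, context=f"record {self.id!r}")
        if not norm:
            raise InvalidInputError(f"record {self.id!r} has an empty sequence")
        object.__setattr__(self, "sequence", norm)

    def __len__(self) -> int:
        return len(self.sequence)


def check_unique_ids(records: Sequence[SequenceRecord]) -> None:
    """Raise :class:`InvalidInputError` on duplicate record ids."""
    seen = set()
    for r in records:
        if r.id in seen:
            raise InvalidInputError(f"duplicate record id {r.id!r}")
        seen.add(r.id)
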