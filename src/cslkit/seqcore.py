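"""Nucleic-acid sequence primitives shared by all other modules.

The package works on plain DNA strings over the strict {A, C, G, T}
alphabet.  Degenerate IUPAC codes are rejected at construction time:
sequences designed here end up on an oligonucleotide synthesis sheet,
where an ambiguous base would be a silent ordering error.

Coordinates are 0-based, half-open, on the sense strand of the
referenced transcript — the BED convention used at every file
interface.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

from Bio import SeqIO
from Bio.Seq import Seq as _BioSeq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlphabetError",
    "Sequence",
    "Interval",
    "Match",
    "reverse_complement",
    "gc_fraction",
    "longest_shared_substring",
    "read_fasta",
    "write_fasta",
    "read_bed",
]

_VALID_BASES = re.compile(r"^[ACGT]+$")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AlphabetError(ValueError):
    """Raised for empty sequences or characters outside {A, C, G, T}."""


@dataclass(frozen=True)
class Sequence:
    """An identified DNA strand, written 5'→3'."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases or not _VALID_BASES.match(self.bases):
            raise AlphabetError(
                f"sequence {self.id!r} must be a non-empty A/C/G/T string "
                "(degenerate IUPAC codes are not accepted)"
            )

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases


@dataclass(frozen=True)
class Interval:
    """A 0-based half-open interval on the sense strand of a transcript."""

    transcript_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.transcript_id}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        """Number of shared bases with ``other`` (0 if different transcripts)."""
        if self.transcript_id != other.transcript_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def _bases(seq: "Sequence | str") -> str:
    return seq.bases if isinstance(seq, Sequence) else seq


def reverse_complement(seq: "Sequence | str") -> "Sequence | str":
    """Watson–Crick reverse complement; the identifier is preserved.

    Accepts either a :class:`Sequence` or a bare string and returns the
    same type.  An involution: ``reverse_complement(reverse_complement(s))``
    restores ``s``.
    """
    if isinstance(seq, Sequence):
        return Sequence(seq.id, seq.bases.translate(_COMPLEMENT)[::-1])
    if not seq or not _VALID_BASES.match(seq):
        raise AlphabetError("reverse_complement requires a non-empty A/C/G/T string")
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: "Sequence | str") -> float:
    """Fraction of G+C bases, in [0, 1]."""
    s = _bases(seq)
    if not s or not _VALID_BASES.match(s):
        raise AlphabetError("gc_fraction requires a non-empty A/C/G/T string")
    return (s.count("G") + s.count("C")) / len(s)


class Match(NamedTuple):
    """Longest exact shared substring between two sequences.

    ``b_start`` is always expressed in the forward coordinates of ``b``;
    ``strand`` is '+' when the shared block lies on ``b`` itself and '-'
    when it lies on the reverse complement of ``b``.  A zero-length match
    carries ``None`` positions.
    """

    length: int
    a_start: "int | None"
    b_start: "int | None"
    strand: str = "+"


def _has_common(a: str, b: str, k: int) -> bool:
    # membership test on the k-mer set of the shorter string
    if k > min(len(a), len(b)):
        return False
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    kmers = {short[i : i + k] for i in range(len(short) - k + 1)}
    return any(long_[j : j + k] in kmers for j in range(len(long_) - k + 1))


def _best_positions(a: str, b: str, k: int) -> "tuple[int, int]":
    # earliest start in a, then earliest start in b for that substring
    first_in_b: dict[str, int] = {}
    for j in range(len(b) - k + 1):
        first_in_b.setdefault(b[j : j + k], j)
    for i in range(len(a) - k + 1):
        j = first_in_b.get(a[i : i + k])
        if j is not None:
            return i, j
    raise AssertionError("no common substring at the verified length")


def _lss_oriented(a: str, b: str) -> Match:
    lo, hi, best = 1, min(len(a), len(b)), 0
    while lo <= hi:
        mid = (lo + hi) // 2
        if _has_common(a, b, mid):
            best, lo = mid, mid + 1
        else:
            hi = mid - 1
    if best == 0:
        return Match(0, None, None, "+")
    i, j = _best_positions(a, b, best)
    return Match(best, i, j, "+")


def longest_shared_substring(
    a: "Sequence | str", b: "Sequence | str", both_strands: bool = False
) -> Match:
    """Longest exact substring shared by ``a`` and ``b``.

    Uses a binary search over the match length with exact k-mer set
    membership (no hashing collisions), O((|a|+|b|)·log min(|a|,|b|)).
    With ``both_strands`` the reverse complement of ``b`` is searched as
    well and the longer match wins; on an exact tie the forward strand is
    reported.  Ties within one orientation resolve to the smallest start
    in ``a``, then the smallest start in ``b``.
    """
    sa, sb = _bases(a), _bases(b)
    fwd = _lss_oriented(sa, sb)
    if not both_strands:
        return fwd
    rev = _lss_oriented(sa, reverse_complement(sb))
    if rev.length > fwd.length:
        # map back into forward coordinates of b
        b_start = len(sb) - rev.b_start - rev.length
        return Match(rev.length, rev.a_start, b_start, "-")
    return fwd


# ---------------------------------------------------------------------------
# file interfaces


def read_fasta(path: "str | Path") -> list[Sequence]:
    """Read a (multi-record, wrapped or unwrapped) FASTA file.

    Bases are upper-cased before validation; anything outside A/C/G/T
    raises :class:`AlphabetError`.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(Sequence(rec.id, str(rec.seq).upper()))
    return records


def write_fasta(seqs: Iterable[Sequence], path: "str | Path", width: int = 70) -> None:
    records = [SeqRecord(_BioSeq(s.bases), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_bed(path: "str | Path") -> list[Interval]:
    """Read BED3/BED6 target regions (extra columns ignored).

    Strand columns are ignored: intervals always refer to the sense
    strand; which strand a probe binds is decided by the tiling rule.
    """
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            intervals.append(Interval(fields[0], int(fields[1]), int(fields[2])))
    return intervals
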