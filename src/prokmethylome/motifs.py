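"""Degenerate (IUPAC) recognition motifs: location, symmetry and RM typing.

A methyltransferase recognition motif is written over the IUPAC alphabet
(e.g. GATC, RAATTY, CAGNNNNNTCA) with one methylatable base per strand.
Palindromic motifs — equal to their own reverse complement — carry a
methylatable base on each strand and are the substrate of the
unmethylated-site analysis; asymmetric motifs are methylated on one strand
only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .io_formats import GenomeRecord

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}


def _check_pattern(pattern: str) -> None:
    bad = set(pattern) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC symbols {sorted(bad)} in {pattern!r}")


def reverse_complement(pattern: str) -> str:
    """IUPAC-aware reverse complement (works for genomes and motifs alike)."""
    _check_pattern(pattern)
    return "".join(_COMPLEMENT[c] for c in reversed(pattern))


def is_palindrome(pattern: str) -> bool:
    """True iff the motif equals its own IUPAC reverse complement."""
    return reverse_complement(pattern) == pattern


@dataclass(frozen=True)
class MotifSpec:
    """A recognition motif with its methylatable base(s).

    ``meth_offset_fwd`` is the 0-based index of the methylated base on the
    strand matching the pattern; ``meth_offset_rev``, present only for
    palindromic double-strand motifs, is the index (still in pattern
    coordinates) of the base methylated on the complementary strand.
    """

    pattern: str
    meth_offset_fwd: int
    mod_type: str  # m6A, m4C or m5C
    meth_offset_rev: Optional[int] = None

    def __post_init__(self):
        _check_pattern(self.pattern)
        if len(self.pattern) < 2:
            raise ValueError("motif pattern must be at least 2 symbols")
        if not (0 <= self.meth_offset_fwd < len(self.pattern)):
            raise ValueError("meth_offset_fwd outside pattern")
        if self.mod_type not in ("m6A", "m4C", "m5C"):
            raise ValueError(f"unknown modification type {self.mod_type!r}")
        target = "A" if self.mod_type == "m6A" else "C"
        sym = self.pattern[self.meth_offset_fwd]
        if target not in IUPAC[sym]:
            raise ValueError(
                f"pattern symbol {sym!r} at offset {self.meth_offset_fwd} "
                f"cannot carry a {self.mod_type} mark"
            )
        if self.meth_offset_rev is not None:
            if not is_palindrome(self.pattern):
                raise ValueError(
                    "meth_offset_rev only valid for palindromic motifs"
                )
            if not (0 <= self.meth_offset_rev < len(self.pattern)):
                raise ValueError("meth_offset_rev outside pattern")

    @classmethod
    def palindromic(cls, pattern: str, meth_offset_fwd: int, mod_type: str) -> "MotifSpec":
        """Build a double-strand motif, deriving the reverse-strand offset."""
        if not is_palindrome(pattern):
            raise ValueError(f"{pattern!r} is not palindromic")
        return cls(pattern, meth_offset_fwd, mod_type,
                   meth_offset_rev=len(pattern) - 1 - meth_offset_fwd)

    @property
    def is_double_strand(self) -> bool:
        return self.meth_offset_rev is not None

    @property
    def methylated_base(self) -> str:
        return "A" if self.mod_type == "m6A" else "C"

    def canonical_pattern(self) -> str:
        """Lexicographically smaller of pattern and its reverse complement."""
        return min(self.pattern, reverse_complement(self.pattern))


@dataclass(frozen=True)
class MotifInstance:
    """A located motif occurrence: footprint plus methylatable-base coordinates.

    ``meth_pos_fwd`` is the genome coordinate (0-based, forward strand) of the
    base methylated on the forward strand; ``meth_pos_rev`` the forward-strand
    coordinate of the base methylated on the reverse strand.
    """

    contig_id: str
    start: int  # 0-based half-open footprint
    end: int
    strand_of_match: str  # '+' or '-'
    meth_pos_fwd: Optional[int] = None
    meth_pos_rev: Optional[int] = None

    def __post_init__(self):
        for pos in (self.meth_pos_fwd, self.meth_pos_rev):
            if pos is not None and not (self.start <= pos < self.end):
                raise ValueError("methylated position outside footprint")


@dataclass(frozen=True)
class MotifTypeCall:
    category: str  # TypeI_bipartite, TypeII_palindromic, TypeIII_like, TypeIIG_like
    rationale: str


def _pattern_to_regex(pattern: str) -> str:
    # N in the GENOME never matches, so character classes list concrete
    # bases only; even the pattern symbol N excludes genomic N.
    parts = []
    for sym in pattern:
        opts = IUPAC[sym]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return "".join(parts)


def find_motif_instances(genome: GenomeRecord, motif: MotifSpec) -> list[MotifInstance]:
    """All occurrences of the motif on both strands, in ascending start order.

    Overlapping occurrences are all reported.  For palindromic double-strand
    motifs each genomic site appears exactly once, with both methylatable
    positions populated.  For asymmetric motifs, forward-strand matches carry
    ``meth_pos_fwd`` and reverse-strand matches ``meth_pos_rev`` (both given
    as forward-strand coordinates).
    """
    seq = genome.sequence
    L = len(motif.pattern)
    if L > len(seq):
        return []
    instances: list[MotifInstance] = []
    fwd_re = re.compile(f"(?=({_pattern_to_regex(motif.pattern)}))")
    if motif.is_double_strand:
        for m in fwd_re.finditer(seq):
            s = m.start()
            instances.append(
                MotifInstance(
                    genome.contig_id, s, s + L, "+",
                    meth_pos_fwd=s + motif.meth_offset_fwd,
                    meth_pos_rev=s + motif.meth_offset_rev,
                )
            )
        return instances
    for m in fwd_re.finditer(seq):
        s = m.start()
        instances.append(
            MotifInstance(genome.contig_id, s, s + L, "+",
                          meth_pos_fwd=s + motif.meth_offset_fwd)
        )
    rev_re = re.compile(f"(?=({_pattern_to_regex(reverse_complement(motif.pattern))}))")
    for m in rev_re.finditer(seq):
        s = m.start()
        instances.append(
            MotifInstance(genome.contig_id, s, s + L, "-",
                          meth_pos_rev=s + (L - 1 - motif.meth_offset_fwd))
        )
    instances.sort(key=lambda i: (i.start, i.strand_of_match))
    return instances


def classify_motif(motif: MotifSpec) -> MotifTypeCall:
    """Assign a restriction-modification architecture from pattern structure.

    Bipartite patterns (an internal run of >=3 Ns between two specific
    half-sites) are Type I.  Palindromic double-strand motifs are classic
    Type II.  Among the remaining single-strand-methylated motifs, short
    recognition sequences (<=5 specific positions) behave like Type III
    systems and longer ones (>=6) like Type IIG.
    """
    pattern = motif.pattern
    internal = pattern[1:-1]
    n_run = re.search(r"N{3,}", internal)
    if n_run and pattern[0] != "N" and pattern[-1] != "N":
        return MotifTypeCall(
            "TypeI_bipartite",
            f"internal spacer of {len(n_run.group())} Ns between specific half-sites",
        )
    if motif.is_double_strand and is_palindrome(pattern):
        return MotifTypeCall("TypeII_palindromic", "palindrome methylated on both strands")
    n_specific = sum(1 for c in pattern if c != "N")
    if n_specific <= 5:
        return MotifTypeCall(
            "TypeIII_like", f"{n_specific} specific positions (<=5)"
        )
    return MotifTypeCall("TypeIIG_like", f"{n_specific} specific positions (>=6)")


def mean_intermotif_distance(instances: list[MotifInstance],
                             genome: GenomeRecord | None = None) -> float:
    """Mean successive start-to-start distance along the ordered instances."""
    if len(instances) < 2:
        raise ValueError("need at least 2 instances for a mean distance")
    starts = sorted(i.start for i in instances)
    gaps = [b - a for a, b in zip(starts, starts[1:])]
    return sum(gaps) / len(gaps)
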