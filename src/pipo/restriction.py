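"""Restriction-enzyme modeling and exhaustive site scanning.

Recognition patterns are IUPAC strings with a single caret marking the
top-strand cut position ("G^AATTC"). Scanning covers both strands, with
degeneracy expanded, and optionally treats the sequence as circular so
that sites spanning the origin are found. Palindromic patterns are
reported once per physical site (strand '+').
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .seqcore import InputError, IUPAC_CODES, reverse_complement

logger = logging.getLogger("pipo")

# IUPAC code -> concrete base set, for regex character classes.
IUPAC_TO_BASES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class RestrictionEnzyme:
    name: str
    recognition: str  # IUPAC pattern, caret removed
    cut_offset: int   # top-strand cut index within the pattern

    def __post_init__(self):
        if len(self.recognition) < 4:
            raise InputError(f"enzyme {self.name!r}: recognition shorter than 4 bp")
        bad = set(self.recognition) - IUPAC_CODES
        if bad:
            raise InputError(f"enzyme {self.name!r}: illegal pattern character(s) {sorted(bad)}")
        if not (0 <= self.cut_offset <= len(self.recognition)):
            raise InputError(f"enzyme {self.name!r}: cut offset {self.cut_offset} outside pattern")

    @property
    def site_len(self) -> int:
        return len(self.recognition)

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == reverse_complement(self.recognition)

    @property
    def is_concrete(self) -> bool:
        return set(self.recognition) <= set("ACGT")


@dataclass(frozen=True)
class SiteHit:
    """One located recognition-site occurrence on the forward strand."""

    enzyme: str
    start: int      # 0-based position of the match on the forward strand
    strand: str     # '+' or '-'


def parse_enzyme_list(text: str) -> list[RestrictionEnzyme]:
    """Parse a plain-text enzyme list: one "Name RECOG^NITION" per line.

    '#' begins a comment line. File order is preserved — it is the
    tie-break preference order everywhere downstream. A pattern without a
    caret gets a mid-pattern cut with a logged notice.
    """
    enzymes: list[RestrictionEnzyme] = []
    seen: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise InputError(f"enzyme list line {lineno}: expected 'Name PATTERN', got {line!r}")
        name, pattern = parts
        if name in seen:
            raise InputError(f"enzyme list line {lineno}: duplicate enzyme name {name!r}")
        seen.add(name)
        pattern = pattern.upper()
        if pattern.count("^") > 1:
            raise InputError(f"enzyme list line {lineno}: more than one caret in {pattern!r}")
        if "^" in pattern:
            cut_offset = pattern.index("^")
            recognition = pattern.replace("^", "")
        else:
            recognition = pattern
            cut_offset = len(recognition) // 2
            logger.info(
                "enzyme %s: no caret in %r, assuming mid-pattern cut at offset %d",
                name, pattern, cut_offset,
            )
        enzymes.append(RestrictionEnzyme(name=name, recognition=recognition, cut_offset=cut_offset))
    if not enzymes:
        raise InputError("enzyme list contains no enzymes")
    return enzymes


def _pattern_regex(pattern: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported
    body = "".join(
        c if len(IUPAC_TO_BASES[c]) == 1 else "[" + IUPAC_TO_BASES[c] + "]"
        for c in pattern
    )
    return re.compile(f"(?={body})")


def find_sites(
    seq: str,
    enzyme: RestrictionEnzyme,
    topology: str = "linear",
) -> list[SiteHit]:
    """All recognition-site occurrences of ``enzyme`` in ``seq``, both strands.

    Circular topology additionally finds sites spanning the origin (match
    positions reported modulo the sequence length). When the forward and
    reverse-complement patterns both match at the same position (palindromes,
    and degenerate patterns whose orientations overlap) a single '+' hit is
    reported for the physical site. Hits are sorted by start position.
    """
    if topology not in ("linear", "circular"):
        raise InputError(f"unknown topology {topology!r}")
    m = enzyme.site_len
    L = len(seq)
    if L < m:
        return []
    if topology == "circular":
        scan_seq = seq + seq[: m - 1]
    else:
        scan_seq = seq

    hits: dict[int, str] = {}
    for pattern, strand in ((enzyme.recognition, "+"), (reverse_complement(enzyme.recognition), "-")):
        if strand == "-" and enzyme.is_palindromic:
            continue
        for match in _pattern_regex(pattern).finditer(scan_seq):
            start = match.start() % L
            prev = hits.get(start)
            if prev is None or (prev == "-" and strand == "+"):
                hits[start] = strand
    return [SiteHit(enzyme=enzyme.name, start=s, strand=hits[s]) for s in sorted(hits)]


def top_strand_cut(hit: SiteHit, enzyme: RestrictionEnzyme) -> int:
    """Top-strand cut coordinate of a hit on the forward strand.

    For a '-' strand hit the enzyme's cut offset counts from the other end
    of the recognition footprint.
    """
    if hit.strand == "+":
        return hit.start + enzyme.cut_offset
    return hit.start + enzyme.site_len - enzyme.cut_offset


def count_sites(seq: str, enzyme: RestrictionEnzyme, topology: str = "linear") -> int:
    return len(find_sites(seq, enzyme, topology))


def is_unique(seq: str, enzyme: RestrictionEnzyme, topology: str = "linear") -> bool:
    return count_sites(seq, enzyme, topology) == 1
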