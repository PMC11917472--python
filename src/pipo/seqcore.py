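"""Sequence primitives and gene-locus handling.

A gene-of-interest (GOI) file carries the tripartite locus used throughout
the pipeline: a fixed-length 5' flanking region (FR), the ORF, and a
fixed-length 3' flanking region, concatenated in genomic 5'->3' order.
Coordinates are 0-based, half-open everywhere; locus coordinate 0 is the
first base of the 5' FR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

logger = logging.getLogger("pipo")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

# Watson-Crick complement including IUPAC ambiguity codes (enzyme patterns
# may be degenerate; locus/backbone sequences must be concrete A/C/G/T).
_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

IUPAC_CODES = frozenset(_COMPLEMENT)


class PipoError(Exception):
    """Base class for all package errors."""


class InputError(PipoError):
    """Malformed or inconsistent user input."""


class AlphabetError(InputError):
    """Sequence contains characters outside the allowed alphabet."""


class SimulationError(PipoError):
    """Recombination simulation could not proceed (carries a code)."""

    def __init__(self, code: str, message: str):
        super().__init__(f"{code}: {message}")
        self.code = code


def clean_sequence(raw: str, *, allow_iupac: bool = False, what: str = "sequence") -> str:
    """Uppercase-normalize and validate a nucleotide string.

    Locus and backbone sequences must be strict A/C/G/T; enzyme recognition
    patterns may additionally use IUPAC ambiguity codes.
    """
    seq = "".join(raw.split()).upper()
    if not seq:
        raise InputError(f"empty {what}")
    allowed = IUPAC_CODES if allow_iupac else frozenset("ACGT")
    bad = set(seq) - allowed
    if bad:
        raise AlphabetError(
            f"illegal character(s) {sorted(bad)} in {what} "
            f"(allowed: {'IUPAC codes' if allow_iupac else 'A/C/G/T'})"
        )
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement; supports IUPAC ambiguity codes."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError as exc:
        raise AlphabetError(f"unknown nucleotide character {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class GeneLocus:
    """Tripartite input locus: 5' FR + ORF + 3' FR."""

    name: str
    upstream: str
    orf: str
    downstream: str

    def __post_init__(self):
        if len(self.upstream) != len(self.downstream):
            raise InputError(
                f"locus {self.name!r}: flanking regions differ in length "
                f"({len(self.upstream)} vs {len(self.downstream)})"
            )

    @property
    def flank_len(self) -> int:
        return len(self.upstream)

    @property
    def full(self) -> str:
        return self.upstream + self.orf + self.downstream

    def __len__(self) -> int:
        return len(self.upstream) + len(self.orf) + len(self.downstream)


@dataclass
class ValidationReport:
    """Coded biological-sanity findings; warnings never abort a run."""

    warnings: list[tuple[str, str, tuple[int, int]]] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not self.warnings

    def add(self, code: str, message: str, interval: tuple[int, int]) -> None:
        self.warnings.append((code, message, interval))
        logger.warning("%s: %s", code, message)


def parse_goi(raw: str, flank_len: int, name: str = "GOI") -> GeneLocus:
    """Partition a raw GOI sequence into 5' FR / ORF / 3' FR.

    The first and last ``flank_len`` bases are the flanking regions; the
    remainder is the ORF, which must be nonempty.
    """
    seq = clean_sequence(raw, what=f"locus {name!r}")
    minimum = 2 * flank_len + 3
    if len(seq) < minimum:
        raise InputError(
            f"locus {name!r} is {len(seq)} bp; at least {minimum} bp required "
            f"(2 x {flank_len} bp flanks plus a nonempty ORF)"
        )
    return GeneLocus(
        name=name,
        upstream=seq[:flank_len],
        orf=seq[flank_len : len(seq) - flank_len],
        downstream=seq[len(seq) - flank_len :],
    )


def validate_locus(
    locus: GeneLocus,
    overlaps: list[tuple[int, int]] | None = None,
) -> ValidationReport:
    """Biological sanity checks on a parsed locus.

    Checks for the canonical start/stop codons at the ORF termini, a
    codon-multiple ORF length, and intersection of user-supplied
    overlapping-ORF intervals (locus coordinates) with either flank.
    Anomalies are reported as warnings, never raised.
    """
    report = ValidationReport()
    U, O = locus.flank_len, len(locus.orf)
    if locus.orf[:3] != START_CODON:
        report.add(
            "START_CODON_MISSING",
            f"ORF of {locus.name!r} does not begin with ATG (found {locus.orf[:3]!r})",
            (U, U + 3),
        )
    if locus.orf[-3:] not in STOP_CODONS:
        report.add(
            "STOP_CODON_MISSING",
            f"ORF of {locus.name!r} does not end with a stop codon (found {locus.orf[-3:]!r})",
            (U + O - 3, U + O),
        )
    if O % 3 != 0:
        report.add(
            "ORF_LENGTH_NOT_CODON_MULTIPLE",
            f"ORF length {O} of {locus.name!r} is not a multiple of 3",
            (U, U + O),
        )
    for interval in overlaps or []:
        start, end = interval
        if end <= start or start < 0 or end > len(locus):
            raise InputError(f"malformed overlap interval {interval!r} for locus of length {len(locus)}")
        for reg_name, reg in (("5' FR", (0, U)), ("3' FR", (U + O, len(locus)))):
            if start < reg[1] and end > reg[0]:
                report.add(
                    "ORF_OVERLAP",
                    f"overlapping ORF interval [{start}, {end}) intersects the {reg_name}",
                    (max(start, reg[0]), min(end, reg[1])),
                )
    return report


def read_fasta_single(path: str | Path, *, what: str = "sequence") -> tuple[str, str]:
    """Read a single-record FASTA file; returns (record id, sequence).

    Multi-record files are an error: every input of the pipeline (locus,
    backbone, linker, tag gene) is one sequence per file.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"{path}: no FASTA records found ({what})")
    if len(records) > 1:
        raise InputError(f"{path}: expected a single FASTA record, found {len(records)}")
    rec = records[0]
    return rec.id, str(rec.seq)
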