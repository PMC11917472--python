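"""Deterministic synthetic test data with planted restriction-site geometry.

Generates gene loci, vector backbones, linkers and tag genes whose
restriction-site content is fully controlled: requested sites are planted
at exact, known distances from the region junctions and every other
occurrence of the working enzyme set is scrubbed from the random
background (GC fraction ~0.40, resembling yeast intergenic sequence).
ORF and tag-gene backgrounds are built codon-wise with no internal stop
codons, so reading-frame properties of tagged fusions are testable.
Everything is reproducible from an integer seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .design import DesignParams
from .restriction import RestrictionEnzyme, find_sites, parse_enzyme_list
from .seqcore import GeneLocus, PipoError, STOP_CODONS

BASES = "ACGT"
BASE_P = (0.30, 0.20, 0.20, 0.30)  # GC ~ 0.40
NONSTOP_CODONS = tuple(
    "".join(c) for c in itertools.product(BASES, repeat=3) if "".join(c) not in STOP_CODONS
)


class FixtureError(PipoError):
    """Infeasible fixture specification."""


DEFAULT_ENZYMES_TEXT = """\
# name    recognition (caret marks the top-strand cut)
EcoRI     G^AATTC
BamHI     G^GATCC
HindIII   A^AGCTT
XhoI      C^TCGAG
SalI      G^TCGAC
SpeI      A^CTAGT
XbaI      T^CTAGA
PstI      CTGCA^G
NheI      G^CTAGC
KpnI      GGTAC^C
BglII     A^GATCT
ClaI      AT^CGAT
SacI      GAGCT^C
SmaI      CCC^GGG
"""

DEFAULT_TAG_ENZYMES_TEXT = """\
# 6-cutters reserved for the exchangeable linker/tag-gene boundaries
NheI      G^CTAGC
KpnI      GGTAC^C
PstI      CTGCA^G
BglII     A^GATCT
ClaI      AT^CGAT
SmaI      CCC^GGG
"""

# glycine/serine-rich linker, 21 bp (7 codons), free of the default sites
DEFAULT_LINKER = "GGTTCTGGTGGTTCTGGTGCT"


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic locus.

    ``plants`` are (enzyme, region, offset) triples: the enzyme's
    top-strand cut lands ``offset`` bp from the region's reference edge —
    the ORF-facing edge for FR5/FR3, the ORF 5' end for ORF plants.
    ``forbidden`` enzymes are scrubbed from the background everywhere.
    """

    seed: int
    orf_len: int = 600
    flank_len: int = 1000
    plants: tuple[tuple[RestrictionEnzyme, str, int], ...] = ()
    forbidden: tuple[RestrictionEnzyme, ...] = ()

    def __post_init__(self):
        if self.orf_len < 6 or self.orf_len % 3 != 0:
            raise FixtureError("orf_len must be a multiple of 3 and >= 6")


def _rand_bases(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(list(BASES), size=n, p=BASE_P))


def _rand_nonstop_codon(rng: np.random.Generator) -> str:
    return NONSTOP_CODONS[rng.integers(len(NONSTOP_CODONS))]


def _in_any(pos: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= pos < e for s, e in intervals)


def _scrub(
    chars: list[str],
    enzymes: list[RestrictionEnzyme],
    protected: list[tuple[int, int]],
    rng: np.random.Generator,
    codon_region: tuple[int, int] | None = None,
    topology: str = "linear",
    max_rounds: int = 500,
) -> None:
    """Re-roll background until no enzyme site survives outside protection.

    Positions inside ``codon_region`` are re-rolled whole-codon-at-a-time
    from the non-stop codon set (frame anchored at the region start) so
    scrubbing never plants an in-frame stop codon.
    """
    L = len(chars)
    for _ in range(max_rounds):
        dirty = False
        seq = "".join(chars)
        for enz in enzymes:
            for hit in find_sites(seq, enz, topology):
                positions = [(hit.start + i) % L for i in range(enz.site_len)]
                if all(_in_any(p, protected) for p in positions):
                    continue
                # a hit counts as planted only if wholly protected
                if any(
                    s <= hit.start and hit.start + enz.site_len <= e for s, e in protected
                ):
                    continue
                dirty = True
                for p in positions:
                    if _in_any(p, protected):
                        continue
                    if codon_region and codon_region[0] <= p < codon_region[1]:
                        cstart = codon_region[0] + ((p - codon_region[0]) // 3) * 3
                        for _try in range(50):
                            codon = _rand_nonstop_codon(rng)
                            new = [
                                codon[i]
                                if not _in_any(cstart + i, protected)
                                else chars[cstart + i]
                                for i in range(3)
                            ]
                            if "".join(new) not in STOP_CODONS:
                                chars[cstart : cstart + 3] = new
                                break
                    else:
                        chars[p] = BASES[rng.integers(4)]
        if not dirty:
            return
    raise FixtureError("could not scrub background free of enzyme sites")


def make_goi(spec: FixtureSpec) -> GeneLocus:
    """Synthetic tripartite locus with planted, unique restriction sites."""
    rng = np.random.default_rng(spec.seed)
    U, O = spec.flank_len, spec.orf_len
    total = 2 * U + O

    chars = _rand_bases(rng, U)
    chars += list("ATG")
    for _ in range(O // 3 - 2):
        chars += list(_rand_nonstop_codon(rng))
    chars += list("TAA")
    chars += _rand_bases(rng, U)
    assert len(chars) == total

    protected: list[tuple[int, int]] = [(U, U + 3), (U + O - 3, U + O)]
    plant_map: list[tuple[RestrictionEnzyme, str, int, int]] = []
    for enz, region, offset in spec.plants:
        if not enz.is_concrete:
            raise FixtureError(f"cannot plant degenerate pattern {enz.name}")
        if region == "FR5":
            cut_abs = U - offset
        elif region == "FR3":
            cut_abs = U + O + offset
        elif region == "ORF":
            cut_abs = U + offset
        else:
            raise FixtureError(f"unknown region {region!r}")
        start = cut_abs - enz.cut_offset
        bounds = {"FR5": (0, U), "ORF": (U, U + O), "FR3": (U + O, total)}[region]
        if start < bounds[0] or start + enz.site_len > bounds[1]:
            raise FixtureError(
                f"plant {enz.name} in {region} at offset {offset} falls outside the region"
            )
        if any(s < start + enz.site_len and start < e for s, e in protected):
            raise FixtureError(f"plant {enz.name} overlaps a protected interval")
        chars[start : start + enz.site_len] = list(enz.recognition)
        protected.append((start, start + enz.site_len))
        plant_map.append((enz, region, offset, start))

    enzymes = {e.name: e for e, _, _ in spec.plants}
    enzymes.update({e.name: e for e in spec.forbidden})
    _scrub(chars, list(enzymes.values()), protected, rng, codon_region=(U + 3, U + O - 3))

    seq = "".join(chars)
    orf = seq[U : U + O]
    for i in range(0, O - 3, 3):
        if orf[i : i + 3] in STOP_CODONS and i > 0:
            raise FixtureError(f"planted site introduced an in-frame stop at ORF codon {i // 3}")
    return GeneLocus(
        name=f"FIX{spec.seed}",
        upstream=seq[:U],
        orf=orf,
        downstream=seq[U + O :],
    )


@dataclass(frozen=True)
class Backbone:
    seq: str
    mcs_interval: tuple[int, int]
    marker_interval: tuple[int, int]


def make_backbone(
    seed: int,
    length: int = 3000,
    mcs_enzymes: tuple[RestrictionEnzyme, ...] = (),
    marker_stub: str | None = None,
    forbidden: tuple[RestrictionEnzyme, ...] = (),
) -> Backbone:
    """Synthetic circular backbone with a planted MCS and an inert marker stub.

    The MCS holds one unique site per enzyme in the given order, spaced by
    8 bp; the marker stub (a placeholder for the selection/counterselection
    genes, whose identity never enters the design math) sits mid-backbone.
    All listed and forbidden enzymes are scrubbed elsewhere (circular scan).
    """
    if not mcs_enzymes:
        raise FixtureError("at least one MCS enzyme required")
    rng = np.random.default_rng(seed)
    spacer = 8
    mcs_len = spacer + sum(e.site_len + spacer for e in mcs_enzymes)
    mcs_start = 50
    marker = marker_stub if marker_stub is not None else "".join(_rand_bases(rng, 500))
    m0 = length // 2
    if length < mcs_start + mcs_len + 100 or m0 + len(marker) > length:
        raise FixtureError("backbone too short for MCS and marker stub")

    chars = _rand_bases(rng, length)
    pos = mcs_start + spacer
    protected: list[tuple[int, int]] = []
    for enz in mcs_enzymes:
        chars[pos : pos + enz.site_len] = list(enz.recognition)
        protected.append((pos, pos + enz.site_len))
        pos += enz.site_len + spacer
    chars[m0 : m0 + len(marker)] = list(marker)

    enzymes = {e.name: e for e in mcs_enzymes} | {e.name: e for e in forbidden}
    _scrub(chars, list(enzymes.values()), protected, rng, topology="circular")
    return Backbone(
        seq="".join(chars),
        mcs_interval=(mcs_start, mcs_start + mcs_len),
        marker_interval=(m0, m0 + len(marker)),
    )


def make_fpg(seed: int, n_codons: int = 80, forbidden: tuple[RestrictionEnzyme, ...] = ()) -> str:
    """Synthetic stand-in for a fluorescent-protein gene: ATG + non-stop
    codons + TAA, scrubbed of the working enzyme set."""
    if n_codons < 3:
        raise FixtureError("tag gene needs at least 3 codons")
    rng = np.random.default_rng(seed)
    chars = list("ATG")
    for _ in range(n_codons - 2):
        chars += list(_rand_nonstop_codon(rng))
    chars += list("TAA")
    protected = [(0, 3), (len(chars) - 3, len(chars))]
    _scrub(chars, list(forbidden), protected, rng, codon_region=(3, len(chars) - 3))
    return "".join(chars)


def default_enzymes() -> tuple[RestrictionEnzyme, ...]:
    return tuple(parse_enzyme_list(DEFAULT_ENZYMES_TEXT))


def default_tag_enzymes() -> tuple[RestrictionEnzyme, ...]:
    return tuple(parse_enzyme_list(DEFAULT_TAG_ENZYMES_TEXT))


def default_fixture(
    seed: int,
    orf_len: int = 600,
    flank_len: int = 1000,
    min_homology: int = 70,
    r_homo: float = 2.0,
) -> tuple[GeneLocus, Backbone, DesignParams]:
    """A complete ready-to-design fixture world.

    Plants one cut site per eligible pop-in region — EcoRI 150 bp into the
    3' FR, BamHI 150 bp from the ORF-facing end of the 5' FR, XhoI
    mid-ORF — so every task has candidates in both role assignments, and
    reserves SalI/SpeI for the backbone MCS. All other default enzymes
    are scrubbed everywhere.
    """
    enzymes = default_enzymes()
    tag_enzymes = default_tag_enzymes()
    by_name = {e.name: e for e in enzymes}
    ss = np.random.SeedSequence(seed)
    s_goi, s_bb, s_fpg = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))

    spec = FixtureSpec(
        seed=s_goi,
        orf_len=orf_len,
        flank_len=flank_len,
        plants=(
            (by_name["EcoRI"], "FR3", 150),
            (by_name["BamHI"], "FR5", 150),
            (by_name["XhoI"], "ORF", orf_len // 2),
        ),
        forbidden=enzymes + tag_enzymes,
    )
    import dataclasses

    locus = dataclasses.replace(make_goi(spec), name=f"GENE{seed}")
    backbone = make_backbone(
        s_bb,
        length=3000,
        mcs_enzymes=(by_name["SalI"], by_name["SpeI"]),
        forbidden=enzymes + tag_enzymes,
    )
    fpg = make_fpg(s_fpg, n_codons=80, forbidden=enzymes + tag_enzymes)
    params = DesignParams(
        enzymes=enzymes,
        min_homology=min_homology,
        r_homo=r_homo,
        flank_len=flank_len,
        linker=DEFAULT_LINKER,
        fpg=fpg,
        tag_flank_enzymes=tag_enzymes,
    )
    return locus, backbone, params
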