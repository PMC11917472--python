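"""Pop-in/pop-out plasmid design engine.

A design edits one gene locus in one of three ways: ORF deletion, or
fluorescent-protein tagging at the N- or C-terminus. Two locus regions
contribute homology: the *pop-in* region holds the unique restriction site
at which the plasmid is linearized before transformation (single-crossover
integration), and the *pop-out* region supplies the direct repeat whose
recombination after counterselection leaves the intended edit. The
user-set ratio R_homo = pop-out length / pop-in length biases the second,
spontaneous recombination toward the edit rather than wild-type reversion.

The engine enumerates every candidate linearization cut site in both
eligible pop-in regions, sizes the two homology arms, assembles the
insert (arms, plus linker / tag gene / 6-bp exchange sites for tagging),
picks subcloning enzymes for the backbone's multiple cloning site (MCS),
assembles the final circular plasmid, and flags the valid candidate with
the shortest synthesized insert as optimal. Rejections are data, never
exceptions: each rejected candidate carries a machine-readable reason.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum

from .restriction import (
    RestrictionEnzyme,
    count_sites,
    find_sites,
    top_strand_cut,
)
from .seqcore import (
    GeneLocus,
    InputError,
    PipoError,
    STOP_CODONS,
    clean_sequence,
    reverse_complement,
)

logger = logging.getLogger("pipo")

# Rejection / warning codes
NOT_UNIQUE_IN_REGION = "NOT_UNIQUE_IN_REGION"
MIN_HOMOLOGY_JUNCTION = "MIN_HOMOLOGY_JUNCTION"
MIN_HOMOLOGY_DISTAL = "MIN_HOMOLOGY_DISTAL"
TAG_SITES_UNAVAILABLE = "TAG_SITES_UNAVAILABLE"
MCS_PAIR_UNAVAILABLE = "MCS_PAIR_UNAVAILABLE"
LINEARIZATION_NOT_UNIQUE = "LINEARIZATION_NOT_UNIQUE"
POP_OUT_TRUNCATED = "POP_OUT_TRUNCATED"


class EditTask(str, Enum):
    DELETE = "delete"
    TAG_N = "tag_n"
    TAG_C = "tag_c"


class Region(str, Enum):
    FR5 = "FR5"
    ORF = "ORF"
    FR3 = "FR3"


@dataclass(frozen=True)
class DesignParams:
    """Tunable design parameters.

    min_homology: minimum homology (bp) required on each side of the
        linearization cut for efficient integration; default 70.
    r_homo: target pop-out/pop-in homology length ratio; >= 2 biases
        pop-out toward the intended edit; default 2.
    flank_len: length of each flanking region in the GOI file; default 1000.
    """

    enzymes: tuple[RestrictionEnzyme, ...]
    min_homology: int = 70
    r_homo: float = 2.0
    flank_len: int = 1000
    linker: str = ""
    fpg: str = ""
    tag_flank_enzymes: tuple[RestrictionEnzyme, ...] = ()

    def __post_init__(self):
        if self.min_homology < 1:
            raise InputError("min_homology must be >= 1")
        if not self.r_homo > 0:
            raise InputError("r_homo must be > 0")
        if not self.enzymes:
            raise InputError("at least one restriction enzyme is required")
        names = [e.name for e in self.enzymes]
        if len(set(names)) != len(names):
            raise InputError("duplicate enzyme names in list")
        for enz in self.tag_flank_enzymes:
            if enz.site_len != 6:
                raise InputError(
                    f"tag-flanking enzyme {enz.name!r} has a {enz.site_len} bp site; 6 bp required"
                )
            if not enz.is_concrete:
                raise InputError(
                    f"tag-flanking enzyme {enz.name!r} has a degenerate site; a concrete "
                    "sequence is required since the site is written into the insert"
                )

    def validate_for_task(self, task: EditTask) -> None:
        if task is EditTask.DELETE:
            return
        if not self.fpg:
            raise InputError(f"task {task.value}: a fluorescent-protein gene sequence is required")
        if not self.linker:
            raise InputError(f"task {task.value}: a linker sequence is required")
        if len(self.linker) % 3 != 0:
            raise InputError(f"linker length {len(self.linker)} is not a multiple of 3")
        if not self.tag_flank_enzymes:
            raise InputError(f"task {task.value}: a tag-flanking enzyme list is required")


@dataclass(frozen=True)
class CutCandidate:
    """One candidate linearization cut site in a pop-in region."""

    enzyme: str
    enzyme_index: int          # position in the enzyme file (tie-break order)
    pop_in_region: Region
    pop_out_region: Region
    cut_pos: int               # top-strand cut coordinate, region-local
    site_start: int            # recognition-site start, region-local
    strand: str
    d_junction: int            # cut -> junction edge distance
    d_distal: int              # cut -> distal usable edge distance
    inadmissible_reasons: tuple[str, ...] = ()

    @property
    def admissible(self) -> bool:
        return not self.inadmissible_reasons


@dataclass(frozen=True)
class HomologyArms:
    pop_in: str
    pop_out: str
    truncated: bool

    @property
    def pop_in_len(self) -> int:
        return len(self.pop_in)

    @property
    def pop_out_len(self) -> int:
        return len(self.pop_out)

    @property
    def achieved_ratio(self) -> float:
        return self.pop_out_len / self.pop_in_len


@dataclass(frozen=True)
class Feature:
    label: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.end < self.start:
            raise PipoError(f"feature {self.label}: end < start")


@dataclass(frozen=True)
class AnnotatedSequence:
    seq: str
    features: tuple[Feature, ...] = ()
    circular: bool = False

    def __len__(self) -> int:
        return len(self.seq)

    def feature(self, label: str) -> Feature | None:
        for f in self.features:
            if f.label == label:
                return f
        return None

    def reverse_complement(self) -> "AnnotatedSequence":
        L = len(self.seq)
        flipped = tuple(
            Feature(f.label, L - f.end, L - f.start, "-" if f.strand == "+" else "+")
            for f in self.features
        )
        return AnnotatedSequence(reverse_complement(self.seq), flipped, self.circular)


@dataclass
class DesignCandidate:
    task: EditTask
    cut: CutCandidate
    arms: HomologyArms | None = None
    insert: AnnotatedSequence | None = None
    plasmid: AnnotatedSequence | None = None
    linearization_enzyme: str = ""
    mcs_pair: tuple[str, str] | None = None
    tag_flank_assignment: tuple[str, ...] = ()
    status: str = "rejected"
    reject_reason: str | None = None
    warnings: list[str] = field(default_factory=list)
    optimal: bool = False

    @property
    def insert_len(self) -> int | None:
        return len(self.insert.seq) if self.insert is not None else None


# ---------------------------------------------------------------------------
# Region geometry
# ---------------------------------------------------------------------------

def eligible_region_pairs(task: EditTask) -> list[tuple[Region, Region]]:
    """(pop-in region, pop-out region) role assignments for an edit task.

    Both role assignments are enumerated: the linearization cut may sit in
    either of the two regions contributing homology.
    """
    if task is EditTask.DELETE:
        return [(Region.FR3, Region.FR5), (Region.FR5, Region.FR3)]
    if task is EditTask.TAG_N:
        return [(Region.FR5, Region.ORF), (Region.ORF, Region.FR5)]
    if task is EditTask.TAG_C:
        return [(Region.FR3, Region.ORF), (Region.ORF, Region.FR3)]
    raise InputError(f"unknown task {task!r}")


def usable_interval(locus: GeneLocus, region: Region, task: EditTask) -> tuple[int, int]:
    """Locus-coordinate interval of a region usable for homology.

    For C-terminal tagging the native stop codon is excised from the edited
    locus, so the usable ORF interval excludes its last 3 bases: sequence
    beyond that point cannot form homology shared by plasmid and genome.
    """
    U, O = locus.flank_len, len(locus.orf)
    if region is Region.FR5:
        return (0, U)
    if region is Region.FR3:
        return (U + O, len(locus))
    if task is EditTask.TAG_C:
        return (U, U + O - 3)
    return (U, U + O)


def junction_side(region: Region, task: EditTask) -> str:
    """Which end of a region faces the insert junction: 'left' or 'right'.

    FR5 always faces the junction with its 3' (right) end, FR3 with its 5'
    (left) end; the ORF faces it with the terminus being tagged.
    """
    if region is Region.FR5:
        return "right"
    if region is Region.FR3:
        return "left"
    return "right" if task is EditTask.TAG_C else "left"


# ---------------------------------------------------------------------------
# Candidate enumeration and arm sizing
# ---------------------------------------------------------------------------

def enumerate_candidates(
    locus: GeneLocus, task: EditTask, params: DesignParams
) -> list[CutCandidate]:
    """Every linearization cut-site candidate in the eligible pop-in regions.

    Inadmissible candidates are returned too, flagged with all their
    reasons: non-unique enzyme within the region, or less than
    ``min_homology`` between the cut and either usable region edge.
    """
    full = locus.full
    out: list[CutCandidate] = []
    for pop_in_region, pop_out_region in eligible_region_pairs(task):
        a, b = usable_interval(locus, pop_in_region, task)
        region_seq = full[a:b]
        side = junction_side(pop_in_region, task)
        for idx, enz in enumerate(params.enzymes):
            hits = find_sites(region_seq, enz, "linear")
            for hit in hits:
                cut_pos = top_strand_cut(hit, enz)
                d_junction = (b - a) - cut_pos if side == "right" else cut_pos
                d_distal = (b - a) - d_junction
                reasons = []
                if len(hits) != 1:
                    reasons.append(NOT_UNIQUE_IN_REGION)
                if d_junction < params.min_homology:
                    reasons.append(MIN_HOMOLOGY_JUNCTION)
                if d_distal < params.min_homology:
                    reasons.append(MIN_HOMOLOGY_DISTAL)
                out.append(
                    CutCandidate(
                        enzyme=enz.name,
                        enzyme_index=idx,
                        pop_in_region=pop_in_region,
                        pop_out_region=pop_out_region,
                        cut_pos=cut_pos,
                        site_start=hit.start,
                        strand=hit.strand,
                        d_junction=d_junction,
                        d_distal=d_distal,
                        inadmissible_reasons=tuple(reasons),
                    )
                )
    return out


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5))


def build_arms(
    locus: GeneLocus, task: EditTask, cut: CutCandidate, params: DesignParams
) -> HomologyArms:
    """Size the pop-in and pop-out homology arms for an admissible cut.

    Pop-in: the whole sequence between the junction edge and the cut, plus
    exactly ``min_homology`` bp beyond the cut. Pop-out: ``r_homo`` times
    the pop-in length (rounded half away from zero), taken from the pop-out
    region flush against the junction; if the region is shorter, all of it
    is taken and the arm is flagged truncated.
    """
    if not cut.admissible:
        raise PipoError(f"build_arms called on inadmissible cut ({cut.inadmissible_reasons})")
    full = locus.full
    a, b = usable_interval(locus, cut.pop_in_region, task)
    cut_abs = a + cut.cut_pos
    if junction_side(cut.pop_in_region, task) == "right":
        pop_in = full[cut_abs - params.min_homology : b]
    else:
        pop_in = full[a : cut_abs + params.min_homology]

    target = _round_half_away(params.r_homo * len(pop_in))
    a2, b2 = usable_interval(locus, cut.pop_out_region, task)
    available = b2 - a2
    truncated = target > available
    take = min(target, available)
    if junction_side(cut.pop_out_region, task) == "right":
        pop_out = full[b2 - take : b2]
    else:
        pop_out = full[a2 : a2 + take]
    return HomologyArms(pop_in=pop_in, pop_out=pop_out, truncated=truncated)


# ---------------------------------------------------------------------------
# Reading-frame checks and tag-gene conventions
# ---------------------------------------------------------------------------

def check_no_stop_inframe(
    site: str,
    frame_offset: int = 0,
    left_context: str = "",
    right_context: str = "",
) -> bool:
    """True iff a 6 bp site introduces no stop codon in the fusion frame.

    ``frame_offset`` is the position of the site's first base within its
    codon (0, 1 or 2). At offset 0 the site contributes exactly two codons;
    at offsets 1/2 the straddling codons are completed from the supplied
    2-base contexts where available (codons with missing context bases are
    not checked).
    """
    if len(site) != 6:
        raise InputError(f"tag-flanking site must be 6 bp, got {len(site)}")
    if frame_offset not in (0, 1, 2):
        raise InputError("frame_offset must be 0, 1 or 2")
    if frame_offset == 0:
        seq = site
    elif len(left_context) >= frame_offset:
        seq = left_context[len(left_context) - frame_offset :] + site
    else:
        # incomplete left context: skip the straddling codon, start at the
        # next codon boundary inside the site
        seq = site[3 - frame_offset :]
    tail_need = (3 - len(seq) % 3) % 3
    if tail_need:
        if len(right_context) >= tail_need:
            seq += right_context[:tail_need]
        else:
            seq = seq[: len(seq) - len(seq) % 3]
    return not any(seq[i : i + 3] in STOP_CODONS for i in range(0, len(seq) - 2, 3))


def prepare_fpg(fpg: str, task: EditTask) -> str:
    """Normalize the tag-gene sequence for its position in the fusion.

    C-terminal tag: the gene terminates the fusion, so a stop codon is
    ensured (TAA appended if absent). N-terminal tag: the gene starts the
    fusion, so its terminal stop (if any) is stripped and a leading ATG is
    ensured. The result must stay a whole number of codons.
    """
    fpg = clean_sequence(fpg, what="tag gene")
    if task is EditTask.TAG_C:
        if fpg[-3:] not in STOP_CODONS:
            fpg = fpg + "TAA"
    elif task is EditTask.TAG_N:
        if fpg[-3:] in STOP_CODONS:
            fpg = fpg[:-3]
        if not fpg.startswith("ATG"):
            fpg = "ATG" + fpg
    if len(fpg) % 3 != 0:
        raise InputError(f"tag gene length {len(fpg)} is not a multiple of 3 after normalization")
    return fpg


def _inframe_flags(task: EditTask) -> tuple[bool, bool, bool]:
    """Which of the three tag-flanking sites lie inside the fusion frame.

    tag_c: [ORF][site1][linker][site2][FPG+stop][site3][3'FR] — site 3
    follows the fusion stop and is exempt. tag_n:
    [5'FR][site1][FPG][site2][linker][site3][ORF] — site 1 precedes the
    fusion start (5' UTR) and is exempt.
    """
    if task is EditTask.TAG_C:
        return (True, True, False)
    return (False, True, True)


# ---------------------------------------------------------------------------
# Insert assembly
# ---------------------------------------------------------------------------

def _part_layout(task: EditTask, cut: CutCandidate, arms: HomologyArms) -> dict[Region, str]:
    parts = {cut.pop_in_region: arms.pop_in, cut.pop_out_region: arms.pop_out}
    return parts


def assemble_insert(
    locus: GeneLocus,
    task: EditTask,
    arms: HomologyArms,
    cut: CutCandidate,
    params: DesignParams,
    tag_flank_assignment: tuple[RestrictionEnzyme, ...] = (),
) -> AnnotatedSequence:
    """Assemble the synthesized insert in genomic 5'->3' order.

    delete:  [5'FR part][3'FR part]
    tag_c:   [ORF part (stop removed)][site1][linker][site2][FPG+stop][site3][3'FR part]
    tag_n:   [5'FR part][site1][FPG (ATG ensured, stop stripped)][site2][linker][site3][ORF part]

    Each part is whichever homology arm belongs to that region. The
    linearization recognition site is annotated inside the pop-in part.
    The fusion reading frame is preserved by construction: each 6 bp site
    contributes two codons and the linker is a whole number of codons.
    """
    params.validate_for_task(task)
    parts = _part_layout(task, cut, arms)
    pieces: list[tuple[str, str]] = []  # (label or "", sequence)
    arm_label = {cut.pop_in_region: "POP_IN_ARM", cut.pop_out_region: "POP_OUT_ARM"}

    if task is EditTask.DELETE:
        order = [
            (arm_label[Region.FR5], parts[Region.FR5]),
            (arm_label[Region.FR3], parts[Region.FR3]),
        ]
    else:
        if len(tag_flank_assignment) != 3:
            raise InputError("tagging tasks require exactly 3 tag-flanking enzymes")
        s1, s2, s3 = (e.recognition for e in tag_flank_assignment)
        linker = clean_sequence(params.linker, what="linker")
        fpg = prepare_fpg(params.fpg, task)
        if task is EditTask.TAG_C:
            order = [
                (arm_label[Region.ORF], parts[Region.ORF]),
                ("TAG_SITE_1", s1),
                ("LINKER", linker),
                ("TAG_SITE_2", s2),
                ("FPG", fpg),
                ("TAG_SITE_3", s3),
                (arm_label[Region.FR3], parts[Region.FR3]),
            ]
        else:
            order = [
                (arm_label[Region.FR5], parts[Region.FR5]),
                ("TAG_SITE_1", s1),
                ("FPG", fpg),
                ("TAG_SITE_2", s2),
                ("LINKER", linker),
                ("TAG_SITE_3", s3),
                (arm_label[Region.ORF], parts[Region.ORF]),
            ]

    seq = ""
    features: list[Feature] = []
    pop_in_offset = None
    for label, piece in order:
        start = len(seq)
        seq += piece
        features.append(Feature(label, start, len(seq)))
        if label == "POP_IN_ARM":
            pop_in_offset = start

    # locate the linearization recognition site inside the pop-in arm
    a, b = usable_interval(locus, cut.pop_in_region, task)
    cut_abs = a + cut.cut_pos
    site_abs = a + cut.site_start
    if junction_side(cut.pop_in_region, task) == "right":
        arm_start_abs = cut_abs - params.min_homology
    else:
        arm_start_abs = a
    site_local = pop_in_offset + (site_abs - arm_start_abs)
    enz = next(e for e in params.enzymes if e.name == cut.enzyme)
    features.append(Feature("LINEARIZATION_SITE", site_local, site_local + enz.site_len))
    return AnnotatedSequence(seq=seq, features=tuple(features))


# ---------------------------------------------------------------------------
# Enzyme selection: tag-flanking sites and MCS subcloning pair
# ---------------------------------------------------------------------------

def select_tag_flank_enzymes(
    pieces: tuple[str, str, str, str],
    backbone: str,
    params: DesignParams,
    linearization_enzyme: str,
    task: EditTask,
) -> tuple[RestrictionEnzyme, ...] | None:
    """Assign three distinct 6-cutters to the tag-flanking sites.

    ``pieces`` are the four fixed insert segments in layout order; site i
    is written between pieces i-1 and i. An enzyme qualifies for a site if
    it (a) introduces no stop codon in the fusion frame when the site lies
    inside it, (b) cuts none of the pieces nor the backbone, and (c) is
    not the linearization enzyme. Assignments are tried greedily in file
    order (site 1 outermost) and the first one whose *assembled* insert
    keeps every chosen site unique is returned — a site flush against its
    neighbor sequence can otherwise gain an overlapping duplicate
    occurrence. Returns None when no assignment exists.
    """
    if len(pieces) != 4:
        raise PipoError("tag-site selection needs exactly 4 insert pieces")
    inframe = _inframe_flags(task)
    pool = []
    for enz in params.tag_flank_enzymes:
        if enz.name == linearization_enzyme:
            continue
        if any(count_sites(p, enz, "linear") > 0 for p in pieces):
            continue
        if count_sites(backbone, enz, "circular") > 0:
            continue
        pool.append(enz)
    per_site = [
        [e for e in pool if not inframe[i] or check_no_stop_inframe(e.recognition)]
        for i in range(3)
    ]
    for e1 in per_site[0]:
        for e2 in per_site[1]:
            if e2 is e1:
                continue
            for e3 in per_site[2]:
                if e3 is e1 or e3 is e2:
                    continue
                insert = (
                    pieces[0] + e1.recognition + pieces[1] + e2.recognition
                    + pieces[2] + e3.recognition + pieces[3]
                )
                if all(count_sites(insert, e, "linear") == 1 for e in (e1, e2, e3)):
                    return (e1, e2, e3)
    return None


def select_mcs_enzymes(
    insert: str,
    backbone: str,
    mcs_interval: tuple[int, int],
    enzymes: tuple[RestrictionEnzyme, ...],
    linearization_enzyme: str,
) -> tuple[RestrictionEnzyme, RestrictionEnzyme] | None:
    """First qualifying (left, right) subcloning enzyme pair, by file order.

    An enzyme qualifies if it cuts the backbone exactly once (circular
    scan), with the recognition site wholly inside the MCS interval, cuts
    the insert zero times, and differs from the linearization enzyme. The
    pair is the first, in file order, whose left member cuts at a lower
    backbone coordinate than the right member.
    """
    s, e = mcs_interval
    if not (0 <= s < e <= len(backbone)):
        raise InputError(f"MCS interval {mcs_interval!r} invalid for backbone of length {len(backbone)}")
    qualified: list[tuple[RestrictionEnzyme, int]] = []
    for enz in enzymes:
        if enz.name == linearization_enzyme:
            continue
        hits = find_sites(backbone, enz, "circular")
        if len(hits) != 1:
            continue
        hit = hits[0]
        if not (s <= hit.start and hit.start + enz.site_len <= e):
            continue
        if count_sites(insert, enz, "linear") > 0:
            continue
        qualified.append((enz, top_strand_cut(hit, enz)))
    for enz1, cut1 in qualified:
        for enz2, cut2 in qualified:
            if enz1 is not enz2 and cut1 < cut2:
                return (enz1, enz2)
    return None


def assemble_plasmid(
    backbone: AnnotatedSequence | str,
    mcs_interval: tuple[int, int],
    insert: AnnotatedSequence,
    mcs_pair: tuple[RestrictionEnzyme, RestrictionEnzyme],
) -> AnnotatedSequence:
    """Digest the backbone at the MCS pair and ligate the insert in between.

    The insert is oriented so its pop-out arm sits adjacent to the left
    (lower-coordinate) MCS cut. Insert features are carried over shifted;
    the retained backbone is annotated as a single (origin-wrapping)
    BACKBONE feature. The result is circular.
    """
    bb_seq = backbone.seq if isinstance(backbone, AnnotatedSequence) else backbone
    left_hits = find_sites(bb_seq, mcs_pair[0], "circular")
    right_hits = find_sites(bb_seq, mcs_pair[1], "circular")
    if len(left_hits) != 1 or len(right_hits) != 1:
        raise PipoError("MCS enzymes must cut the backbone exactly once")
    lc = top_strand_cut(left_hits[0], mcs_pair[0])
    rc = top_strand_cut(right_hits[0], mcs_pair[1])
    if not lc < rc:
        raise PipoError("left MCS cut must precede right MCS cut")

    oriented = insert
    pin, pout = insert.feature("POP_IN_ARM"), insert.feature("POP_OUT_ARM")
    if pin is None or pout is None:
        raise PipoError("insert must carry POP_IN_ARM and POP_OUT_ARM features")
    if pout.start > pin.start:
        oriented = insert.reverse_complement()

    seq = bb_seq[:lc] + oriented.seq + bb_seq[rc:]
    features = [Feature(f.label, f.start + lc, f.end + lc, f.strand) for f in oriented.features]
    # retained backbone wraps the origin: [lc + insert .. L) ∪ [0 .. lc),
    # recorded with end > L (coordinates modulo plasmid length)
    L = len(seq)
    ins_len = len(oriented.seq)
    features.append(Feature("BACKBONE", lc + ins_len, lc + ins_len + (L - ins_len)))
    features.append(Feature("MCS_LEFT", lc, lc))
    features.append(Feature("MCS_RIGHT", lc + ins_len, lc + ins_len))
    return AnnotatedSequence(seq=seq, features=tuple(features), circular=True)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def _enzyme_by_name(params: DesignParams, name: str) -> RestrictionEnzyme:
    return next(e for e in params.enzymes if e.name == name)


def design(
    locus: GeneLocus,
    task: EditTask,
    params: DesignParams,
    backbone: AnnotatedSequence | str,
    mcs_interval: tuple[int, int],
) -> list[DesignCandidate]:
    """Run the full design pipeline for one locus and one edit task.

    Returns every candidate (valid and rejected, each rejection carrying
    its coded reason). Among valid candidates exactly one is flagged
    optimal: minimal insert length, ties broken by larger achieved
    homology ratio, then smaller junction distance, then enzyme file
    order. Zero valid candidates is a legitimate result (the caller can
    summarize the rejection reasons).
    """
    params.validate_for_task(task)
    bb_seq = backbone.seq if isinstance(backbone, AnnotatedSequence) else backbone
    results: list[DesignCandidate] = []

    for cut in enumerate_candidates(locus, task, params):
        cand = DesignCandidate(task=task, cut=cut, linearization_enzyme=cut.enzyme)
        results.append(cand)
        if not cut.admissible:
            cand.reject_reason = cut.inadmissible_reasons[0]
            cand.warnings.extend(cut.inadmissible_reasons[1:])
            logger.info(
                "candidate %s @ %s:%d rejected: %s",
                cut.enzyme, cut.pop_in_region.value, cut.cut_pos, cand.reject_reason,
            )
            continue

        arms = build_arms(locus, task, cut, params)
        cand.arms = arms
        if arms.truncated:
            cand.warnings.append(POP_OUT_TRUNCATED)
            logger.info(
                "candidate %s @ %s:%d: pop-out arm truncated to %d bp (ratio %.3f)",
                cut.enzyme, cut.pop_in_region.value, cut.cut_pos,
                arms.pop_out_len, arms.achieved_ratio,
            )

        tag_assignment: tuple[RestrictionEnzyme, ...] = ()
        if task is not EditTask.DELETE:
            parts = _part_layout(task, cut, arms)
            linker = clean_sequence(params.linker, what="linker")
            fpg = prepare_fpg(params.fpg, task)
            if task is EditTask.TAG_C:
                pieces = (parts[Region.ORF], linker, fpg, parts[Region.FR3])
            else:
                pieces = (parts[Region.FR5], fpg, linker, parts[Region.ORF])
            assignment = select_tag_flank_enzymes(pieces, bb_seq, params, cut.enzyme, task)
            if assignment is None:
                cand.reject_reason = TAG_SITES_UNAVAILABLE
                logger.info("candidate %s: no tag-flanking enzyme assignment", cut.enzyme)
                continue
            tag_assignment = assignment
            cand.tag_flank_assignment = tuple(e.name for e in assignment)

        insert = assemble_insert(locus, task, arms, cut, params, tag_assignment)
        cand.insert = insert

        pair = select_mcs_enzymes(insert.seq, bb_seq, mcs_interval, params.enzymes, cut.enzyme)
        if pair is None:
            cand.reject_reason = MCS_PAIR_UNAVAILABLE
            logger.info("candidate %s: no MCS subcloning pair", cut.enzyme)
            continue
        cand.mcs_pair = (pair[0].name, pair[1].name)

        plasmid = assemble_plasmid(backbone, mcs_interval, insert, pair)
        cand.plasmid = plasmid

        lin_enz = _enzyme_by_name(params, cut.enzyme)
        if count_sites(plasmid.seq, lin_enz, "circular") != 1:
            cand.reject_reason = LINEARIZATION_NOT_UNIQUE
            logger.info("candidate %s: linearization site not unique on plasmid", cut.enzyme)
            continue
        tag_ok = all(
            count_sites(plasmid.seq, enz, "circular") == 1 for enz in tag_assignment
        )
        if not tag_ok:
            cand.reject_reason = TAG_SITES_UNAVAILABLE
            logger.info("candidate %s: tag site not unique on plasmid", cut.enzyme)
            continue
        cand.status = "valid"

    valid = [c for c in results if c.status == "valid"]
    if valid:
        best = min(
            valid,
            key=lambda c: (
                c.insert_len,
                -c.arms.achieved_ratio,
                c.cut.d_junction,
                c.cut.enzyme_index,
            ),
        )
        best.optimal = True
    return results


def summarize_reasons(candidates: list[DesignCandidate]) -> dict[str, int]:
    """Tally of rejection reasons over a candidate list."""
    tally: dict[str, int] = {}
    for c in candidates:
        if c.status == "rejected" and c.reject_reason:
            tally[c.reject_reason] = tally.get(c.reject_reason, 0) + 1
    return tally
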