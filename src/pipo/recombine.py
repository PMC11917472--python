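"""In-silico pop-in integration and pop-out excision.

Verifies a design end-to-end: linearizing the assembled plasmid at its
unique cut site, integrating it into the wild-type locus by single
crossover, and enumerating the direct-repeat excisions available to the
counterselected cell. A correct design yields exactly two outcomes —
reversion to the wild-type locus (recombination through the pop-in
repeat) and the intended edit (through the pop-out repeat) — and nothing
else. Recombination is modeled as exact-match direct-repeat excision; no
mismatch tolerance, gene conversion, or outcome probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .design import (
    AnnotatedSequence,
    DesignParams,
    EditTask,
    Feature,
    prepare_fpg,
)
from .restriction import RestrictionEnzyme, find_sites, top_strand_cut
from .seqcore import GeneLocus, SimulationError, reverse_complement

logger = logging.getLogger("pipo")

HOMOLOGY_NOT_FOUND = "HOMOLOGY_NOT_FOUND"

POP_IN_REPEAT = "POP_IN_REPEAT"
POP_OUT_REPEAT = "POP_OUT_REPEAT"

WT_REVERSION = "WT_REVERSION"
INTENDED_EDIT = "INTENDED_EDIT"
OTHER = "OTHER"


@dataclass
class IntegrationProduct:
    """Edited locus after pop-in, with the direct repeats that drive pop-out."""

    seq: str
    repeats: list[tuple[str, tuple[int, int], tuple[int, int]]]
    marker_interval: tuple[int, int]
    insert_span: tuple[int, int]  # where the linearized plasmid sits in seq
    wt: str = ""


@dataclass(frozen=True)
class PopOutOutcome:
    product: str
    via: str            # repeat label (or SCAN for safety-scan finds)
    classification: str  # WT_REVERSION | INTENDED_EDIT | OTHER


def intended_edit(
    locus: GeneLocus,
    task: EditTask,
    params: DesignParams,
    tag_flank_assignment: tuple[RestrictionEnzyme, ...] = (),
) -> str:
    """The desired edited locus, built independently of any plasmid.

    delete: upstream + downstream. tag_c: the stop-free ORF is extended
    with site1-linker-site2-FPG(+stop)-site3 before the 3' FR. tag_n:
    site1-FPG(-stop,+ATG)-site2-linker-site3 is placed between the 5' FR
    and the intact ORF.
    """
    if task is EditTask.DELETE:
        return locus.upstream + locus.downstream
    if len(tag_flank_assignment) != 3:
        raise SimulationError(HOMOLOGY_NOT_FOUND, "tagging tasks need 3 tag-flanking enzymes")
    s1, s2, s3 = (e.recognition for e in tag_flank_assignment)
    fpg = prepare_fpg(params.fpg, task)
    if task is EditTask.TAG_C:
        return (
            locus.upstream
            + locus.orf[:-3]
            + s1 + params.linker + s2 + fpg + s3
            + locus.downstream
        )
    return (
        locus.upstream
        + s1 + fpg + s2 + params.linker + s3
        + locus.orf
        + locus.downstream
    )


def linearize_plasmid(
    plasmid: AnnotatedSequence, enzyme: RestrictionEnzyme
) -> AnnotatedSequence:
    """Open a circular plasmid at its unique cut site for ``enzyme``.

    Features are rotated with the sequence; features that would span the
    new ends (the pop-in arm, which contains the cut) are dropped.
    """
    hits = find_sites(plasmid.seq, enzyme, "circular")
    if len(hits) != 1:
        raise SimulationError(
            HOMOLOGY_NOT_FOUND,
            f"enzyme {enzyme.name} cuts the plasmid {len(hits)} times; exactly one required",
        )
    cut = top_strand_cut(hits[0], enzyme) % len(plasmid.seq)
    L = len(plasmid.seq)
    seq = plasmid.seq[cut:] + plasmid.seq[:cut]
    features = []
    for f in plasmid.features:
        length = f.end - f.start
        start = (f.start - cut) % L
        if start + length <= L:
            features.append(Feature(f.label, start, start + length, f.strand))
    return AnnotatedSequence(seq=seq, features=tuple(features), circular=False)


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _locate_integration(full: str, P: str, min_homology: int) -> list[int]:
    """Genomic coordinates where both plasmid termini map adjacently."""
    if len(P) < 2 * min_homology:
        return []
    prefix, suffix = P[:min_homology], P[-min_homology:]
    sites = []
    for g in _find_all(full, prefix):
        if g >= min_homology and full[g - min_homology : g] == suffix:
            sites.append(g)
    return sites


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _infer_marker_interval(P: str, full: str, g: int, k: int = 25) -> tuple[int, int]:
    """Longest stretch of the integrated plasmid with no k-mer shared with
    the locus — a stand-in for the backbone/marker block when the plasmid
    carries no annotation."""
    locus_kmers = {full[i : i + k] for i in range(len(full) - k + 1)}
    best = (0, 0)
    run_start = None
    for i in range(len(P) - k + 1):
        if P[i : i + k] not in locus_kmers:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and (i + k - 1) - run_start > best[1] - best[0]:
                best = (run_start, i + k - 1)
            run_start = None
    if run_start is not None and (len(P)) - run_start > best[1] - best[0]:
        best = (run_start, len(P))
    return (g + best[0], g + best[1])


def simulate_pop_in(
    wt_locus: GeneLocus,
    linearized_plasmid: AnnotatedSequence | str,
    min_homology: int,
) -> IntegrationProduct:
    """Single-crossover integration of a linearized plasmid into the locus.

    The plasmid's two termini must each carry at least ``min_homology`` of
    sequence mapping adjacently and uniquely in the locus (either
    orientation is accepted). The product is
    ``locus[:g] + plasmid + locus[g:]`` with the two direct-repeat pairs
    annotated: the duplicated pop-in homology around the integration
    point, and the pop-out arm opposite its genomic counterpart.
    """
    full = wt_locus.full
    if isinstance(linearized_plasmid, str):
        linearized_plasmid = AnnotatedSequence(seq=linearized_plasmid)

    candidates = []
    for oriented in (linearized_plasmid, linearized_plasmid.reverse_complement()):
        for g in _locate_integration(full, oriented.seq, min_homology):
            candidates.append((oriented, g))
    if len(candidates) != 1:
        raise SimulationError(
            HOMOLOGY_NOT_FOUND,
            f"plasmid terminal homology found {len(candidates)} times in the locus "
            "(exactly one required)",
        )
    plasmid, g = candidates[0]
    P = plasmid.seq
    product = full[:g] + P + full[g:]

    # pop-in repeat: maximal terminal homology extension around the cut
    k1 = _common_prefix_len(P, full[g:])
    k2 = _common_prefix_len(P[::-1], full[:g][::-1])
    repeats = [
        (POP_IN_REPEAT, (g - k2, g + k1), (g + len(P) - k2, g + len(P) + k1)),
    ]

    pout = plasmid.feature("POP_OUT_ARM")
    if pout is not None:
        S = P[pout.start : pout.end]
        occ = _find_all(full, S)
        if len(occ) != 1:
            raise SimulationError(
                HOMOLOGY_NOT_FOUND,
                f"pop-out homology found {len(occ)} times in the locus (exactly one required)",
            )
        p = occ[0]
        plasmid_copy = (g + pout.start, g + pout.end)
        if p >= g:
            genomic_copy = (p + len(P), p + len(P) + len(S))
            pair = (plasmid_copy, genomic_copy)
        else:
            genomic_copy = (p, p + len(S))
            pair = (genomic_copy, plasmid_copy)
        repeats.append((POP_OUT_REPEAT, pair[0], pair[1]))

    bb = plasmid.feature("BACKBONE")
    if bb is not None:
        marker = (g + bb.start, g + bb.end)
    else:
        marker = _infer_marker_interval(P, full, g)

    return IntegrationProduct(
        seq=product,
        repeats=repeats,
        marker_interval=marker,
        insert_span=(g, g + len(P)),
        wt=full,
    )


def _excise(seq: str, copy1: tuple[int, int], copy2: tuple[int, int]) -> str:
    """Recombination between two direct-repeat copies: keep one copy,
    drop everything between the copies' start coordinates."""
    return seq[: copy1[0]] + seq[copy2[0] :]


def enumerate_pop_out(
    product: IntegrationProduct,
    min_repeat: int = 25,
    intended: str | None = None,
) -> list[PopOutOutcome]:
    """All direct-repeat excisions that remove the marker block.

    The two annotated repeat pairs are excised first; a k-mer safety scan
    (k = ``min_repeat``) then searches for any *other* direct repeat pair
    flanking the marker block, whose excision would be an unintended but
    selectable product. Each product is classified by exact equality
    against the wild-type locus and (when supplied) the intended edit.
    """

    def classify(seq: str) -> str:
        if seq == product.wt:
            return WT_REVERSION
        if intended is not None and seq == intended:
            return INTENDED_EDIT
        return OTHER

    outcomes: list[PopOutOutcome] = []
    seen: set[str] = set()
    for label, c1, c2 in product.repeats:
        prod = _excise(product.seq, c1, c2)
        seen.add(prod)
        outcomes.append(PopOutOutcome(product=prod, via=label, classification=classify(prod)))

    ms, me = product.marker_interval
    k = min_repeat
    seq = product.seq
    kmer_pos: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer_pos.setdefault(seq[i : i + k], []).append(i)
    for positions in kmer_pos.values():
        if len(positions) < 2:
            continue
        lefts = [i for i in positions if i <= ms]
        rights = [j for j in positions if j >= me]
        for i in lefts:
            for j in rights:
                if j <= i:
                    continue
                prod = _excise(seq, (i, i + k), (j, j + k))
                if prod in seen:
                    continue
                seen.add(prod)
                outcomes.append(
                    PopOutOutcome(product=prod, via="SCAN", classification=classify(prod))
                )
    return outcomes


def verify_design(
    locus: GeneLocus,
    task: EditTask,
    params: DesignParams,
    candidate,
    min_repeat: int = 25,
) -> list[PopOutOutcome]:
    """Round-trip a valid design candidate: linearize, integrate, pop out.

    Convenience wrapper used by tests, the batch driver and the CLI.
    """
    from .design import _enzyme_by_name

    enz = _enzyme_by_name(params, candidate.linearization_enzyme)
    linearized = linearize_plasmid(candidate.plasmid, enz)
    integration = simulate_pop_in(locus, linearized, params.min_homology)
    assignment = tuple(
        next(e for e in params.tag_flank_enzymes if e.name == n)
        for n in candidate.tag_flank_assignment
    )
    target = intended_edit(locus, task, params, assignment)
    return enumerate_pop_out(integration, min_repeat=min_repeat, intended=target)
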