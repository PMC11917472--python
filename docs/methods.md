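# Methods

## The editing model

Pop-in/pop-out editing proceeds in two recombination events. First, an
integrative plasmid carrying a counterselectable marker is linearized at
a unique restriction site inside a region of homology with the target
locus and integrates by single crossover at that cut (pop-in). The
integration duplicates the homologous sequence, so the product carries
two pairs of direct repeats flanking the plasmid backbone: the
duplicated *pop-in* homology (recombination between these copies excises
the plasmid and restores the wild type) and the *pop-out* homology — a
sequence from the *other* locus region, placed in the insert so that
after integration it faces an identical genomic copy (recombination here
leaves the intended edit). Because spontaneous mitotic recombination
frequency grows with repeat length, the ratio

    R_homo = pop-out length / pop-in length

biases the counterselected outcome: `R_homo >= 2` (the default)
empirically favors the intended edit.

Each edit task pairs two locus regions, and both role assignments are
enumerated (the cut may sit in either region):

| task   | region pairs (pop-in, pop-out)       | insert layout (genomic 5′→3′)                                |
|--------|--------------------------------------|--------------------------------------------------------------|
| delete | (3′FR, 5′FR), (5′FR, 3′FR)           | [5′FR part][3′FR part]                                        |
| tag_n  | (5′FR, ORF), (ORF, 5′FR)             | [5′FR part] s1 [FPG] s2 [linker] s3 [ORF part]                |
| tag_c  | (3′FR, ORF), (ORF, 3′FR)             | [ORF part −stop] s1 [linker] s2 [FPG +stop] s3 [3′FR part]    |

where each *part* is whichever homology arm belongs to that region and
s1–s3 are the three 6-bp tag-flanking sites.

## Candidate enumeration and arm sizing

Coordinates are 0-based, half-open; locus coordinate 0 is the first base
of the 5′ flank. A restriction site is a candidate only if its whole
recognition pattern lies inside the usable region interval (a site
straddling a boundary would not survive in the synthesized insert), and
is admissible iff the enzyme is unique within that interval and the
top-strand cut coordinate lies at least `min_homology` from both usable
edges. For C-terminal tagging the usable ORF interval excludes the
native stop codon — sequence beyond it cannot form homology shared by
plasmid and genome, since the edit removes the stop.

The pop-in arm runs from the region's junction edge through the cut plus
exactly `min_homology` bp beyond it (length = junction distance +
`min_homology`). The pop-out arm targets `round(R_homo × pop-in length)`
bp (rounding half away from zero), taken flush against the junction and
extending away from it — flush placement is what makes the post-pop-in
direct repeats contiguous. If the pop-out region is shorter than the
target, the whole region is taken and the design carries a
`POP_OUT_TRUNCATED` warning rather than being rejected.

## Restriction scanning

Recognition patterns are IUPAC strings with a caret cut mark
(`G^AATTC`); matching expands degeneracy and covers both strands, with
palindromic patterns (and degenerate patterns whose two orientations
coincide at a position) reported once per physical site. Circular scans
find origin-spanning sites by scanning `seq + seq[:m-1]` with modular
positions. Cut position arithmetic uses the top-strand cut coordinate
only; overhang geometry is deliberately ignored because the algorithm
measures recombination homology, not ligation chemistry. Uniqueness
checks on the final plasmid use circular topology; insert-only checks
are linear.

## Stop-codon and frame conventions

Fusion-frame integrity is guaranteed by construction: homology arms from
the ORF keep their genomic phase, each 6-bp site contributes exactly two
codons, and the linker must be a whole number of codons. The tag gene is
normalized per task: for C-terminal tags a terminal stop is ensured
(TAA appended if missing); for N-terminal tags any terminal stop is
stripped and a leading ATG ensured, while the native ORF keeps its own
ATG downstream of the linker (an extra in-frame methionine, the standard
cost of N-terminal fusion constructs). Tag-flanking sites inside the
fusion frame are screened against TAA/TAG/TGA; the site after the fusion
stop (tag_c s3) and the site in the 5′ UTR (tag_n s1) are exempt.

Tag-site selection searches assignments of three *distinct* 6-cutters in
enzyme-file order (site 1 outermost) and accepts the first whose
actually-assembled insert keeps every chosen site unique — the context
check matters because a site written flush against its neighbor can gain
an overlapping duplicate occurrence (e.g. `GCTAGC` followed by `TAGC…`).
MCS subcloning enzymes are the first file-order pair that each cut the
backbone exactly once inside the MCS, never cut the insert, and differ
from the linearization enzyme; after assembly the linearization and tag
sites are re-verified unique on the circular plasmid, and junction
artifacts reject the candidate with a coded reason.

## Optimality and determinism

Among valid candidates the optimum minimizes the synthesized insert
length; ties break by larger achieved homology ratio, then smaller
junction distance, then enzyme file order. There is no randomness
anywhere in the design path: identical inputs (including enzyme file
order) give byte-identical outputs.

## Recombination simulation

The verifier linearizes the assembled plasmid at its unique cut, locates
the single genomic position where both plasmid termini map adjacently
(at least `min_homology` each; either orientation accepted), and forms
`locus[:g] + plasmid + locus[g:]`. The pop-in repeat is annotated by
maximal terminal-homology extension; the pop-out repeat by matching the
pop-out arm against its unique genomic copy. Excision between a repeat
pair keeps one copy and drops the intervening loop. Besides the two
annotated repeats, a k-mer safety scan (k = `min_repeat`, default 25 bp
— below which spontaneous recombination is negligible) searches for any
other direct repeat whose excision would remove the marker block and
reports such products as `OTHER`. Recombination is modeled as
exact-match excision: no mismatch tolerance, no gene conversion, and no
outcome probabilities — the efficiency-versus-`R_homo` relationship is
an empirical wet-lab quantity this package does not re-derive.

## Synthetic data

The fixture generator emulates the stated input world: 1,000 bp flanks,
a 600 bp ORF (canonical ATG/TAA, internally stop-free), random
background at GC ≈ 0.40 to resemble yeast intergenic sequence, one
planted cut site per eligible pop-in region (150 bp from the junction in
each flank, mid-ORF) and a 3 kb circular backbone with a planted
two-enzyme MCS and an inert 500 bp marker stub (marker identity never
enters the design math). All other enzymes in the working set are
scrubbed everywhere, so site geometry is fully controlled and every run
is reproducible from one integer seed. What green tests on fixtures do
*not* establish: behavior on real genomes with repetitive flanks or
overlapping ORFs (overlaps must be declared by the user — similarity
detection against the reference genome is out of scope), performance of
degenerate-site enzyme lists, or any wet-lab efficiency.

## Parameters

| parameter      | default | meaning                                                               |
|----------------|---------|-----------------------------------------------------------------------|
| `min_homology` | 70 bp   | minimum homology on each side of the linearization cut for efficient integration |
| `r_homo`       | 2.0     | target pop-out/pop-in length ratio; ≥ 2 biases pop-out toward the edit |
| `flank_len`    | 1000 bp | length of each flanking region in the locus file                       |
| `min_repeat`   | 25 bp   | shortest direct repeat considered recombinogenic by the safety scan    |

## Known limitations

- Recombination homology is measured in base pairs of exact sequence;
  methylation sensitivity, star activity and Type IIS cutting geometry
  are not modeled.
- Duplicate restriction sites inside a user-supplied tag gene must be
  removed by the user (e.g. by synonymous codon swaps); the tool rejects
  rather than rewrites.
- The batch driver treats each gene file independently; it does not
  detect overlapping ORFs between files.
- No primer design, codon optimization, or Gibson/Golden-Gate planning.
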