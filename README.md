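# pipo — design of pop-in/pop-out genome-editing plasmids for budding yeast

Pop-in/pop-out (PIPO) is the classic marker-recycling strategy for
scarless genome editing in *Saccharomyces cerevisiae*: an integrative
plasmid carrying a counterselectable marker (e.g. *URA3*) is linearized
inside a region homologous to the target locus and integrated by single
crossover (**pop-in**, selected); spontaneous recombination between the
direct repeats created by the integration then excises the plasmid
backbone (**pop-out**, counterselected on 5-FOA), leaving either the
intended edit or the wild-type sequence. With gene synthesis now cheap,
the practical question is: *what is the shortest insert you need to
synthesize so that the construct is buildable, cuttable, and biased
toward the desired pop-out?*

`pipo` answers that question automatically for the three standard edit
tasks — ORF deletion, N-terminal tagging and C-terminal tagging. For a
gene locus supplied as 1,000 bp of 5′ flank + ORF + 1,000 bp of 3′ flank
it:

1. checks the locus (start/stop codons, user-declared ORF overlaps);
2. enumerates every unique restriction site in the two eligible homology
   regions as a candidate linearization cut, requiring at least
   `min_homology` (default 70 bp) on both sides of the cut;
3. sizes the **pop-in arm** (junction-to-cut distance + 70 bp) and the
   **pop-out arm** as `R_homo ×` the pop-in length (default `R_homo = 2`,
   the ratio shown empirically to favor the intended pop-out; the arm is
   truncated with a warning if the region is shorter);
4. assembles the insert — for tagging, with a linker, the
   fluorescent-protein gene (FPG), and three unique 6-bp restriction
   sites around them for later part exchange, verified not to introduce
   stop codons in the fusion frame;
5. picks a subcloning enzyme pair for the backbone's multiple cloning
   site (MCS) that keeps the linearization site unique on the final
   circular plasmid;
6. reports every candidate (with machine-readable rejection reasons) and
   flags the valid design with the **minimal synthesized insert** as
   optimal;
7. *verifies* each design in silico by simulating the pop-in integration
   and enumerating all direct-repeat pop-out products — a correct design
   yields exactly one wild-type reversion and one intended edit.

## Worked example

The package ships a deterministic synthetic-data generator, so you can
try the full pipeline without any real sequences:

```
$ pipo fixtures --out demo --seed 1 --n-genes 1
wrote 1 gene(s), backbone and parameter files under demo

$ pipo design --task tag-c --goi demo/genes/GENE1.fasta \
      --config demo/config.yml --out demo/out
GENE1 tag-c: 2/2 valid candidates; optimal EcoRI in FR3 (insert 939 bp, ratio 2.000)
```

`demo/out/GENE1_tag_c_report.tsv` then contains one row per candidate
linearization cut:

```
gene   task   enzyme  pop_in_region  cut_pos  d_junction  pop_in_len  pop_out_len  achieved_ratio  truncated  tag_sites       mcs_left  mcs_right  insert_len  status  reason  optimal
GENE1  tag_c  EcoRI   FR3            150      150         220         440          2.0             False      NheI,KpnI,PstI  SalI      SpeI       939         valid           True
GENE1  tag_c  XhoI    ORF            300      297         367         734          2.0             False      NheI,KpnI,PstI  SalI      SpeI       1380        valid           False
```

Reading the optimal row: the plasmid is linearized with EcoRI, whose cut
sits 150 bp into the 3′ flank; the pop-in arm is 150 + 70 = 220 bp, the
pop-out arm (taken from the ORF end) is 2 × 220 = 440 bp; the insert to
synthesize — both arms, the linker, the tag gene, and the three flanking
sites NheI/KpnI/PstI — totals 939 bp, and the insert is subcloned into
the backbone MCS between SalI and SpeI. The assembled circular plasmid
and the insert are written as FASTA next to the report.

Every design can be checked end-to-end:

```
$ pipo simulate --plasmid demo/out/GENE1_tag_c_plasmid.fasta \
      --goi demo/genes/GENE1.fasta --enzymes demo/enzymes.txt \
      --enzyme EcoRI --out demo/sim
2 pop-out outcome(s): WT_REVERSION, OTHER
```

(i.e. one pop-out reverts to wild type; the other is the edit — pass the
expected edited locus via `--intended` to have it labeled
`INTENDED_EDIT`.)

Batch mode (`pipo batch --genes <dir> ...`) designs a whole directory of
gene FASTAs for all tasks and reports the designable fraction.

## Library use

All functionality is importable; the CLI is a thin wrapper:

```python
from pipo import default_fixture, design, verify_design, EditTask

locus, backbone, params = default_fixture(seed=1)
candidates = design(locus, EditTask.TAG_C, params, backbone.seq, backbone.mcs_interval)
best = next(c for c in candidates if c.optimal)
outcomes = verify_design(locus, EditTask.TAG_C, params, best)
# -> one WT_REVERSION and one INTENDED_EDIT, nothing else
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates a 25-locus synthetic battery from the seed, designs plasmids
for all three tasks, and re-verifies every valid design by pop-in/pop-out
simulation, writing the results JSON to `--out`. It exits non-zero if any
design fails to round-trip.

See `docs/methods.md` for the model, parameter semantics, numerical
conventions and known limitations.
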