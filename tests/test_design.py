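import pytest
from Bio.Seq import Seq

from pipo import (
    AnnotatedSequence,
    DesignParams,
    EditTask,
    Feature,
    InputError,
    Region,
    assemble_plasmid,
    build_arms,
    check_no_stop_inframe,
    design,
    eligible_region_pairs,
    enumerate_candidates,
    find_sites,
    intended_edit,
    make_backbone,
    make_goi,
    select_mcs_enzymes,
    select_tag_flank_enzymes,
)
from pipo.design import (
    MIN_HOMOLOGY_DISTAL,
    MIN_HOMOLOGY_JUNCTION,
)
from pipo.fixtures import DEFAULT_LINKER, FixtureSpec, make_fpg


def planted_world(enzymes, by_name, *, fr3_offset=None, orf_len=600, seed=11):
    """Locus with a single EcoRI site planted in the 3' FR."""
    plants = []
    if fr3_offset is not None:
        plants.append((by_name["EcoRI"], "FR3", fr3_offset))
    spec = FixtureSpec(seed=seed, orf_len=orf_len, flank_len=1000,
                       plants=tuple(plants), forbidden=enzymes)
    return make_goi(spec)


@pytest.fixture(scope="module")
def params(enzymes_module, tag_enzymes_module):
    return DesignParams(
        enzymes=enzymes_module,
        linker=DEFAULT_LINKER,
        fpg=make_fpg(5, n_codons=60, forbidden=enzymes_module + tag_enzymes_module),
        tag_flank_enzymes=tag_enzymes_module,
    )


@pytest.fixture(scope="module")
def enzymes_module():
    from pipo import default_enzymes

    return default_enzymes()


@pytest.fixture(scope="module")
def tag_enzymes_module():
    from pipo import default_tag_enzymes

    return default_tag_enzymes()


@pytest.fixture(scope="module")
def by_name_module(enzymes_module):
    return {e.name: e for e in enzymes_module}


class TestEligibleRegionPairs:
    def test_delete_both_roles(self):
        assert eligible_region_pairs(EditTask.DELETE) == [
            (Region.FR3, Region.FR5),
            (Region.FR5, Region.FR3),
        ]

    def test_tag_c_depicted_variant_first(self):
        pairs = eligible_region_pairs(EditTask.TAG_C)
        assert pairs[0] == (Region.FR3, Region.ORF)
        assert len(pairs) == 2

    def test_tag_n_two_pairs(self):
        assert eligible_region_pairs(EditTask.TAG_N) == [
            (Region.FR5, Region.ORF),
            (Region.ORF, Region.FR5),
        ]


class TestEnumerateCandidates:
    def test_admissible_planted_site(self, enzymes_module, by_name_module, params):
        locus = planted_world(enzymes_module, by_name_module, fr3_offset=100)
        cands = [c for c in enumerate_candidates(locus, EditTask.TAG_C, params)
                 if c.pop_in_region is Region.FR3]
        assert len(cands) == 1
        c = cands[0]
        assert c.enzyme == "EcoRI" and c.admissible
        assert c.d_junction == 100
        assert c.d_distal == 900
        assert c.d_junction + c.d_distal == 1000

    def test_too_close_to_junction(self, enzymes_module, by_name_module, params):
        locus = planted_world(enzymes_module, by_name_module, fr3_offset=40)
        (c,) = [c for c in enumerate_candidates(locus, EditTask.TAG_C, params)
                if c.pop_in_region is Region.FR3]
        assert MIN_HOMOLOGY_JUNCTION in c.inadmissible_reasons

    def test_too_close_to_distal_end(self, enzymes_module, by_name_module, params):
        locus = planted_world(enzymes_module, by_name_module, fr3_offset=960)
        (c,) = [c for c in enumerate_candidates(locus, EditTask.TAG_C, params)
                if c.pop_in_region is Region.FR3]
        assert c.d_distal == 40
        assert MIN_HOMOLOGY_DISTAL in c.inadmissible_reasons

    def test_monotone_in_min_homology(self, world):
        """Raising min_homology can only shrink the admissible set."""
        locus, _, params = world
        for task in EditTask:
            loose = {
                (c.enzyme, c.pop_in_region, c.cut_pos)
                for c in enumerate_candidates(locus, task, params)
                if c.admissible
            }
            import dataclasses

            tight_params = dataclasses.replace(params, min_homology=200)
            tight = {
                (c.enzyme, c.pop_in_region, c.cut_pos)
                for c in enumerate_candidates(locus, task, tight_params)
                if c.admissible
            }
            assert tight <= loose


class TestBuildArms:
    def _cut(self, locus, params, task=EditTask.TAG_C):
        (c,) = [c for c in enumerate_candidates(locus, task, params)
                if c.pop_in_region is Region.FR3 and c.admissible]
        return c

    def test_pop_in_plus_target_ratio(self, enzymes_module, by_name_module, params):
        locus = planted_world(enzymes_module, by_name_module, fr3_offset=100)
        cut = self._cut(locus, params)
        arms = build_arms(locus, EditTask.TAG_C, cut, params)
        assert arms.pop_in_len == 100 + 70
        assert arms.pop_out_len == 340  # round(2 * 170)
        assert not arms.truncated
        assert abs(arms.achieved_ratio - 2.0) <= 1 / arms.pop_in_len
        # arms are genomic sequence
        assert arms.pop_in in locus.full
        assert arms.pop_out in locus.orf

    def test_truncation_takes_whole_region(self, enzymes_module, by_name_module, params):
        locus = planted_world(enzymes_module, by_name_module, fr3_offset=100, orf_len=204)
        cut = self._cut(locus, params)
        arms = build_arms(locus, EditTask.TAG_C, cut, params)
        # usable ORF (stop codon excluded) is 201 bp < target 340
        assert arms.truncated
        assert arms.pop_out_len == 201
        assert arms.pop_out == locus.orf[:-3]
        assert arms.achieved_ratio == pytest.approx(201 / 170)

    @pytest.mark.parametrize("r_homo,expected", [(0.5, 85), (0.75, 128), (2.0, 340)])
    def test_rounding_half_away_from_zero(
        self, enzymes_module, by_name_module, params, r_homo, expected
    ):
        import dataclasses

        locus = planted_world(enzymes_module, by_name_module, fr3_offset=100)
        p = dataclasses.replace(params, r_homo=r_homo)
        arms = build_arms(locus, EditTask.TAG_C, self._cut(locus, p), p)
        assert arms.pop_out_len == expected


class TestCheckNoStopInframe:
    @pytest.mark.parametrize(
        "site,ok",
        [
            ("GGATCC", True),   # GGA TCC
            ("TTAATT", True),   # TTA ATT
            ("CTAACT", True),   # CTA ACT
            ("TAATGA", False),  # TAA
            ("GAATTC", True),   # GAA TTC
            ("ATGATC", True),
        ],
    )
    def test_frame_zero(self, site, ok):
        assert check_no_stop_inframe(site) is ok

    def test_offset_with_context(self):
        # left context T completes T|AA TAA CC C -> TAA at codon 1
        assert check_no_stop_inframe("AATAAC", 1, left_context="GT", right_context="CC") is False
        assert check_no_stop_inframe("AACAAC", 1, left_context="GC", right_context="CC") is True

    def test_wrong_length_rejected(self):
        with pytest.raises(InputError):
            check_no_stop_inframe("GGATC")


class TestInsertAssembly:
    def test_delete_is_arm_concatenation(self, world):
        locus, bb, params = world
        cands = design(locus, EditTask.DELETE, params, bb.seq, bb.mcs_interval)
        for c in cands:
            if c.status != "valid":
                continue
            arms = c.arms
            assert len(c.insert.seq) == arms.pop_in_len + arms.pop_out_len
            # genomic 5'->3' order: 5'FR part then 3'FR part
            fr5_part = arms.pop_in if c.cut.pop_in_region is Region.FR5 else arms.pop_out
            fr3_part = arms.pop_in if c.cut.pop_in_region is Region.FR3 else arms.pop_out
            assert c.insert.seq == fr5_part + fr3_part
            assert c.insert.feature("LINEARIZATION_SITE") is not None

    def test_tag_c_drops_native_stop(self, world):
        locus, bb, params = world
        assert locus.orf[-3:] == "TAA"
        cands = design(locus, EditTask.TAG_C, params, bb.seq, bb.mcs_interval)
        for c in cands:
            if c.status != "valid" or c.cut.pop_in_region is not Region.FR3:
                continue
            orf_part_feature = c.insert.feature("POP_OUT_ARM")
            orf_part = c.insert.seq[orf_part_feature.start : orf_part_feature.end]
            assert orf_part[-3:] not in {"TAA", "TAG", "TGA"}
            assert orf_part == locus.orf[-3 - len(orf_part) : -3]

    def test_tagged_fusion_translates_without_internal_stop(self, world):
        """Independent check with Biopython's codon table on the edited locus."""
        locus, bb, params = world
        U, O = locus.flank_len, len(locus.orf)
        for task in (EditTask.TAG_C, EditTask.TAG_N):
            cands = design(locus, task, params, bb.seq, bb.mcs_interval)
            best = next(c for c in cands if c.optimal)
            assignment = tuple(
                next(e for e in params.tag_flank_enzymes if e.name == n)
                for n in best.tag_flank_assignment
            )
            edited = intended_edit(locus, task, params, assignment)
            if task is EditTask.TAG_C:
                cds = edited[U : len(edited) - U]  # ATG .. site3 end
                # fusion CDS: native start to FPG stop; site 3 follows the stop
                cds = cds[: len(cds) - 6]
            else:
                # fusion starts at the FPG ATG, after site 1 in the 5' UTR
                cds = edited[U + 6 : len(edited) - U]
            assert len(cds) % 3 == 0
            protein = str(Seq(cds).translate())
            assert protein.count("*") == 1 and protein.endswith("*")
            assert protein.startswith("M")

    def test_linker_not_codon_multiple_rejected(self, world):
        import dataclasses

        locus, bb, params = world
        bad = dataclasses.replace(params, linker="GGTT")
        with pytest.raises(InputError, match="linker"):
            design(locus, EditTask.TAG_C, bad, bb.seq, bb.mcs_interval)

    def test_fpg_required_for_tagging(self, world):
        import dataclasses

        locus, bb, params = world
        bad = dataclasses.replace(params, fpg="")
        with pytest.raises(InputError, match="fluorescent"):
            design(locus, EditTask.TAG_N, bad, bb.seq, bb.mcs_interval)


class TestSelectTagFlankEnzymes:
    PIECES = ("CACCACCAC", "GGTGGTGGT", "ATGCATCATCATTAA", "CCACCACCA")

    def test_greedy_file_order(self, params):
        chosen = select_tag_flank_enzymes(self.PIECES, "A" * 200, params, "EcoRI", EditTask.TAG_C)
        assert tuple(e.name for e in chosen) == ("NheI", "KpnI", "PstI")

    def test_enzyme_with_site_in_piece_skipped(self, params, by_name_module):
        pieces = (self.PIECES[0], self.PIECES[1],
                  "ATG" + by_name_module["NheI"].recognition + "CATTAA", self.PIECES[3])
        chosen = select_tag_flank_enzymes(pieces, "A" * 200, params, "EcoRI", EditTask.TAG_C)
        assert "NheI" not in {e.name for e in chosen}

    def test_pigeonhole_rejection(self, enzymes_module, by_name_module):
        few = DesignParams(
            enzymes=enzymes_module,
            linker=DEFAULT_LINKER,
            fpg="ATGCATCATTAA",
            tag_flank_enzymes=(by_name_module["NheI"], by_name_module["KpnI"]),
        )
        assert select_tag_flank_enzymes(self.PIECES, "A" * 200, few, "EcoRI", EditTask.TAG_C) is None

    def test_linearization_enzyme_excluded(self, params):
        chosen = select_tag_flank_enzymes(self.PIECES, "A" * 200, params, "NheI", EditTask.TAG_C)
        assert "NheI" not in {e.name for e in chosen}


class TestSelectMcsEnzymes:
    def test_planted_pair_found(self, world):
        locus, bb, params = world
        pair = select_mcs_enzymes("A" * 100, bb.seq, bb.mcs_interval, params.enzymes, "EcoRI")
        assert tuple(e.name for e in pair) == ("SalI", "SpeI")

    def test_enzyme_cutting_insert_excluded(self, world, by_name_module, enzymes_module):
        locus, bb, params = world
        insert = "A" * 50 + by_name_module["SalI"].recognition + "A" * 50
        assert select_mcs_enzymes(insert, bb.seq, bb.mcs_interval, params.enzymes, "EcoRI") is None

    def test_three_site_mcs_skips_blocked_enzyme(self, enzymes_module, by_name_module):
        bb = make_backbone(
            3, length=3000,
            mcs_enzymes=(by_name_module["SalI"], by_name_module["SpeI"], by_name_module["XbaI"]),
            forbidden=enzymes_module,
        )
        insert = "A" * 50 + by_name_module["SpeI"].recognition + "A" * 50
        pair = select_mcs_enzymes(insert, bb.seq, bb.mcs_interval, enzymes_module, "EcoRI")
        assert tuple(e.name for e in pair) == ("SalI", "XbaI")

    def test_linearization_enzyme_not_reused(self, world):
        locus, bb, params = world
        pair = select_mcs_enzymes("A" * 100, bb.seq, bb.mcs_interval, params.enzymes, "SalI")
        assert pair is None  # only SpeI left inside the MCS

    def test_invalid_interval_rejected(self, world):
        locus, bb, params = world
        with pytest.raises(InputError):
            select_mcs_enzymes("A", bb.seq, (500, 100), params.enzymes, "EcoRI")


class TestAssemblePlasmid:
    def test_length_conservation_and_backbone_preserved(self, world):
        locus, bb, params = world
        cands = design(locus, EditTask.DELETE, params, bb.seq, bb.mcs_interval)
        best = next(c for c in cands if c.optimal)
        lc_enz = next(e for e in params.enzymes if e.name == best.mcs_pair[0])
        rc_enz = next(e for e in params.enzymes if e.name == best.mcs_pair[1])
        from pipo import top_strand_cut

        lc = top_strand_cut(find_sites(bb.seq, lc_enz)[0], lc_enz)
        rc = top_strand_cut(find_sites(bb.seq, rc_enz)[0], rc_enz)
        excised = rc - lc
        assert len(best.plasmid.seq) == len(bb.seq) - excised + best.insert_len
        # retained backbone is untouched outside the excised MCS fragment
        assert best.plasmid.seq.startswith(bb.seq[:lc])
        assert best.plasmid.seq.endswith(bb.seq[rc:])

    def test_pop_out_arm_adjacent_to_left_mcs_cut(self, world):
        locus, bb, params = world
        for task in EditTask:
            for c in design(locus, task, params, bb.seq, bb.mcs_interval):
                if c.status != "valid":
                    continue
                pin = c.plasmid.feature("POP_IN_ARM")
                pout = c.plasmid.feature("POP_OUT_ARM")
                assert pout.start < pin.start

    def test_rotation_invariance_of_linearization(self, world):
        from pipo import linearize_plasmid

        locus, bb, params = world
        cands = design(locus, EditTask.DELETE, params, bb.seq, bb.mcs_interval)
        best = next(c for c in cands if c.optimal)
        enz = next(e for e in params.enzymes if e.name == best.linearization_enzyme)
        opened = linearize_plasmid(best.plasmid, enz)
        assert len(opened.seq) == len(best.plasmid.seq)
        assert opened.seq in best.plasmid.seq + best.plasmid.seq

    def test_requires_arm_features(self, world):
        locus, bb, params = world
        bare = AnnotatedSequence("ACGT" * 30, (Feature("LINKER", 0, 4),))
        enz1 = next(e for e in params.enzymes if e.name == "SalI")
        enz2 = next(e for e in params.enzymes if e.name == "SpeI")
        from pipo.seqcore import PipoError

        with pytest.raises(PipoError):
            assemble_plasmid(bb.seq, bb.mcs_interval, bare, (enz1, enz2))


class TestDesignPipeline:
    def test_optimal_is_brute_force_minimum(self, world):
        locus, bb, params = world
        for task in EditTask:
            cands = design(locus, task, params, bb.seq, bb.mcs_interval)
            valid = [c for c in cands if c.status == "valid"]
            best = next(c for c in cands if c.optimal)
            assert best.insert_len == min(c.insert_len for c in valid)
            assert sum(c.optimal for c in cands) == 1

    def test_symmetric_tie_broken_by_enzyme_file_order(self, world):
        """Both delete-role candidates are planted 150 bp from the junction:
        equal insert length and ratio, so enzyme file order decides."""
        locus, bb, params = world
        cands = design(locus, EditTask.DELETE, params, bb.seq, bb.mcs_interval)
        valid = [c for c in cands if c.status == "valid"]
        assert len({c.insert_len for c in valid}) == 1
        best = next(c for c in cands if c.optimal)
        assert best.cut.enzyme == "EcoRI"  # before BamHI in the default list

    def test_rejections_carry_reasons(self, world):
        import dataclasses

        locus, bb, params = world
        strict = dataclasses.replace(params, min_homology=400)
        cands = design(locus, EditTask.DELETE, strict, bb.seq, bb.mcs_interval)
        assert all(c.status == "rejected" for c in cands)
        assert all(c.reject_reason for c in cands)

    def test_deterministic_output(self, world):
        locus, bb, params = world
        a = design(locus, EditTask.TAG_C, params, bb.seq, bb.mcs_interval)
        b = design(locus, EditTask.TAG_C, params, bb.seq, bb.mcs_interval)
        assert [(c.status, c.insert.seq if c.insert else None, c.optimal) for c in a] == [
            (c.status, c.insert.seq if c.insert else None, c.optimal) for c in b
        ]
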