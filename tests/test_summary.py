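"""Site-level summaries on the packaged 48-phosphopeptide inventory."""

import pytest

from phosphopmf import (
    annotate_novelty,
    deduplicate_sites,
    group_isoforms,
    motif_matrix,
    repeat_statistics,
    residue_distribution,
    sites_table,
)
from phosphopmf.summary import GAP, PeptideSiteRecord, parse_annotated_peptide


class TestAnnotationParsing:
    @pytest.mark.parametrize(
        "annotated,plain,mods",
        [
            ("Y^PNQLLR", "YNQLLR", [(1, "P")]),
            ("FPGQLNS^PDLRK", "FPGQLNSDLRK", [(7, "P")]),
            ("IVMELFADC^CamT^PPR", "IVMELFADCTPR", [(9, "Cam"), (10, "P")]),
            ("LC^CamES^PQGIDYEYGSGR", "LCESQGIDYEYGSGR", [(2, "Cam"), (4, "P")]),
        ],
    )
    def test_marker_parsing(self, annotated, plain, mods):
        seq, parsed = parse_annotated_peptide(annotated)
        assert seq == plain and parsed == mods

    def test_dangling_marker_rejected(self):
        with pytest.raises(ValueError):
            parse_annotated_peptide("^PYNQLLR")


class TestPackagedInventory:
    def test_48_rows_with_consistent_coordinates(self, inventory_records):
        assert len(inventory_records) == 48
        for r in inventory_records:
            assert r.end - r.start + 1 == len(r.peptide)
            assert r.peptide[r.site - r.start] == r.residue

    def test_dedup_yields_40_unique_sites(self, inventory_records):
        sites = deduplicate_sites(inventory_records)
        assert len(sites) == 40

    def test_13_repeat_rows_in_5_groups(self, inventory_records):
        sites = deduplicate_sites(inventory_records)
        repeat_rows, repeat_groups = repeat_statistics(sites)
        assert (repeat_rows, repeat_groups) == (13, 5)

    def test_enolase_repeat_group_has_four_supporting_spots(self, inventory_records):
        sites = deduplicate_sites(inventory_records)
        eno = [
            s
            for s in sites
            if s.accession == "AY297757"
            and any(r.peptide == "AAVPSGASTGIYEALELR" for r in s.supporting_peptides)
        ]
        [site] = eno
        assert site.residue == "Y" and site.position == 47
        assert {r.spot_id for r in site.supporting_peptides} == {"117", "135", "204", "233"}

    def test_residue_distribution_s22_t14_y4(self, inventory_records):
        dist = residue_distribution(deduplicate_sites(inventory_records))
        assert dist == {"S": 22, "T": 14, "Y": 4}

    def test_40_distinct_spots(self, inventory_records):
        iso = group_isoforms(inventory_records)
        assert iso["spot_id"].nunique() == 40

    def test_enolase_isoform_row_and_spot135_two_sites(self, inventory_records):
        iso = group_isoforms(inventory_records).set_index(["accession", "spot_id"])
        eno_spots = {s for a, s in iso.index if a == "AY297757"}
        assert eno_spots == {"117", "135", "204", "233"}
        assert iso.loc[("AY297757", "135"), "n_sites"] == 2


class TestDedupBehaviour:
    def test_idempotent(self, inventory_records):
        once = deduplicate_sites(inventory_records)
        again = deduplicate_sites(
            [r for s in once for r in s.supporting_peptides]
        )
        assert {(s.accession, s.position, s.residue) for s in again} == {
            (s.accession, s.position, s.residue) for s in once
        }

    def test_identical_records_collapse_to_one_supporting_peptide(self):
        rec = PeptideSiteRecord("1", "ACC", "YNQLLR", 417, 422, 417, "Y", 21.29)
        [site] = deduplicate_sites([rec, rec])
        assert len(site.supporting_peptides) == 1

    def test_conflicting_residue_at_same_position_raises(self):
        a = PeptideSiteRecord("1", "ACC", "SYR", 10, 12, 10, "S", 20.0)
        b = PeptideSiteRecord("2", "ACC", "YSR", 10, 12, 10, "Y", 20.0)
        with pytest.raises(ValueError, match="conflicting"):
            deduplicate_sites([a, b])

    def test_empty_input_gives_all_zero_distribution(self):
        assert residue_distribution([]) == {"S": 0, "T": 0, "Y": 0}


class TestMotifMatrix:
    def test_terminus_padding_records_gaps(self):
        rec = PeptideSiteRecord("1", "ACC", "SYR", 1, 3, 1, "S", 20.0)
        mm = motif_matrix(deduplicate_sites([rec]), flank=6)
        for pos in range(-6, 0):
            assert mm.counts.loc[GAP, pos] == 1
        assert mm.counts.loc["S", 0] == 1

    def test_column_sums_equal_site_count(self, inventory_records):
        sites = deduplicate_sites(inventory_records)
        mm = motif_matrix(sites, flank=6)
        assert (mm.counts.sum(axis=0) == len(sites)).all()

    def test_full_sequence_context_preferred_over_peptide(self):
        rec = PeptideSiteRecord("1", "ACC", "SYR", 5, 7, 5, "S", 20.0)
        seqs = {"ACC": "WWWWSYRWWW"}
        mm = motif_matrix(deduplicate_sites([rec]), protein_sequences=seqs, flank=3)
        # peptide-context mode would record gaps here; full sequence fills W
        assert mm.counts.loc["W", -2] == 1 and mm.counts.loc["W", 3] == 1
        assert mm.counts.loc[GAP].sum() == 0

    def test_site_outside_supplied_sequence_raises(self):
        rec = PeptideSiteRecord("1", "ACC", "SYR", 5, 7, 5, "S", 20.0)
        with pytest.raises(ValueError, match="ACC"):
            motif_matrix(deduplicate_sites([rec]), protein_sequences={"ACC": "SY"})

    def test_acidic_enrichment_near_serine_exceeds_threonine(self, inventory_records):
        """E+D frequency at positions -1..+4 around pS sites exceeds the
        same frequency around pT sites (acidic-motif signature)."""
        sites = deduplicate_sites(inventory_records)
        cols = [-1, 1, 2, 3, 4]

        def acid_freq(residue):
            sub = [s for s in sites if s.residue == residue]
            mm = motif_matrix(sub, flank=6)
            freq = mm.frequencies(include_gaps=True)
            return freq.loc[["E", "D"], cols].to_numpy().sum()

        assert acid_freq("S") > acid_freq("T")


class TestNovelty:
    def test_no_known_list_means_undetermined(self, inventory_records):
        sites = annotate_novelty(deduplicate_sites(inventory_records), None)
        assert {s.novelty for s in sites} == {"undetermined"}

    def test_lookup_flags_known_sites(self):
        rec = PeptideSiteRecord("1", "ACC", "YNQLLR", 417, 422, 417, "Y", 21.29)
        other = PeptideSiteRecord("2", "ACC2", "SGR", 1, 3, 1, "S", 30.0)
        sites = deduplicate_sites([rec, other])
        flagged = annotate_novelty(sites, [("YNQLLR", 1)])
        by_acc = {s.accession: s.novelty for s in flagged}
        assert by_acc == {"ACC": "known", "ACC2": "new"}

    def test_duplicate_known_entries_equivalent_to_unique(self, inventory_records):
        sites = deduplicate_sites(inventory_records)
        known = [("YNQLLR", 1), ("YNQLLR", 1), ("FPGQLNSDLRK", 7)]
        a = annotate_novelty(sites, known)
        b = annotate_novelty(sites, list(set(known)))
        assert [s.novelty for s in a] == [s.novelty for s in b]

    def test_packaged_known_flags_recoverable_from_fixture(self, inventory_records):
        """Using the fixture's own database-known annotations as the
        lookup table flags exactly those sites as known."""
        sites = deduplicate_sites(inventory_records)
        known = [
            (r.peptide, r.site_offset) for r in inventory_records if r.known_flag
        ]
        flagged = annotate_novelty(sites, known)
        for s in flagged:
            expect = any(r.known_flag for r in s.supporting_peptides)
            assert (s.novelty == "known") == expect


def test_sites_table_has_one_row_per_site(inventory_records):
    sites = deduplicate_sites(inventory_records)
    df = sites_table(sites)
    assert len(df) == 40
    assert df["n_supporting_peptides"].sum() == 48
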