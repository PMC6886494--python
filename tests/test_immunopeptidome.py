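import io

import pytest

from conftest import hypergeom_tail_by_enumeration, records_from_frame
from ndnet.enrichment import EnrichmentParams
from ndnet.immunopeptidome import (
    DR15_ALLELE_GROUP,
    EpitopeAssayRecord,
    FilterCriteria,
    RestrictionProfile,
    build_restriction_profiles,
    exclusive_restriction,
    filter_assays,
    parent_set_enrichment,
    parse_assays,
)
from ndnet.seed_registry import GeneRef, GeneSet, IdMap

HEADER = (
    "epitope_seq\tparent_accession\tparent_symbol\tmhc_class\trestriction\t"
    "assay_method\thost\tantigen_organism\tcell_lineage\timmunized\tstudy_id\n"
)


def row(
    seq="ACDEFGHIKLMNPQR",
    acc="P00001",
    sym="GENE1",
    mhc="II",
    restriction="HLA-DR1",
    method="cellular MHC/mass spectrometry",
    host="Homo sapiens",
    antigen="Homo sapiens",
    lineage="EBV-transformed B cell",
    immunized="false",
    study="S1",
):
    return "\t".join(
        [seq, acc, sym, mhc, restriction, method, host, antigen, lineage, immunized, study]
    ) + "\n"


def parse(rows: str):
    return parse_assays(io.StringIO(HEADER + rows))


class TestParseAssays:
    def test_one_record_per_row(self):
        recs = parse(row() + row(acc="P00002") + row(acc="P00003"))
        assert len(recs) == 3

    def test_mhc_class_token_normalization(self):
        recs = parse(row(mhc="class II") + row(mhc="I") + row(mhc="whatever"))
        assert [r.mhc_class for r in recs] == ["II", "I", "unknown"]

    def test_non_amino_acid_epitope_errors(self):
        with pytest.raises(ValueError, match="amino-acid"):
            parse(row(seq="PEPT1DE"))

    def test_missing_parent_accession_errors(self):
        with pytest.raises(ValueError, match="parent_accession"):
            parse(row(acc=""))

    def test_missing_column_errors(self):
        with pytest.raises(ValueError, match="restriction"):
            parse_assays(io.StringIO("epitope_seq\tparent_accession\nPEPTIDE\tP1\n"))


class TestFilterAssays:
    def test_keeps_only_endogenous_b_cell_ms_elution(self):
        recs = parse(
            row()  # compliant
            + row(method="T cell assay")  # wrong assay
            + row(immunized="true")  # immunized
        )
        res = filter_assays(recs)
        assert res.n_kept == 1
        assert res.dropped["assay_method"] == 1
        assert res.dropped["immunized_or_stimulated"] == 1

    def test_non_human_antigen_dropped(self):
        res = filter_assays(parse(row(antigen="Mus musculus")))
        assert res.n_kept == 0 and res.dropped["antigen_organism"] == 1

    def test_identity_on_compliant_input(self):
        recs = parse(row() + row(acc="P00002"))
        res = filter_assays(recs)
        assert res.records == tuple(recs)

    def test_idempotent_and_order_preserving(self):
        recs = parse(row(acc="P00003") + row(acc="P00001") + row(mhc="I"))
        once = filter_assays(recs)
        twice = filter_assays(once.records)
        assert twice.records == once.records
        assert [r.parent_accession for r in once.records] == ["P00003", "P00001"]

    def test_drop_counts_conserve_record_count(self):
        recs = parse(
            row()
            + row(mhc="I")
            + row(host="Mus musculus")
            + row(lineage="T lymphocyte")
            + row(immunized="true")
        )
        res = filter_assays(recs)
        assert res.n_kept + sum(res.dropped.values()) == res.n_input == 5

    def test_custom_vocabulary(self):
        crit = FilterCriteria(b_lineages=frozenset({"weird line"}))
        res = filter_assays(parse(row(lineage="weird line")), crit)
        assert res.n_kept == 1


class TestBuildRestrictionProfiles:
    def test_restrictions_union_per_parent(self):
        recs = parse(row(restriction="HLA-DR1") + row(restriction="HLA-DQ7.5"))
        profiles = build_restriction_profiles(recs)
        assert len(profiles) == 1
        assert profiles[0].restrictions == {"HLA-DR1", "HLA-DQ7.5"}
        assert profiles[0].n_supporting_records == 2

    def test_idmap_merges_obsolete_accessions(self):
        recs = parse(
            row(acc="X00001", restriction="HLA-DR1")
            + row(acc="P00441", restriction="HLA-DQ7.5")
        )
        idmap = IdMap({"X00001": "P00441"})
        profiles = build_restriction_profiles(recs, idmap=idmap)
        assert len(profiles) == 1
        assert profiles[0].parent_accession == "P00441"
        assert profiles[0].restrictions == {"HLA-DR1", "HLA-DQ7.5"}

    def test_supporting_records_conserved(self):
        recs = parse(
            row() + row(acc="P00002") + row(acc="P00002", restriction="HLA-DQ")
        )
        profiles = build_restriction_profiles(recs)
        assert sum(p.n_supporting_records for p in profiles) == len(recs)

    def test_seed_restriction(self):
        recs = parse(row(sym="SQSTM1") + row(acc="P00002", sym="NOTSEED"))
        seed = GeneSet(name="s", members=(GeneRef("SQSTM1"),))
        profiles = build_restriction_profiles(recs, seed=seed)
        assert [p.parent_symbol for p in profiles] == ["SQSTM1"]

    def test_packaged_hub_profile_traf6(self, table5_profiles):
        traf6 = next(p for p in table5_profiles if p.parent_symbol == "TRAF6")
        assert traf6.restrictions == {"HLA-DR1"}


class TestExclusiveRestriction:
    def test_dr15_exclusive_parents_on_packaged_table(self, table4_profiles):
        out = exclusive_restriction(table4_profiles, {"HLA-DR15/DR51"})
        assert {p.parent_symbol for p in out} == {"TBK1", "PSEN2", "MAPT"}

    def test_absent_allele_group_returns_empty(self, table4_profiles):
        assert exclusive_restriction(table4_profiles, {"HLA-DR99"}) == []

    def test_mixed_profile_is_not_exclusive(self):
        p = RestrictionProfile(
            parent_symbol="X",
            parent_accession="P00001",
            restrictions=frozenset({"HLA-DR15/DR51", "HLA-DR1"}),
            n_supporting_records=2,
            studies=frozenset(),
        )
        assert exclusive_restriction([p], {"HLA-DR15/DR51"}) == []

    def test_empty_allele_group_errors(self, table4_profiles):
        with pytest.raises(ValueError):
            exclusive_restriction(table4_profiles, set())

    def test_output_subset_of_intersecting_profiles(self, table4_profiles):
        group = DR15_ALLELE_GROUP
        out = exclusive_restriction(table4_profiles, group)
        intersecting = [
            p for p in table4_profiles if p.restrictions & set(group)
        ]
        assert set(out) <= set(intersecting)


def make_profiles(n, seed_symbols):
    profiles = []
    for i, sym in enumerate(seed_symbols):
        profiles.append(
            RestrictionProfile(sym, f"Q{i:05d}", frozenset({"HLA-DR"}), 1, frozenset())
        )
    for i in range(n - len(seed_symbols)):
        profiles.append(
            RestrictionProfile(
                f"PAR{i:05d}", f"P{i:05d}", frozenset({"HLA-DR"}), 1, frozenset()
            )
        )
    return profiles


class TestParentSetEnrichment:
    def seed(self):
        return GeneSet(
            name="s",
            members=tuple(GeneRef(f"ND{i:03d}") for i in range(1, 39)),
            declared_size=48,
        )

    def test_reported_share_of_seed_parents(self):
        seed = self.seed()
        profiles = make_profiles(3523, [f"ND{i:03d}" for i in range(1, 23)])
        res = parent_set_enrichment(
            profiles, seed, EnrichmentParams(K=48, N=20000)
        )
        assert res.k_seed == 22
        assert res.share_percent == 0.62
        assert res.ef == pytest.approx((22 / 3523) / (48 / 20000))

    def test_zero_overlap(self):
        res = parent_set_enrichment(
            make_profiles(10, []), self.seed(), EnrichmentParams(K=48, N=20000)
        )
        assert res.ef == 0.0 and res.p_value == 1.0

    def test_small_case_matches_enumeration_oracle(self):
        seed = GeneSet(
            name="s",
            members=tuple(GeneRef(f"ND{i:03d}") for i in range(1, 5)),
            declared_size=4,
        )
        profiles = make_profiles(5, ["ND001", "ND002"])
        res = parent_set_enrichment(profiles, seed, EnrichmentParams(K=4, N=20))
        expected = hypergeom_tail_by_enumeration(5, 4, 20)[2]
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_empty_parent_list_errors(self):
        with pytest.raises(ValueError):
            parent_set_enrichment([], self.seed())


def test_packaged_profile_counts(table4_profiles, table5_profiles):
    assert len(table4_profiles) == 23
    assert len(table5_profiles) == 8
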