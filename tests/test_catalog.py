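"""Allele catalog, variant derivation, filtering, and annotation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hlapqtl as h
from hlapqtl.catalog import (
    LOCI,
    amino_acid_variant_id,
    compute_maf,
    one_field_name,
)


def _toy_alleles():
    return [
        h.Allele("DRB1", "DRB1*04:01", {11: "S", 12: "A"}, {11: 2, 12: 2}),
        h.Allele("DRB1", "DRB1*04:04", {11: "S", 12: "A"}, {11: 2, 12: 2}),
        h.Allele("DRB1", "DRB1*15:01", {11: "G", 12: "A"}, {11: 2, 12: 2}),
    ]


def _toy_dosages(dosage_rows):
    alleles = _toy_alleles()
    variants = [h.VariantDef(a.two_field, "two_field", "DRB1") for a in alleles]
    return h.DosageMatrix(
        [f"I{i}" for i in range(len(dosage_rows))], variants, np.array(dosage_rows)
    )


class TestAminoAcidDerivation:
    def test_homozygote_carries_its_residues_everywhere(self, catalog):
        # an individual homozygous DRB1*04:01 has dosage 2 for every residue
        # that allele carries, at every polymorphic DRB1 position
        d = _toy_dosages([[2.0, 0.0, 0.0]])
        aa = h.derive_amino_acid_dosages(d, _toy_alleles())
        s_col = aa.column(amino_acid_variant_id("DRB1", 11, 2, {"S"}))
        assert s_col[0] == pytest.approx(2.0)

    def test_monomorphic_position_emits_no_variant(self):
        d = _toy_dosages([[1.0, 1.0, 0.0]])
        aa = h.derive_amino_acid_dosages(d, _toy_alleles())
        assert all(v.position != 12 for v in aa.variants)  # 12 is monomorphic

    def test_fractional_dosages_sum_per_residue(self):
        # alleles carrying (S, S, G) with dosages (0.5, 0.5, 1.0)
        d = _toy_dosages([[0.5, 0.5, 1.0]])
        aa = h.derive_amino_acid_dosages(d, _toy_alleles())
        assert aa.column(amino_acid_variant_id("DRB1", 11, 2, {"S"}))[0] == pytest.approx(1.0)
        assert aa.column(amino_acid_variant_id("DRB1", 11, 2, {"G"}))[0] == pytest.approx(1.0)

    def test_unknown_allele_is_a_hard_error_naming_it(self):
        d = _toy_dosages([[1.0, 1.0, 0.0]])
        with pytest.raises(KeyError, match="DRB1\\*15:01"):
            h.derive_amino_acid_dosages(d, _toy_alleles()[:2])

    def test_grouped_residue_marker_sums_over_the_set(self):
        d = _toy_dosages([[0.5, 0.5, 1.0]])
        aa = h.derive_amino_acid_dosages(
            d, _toy_alleles(), grouped_markers=[("DRB1", 11, {"S", "G"})]
        )
        grouped = aa.column(amino_acid_variant_id("DRB1", 11, 2, {"S", "G"}))
        assert grouped[0] == pytest.approx(2.0)

    def test_dosage_conservation_on_simulated_cohort(self, cohort, catalog):
        # per individual and position, residue dosages sum to the locus total
        aa = h.derive_amino_acid_dosages(cohort.observed_dosages, catalog)
        two = cohort.observed_dosages
        by_pos = {}
        for j, v in enumerate(aa.variants):
            by_pos.setdefault((v.locus, v.position), []).append(j)
        for (locus, _pos), idx in by_pos.items():
            locus_total = two.select(lambda v: v.locus == locus).dosage.sum(axis=1)
            np.testing.assert_allclose(
                aa.dosage[:, idx].sum(axis=1), locus_total, atol=1e-9
            )


class TestOneFieldDerivation:
    def test_members_sum_into_the_group(self):
        d = _toy_dosages([[1.0, 1.0, 0.0]])
        one = h.derive_one_field_dosages(d)
        assert one.column("DRB1*04")[0] == pytest.approx(2.0)

    def test_single_member_group_is_identity(self):
        d = _toy_dosages([[0.0, 0.0, 1.5]])
        assert h.derive_one_field_dosages(d).column("DRB1*15")[0] == pytest.approx(1.5)

    def test_fractional_grouping_matches_hand_sums(self):
        rows = [[0.25, 0.5, 1.25], [1.0, 0.75, 0.25]]
        one = h.derive_one_field_dosages(_toy_dosages(rows))
        np.testing.assert_allclose(one.column("DRB1*04"), [0.75, 1.75])
        np.testing.assert_allclose(one.column("DRB1*15"), [1.25, 0.25])

    def test_unparseable_name_errors(self):
        with pytest.raises(ValueError, match="parse"):
            one_field_name("DRB1-0401")


class TestFilterVariants:
    def _matrix(self, specs):
        variants = [
            h.VariantDef(f"v{i}", "two_field", "A", maf=maf, imputation_r2=r2)
            for i, (maf, r2) in enumerate(specs)
        ]
        dosage = np.tile(0.5, (4, len(specs)))
        return h.DosageMatrix(["a", "b", "c", "d"], variants, dosage)

    def test_low_maf_removed_and_inclusive_boundaries(self):
        d = self._matrix([(0.005, 0.9), (0.01, 0.70)])
        kept = h.filter_variants(d, 0.01, 0.7)
        assert kept.variant_ids == ["v1"]  # MAF 0.5% out; exact bounds retained

    def test_matches_brute_force_enumeration(self):
        specs = [(0.2, 0.9), (0.005, 0.95), (0.3, 0.5), (0.01, 0.7), (0.4, None)]
        d = self._matrix(specs)
        kept = h.filter_variants(d, 0.01, 0.7)
        expected = [
            f"v{i}" for i, (maf, r2) in enumerate(specs)
            if maf >= 0.01 and (r2 is None or r2 >= 0.7)
        ]
        assert kept.variant_ids == expected

    def test_idempotent(self, all_variants):
        once = h.filter_variants(all_variants, 0.05, 0.7)
        twice = h.filter_variants(once, 0.05, 0.7)
        assert once.variant_ids == twice.variant_ids


class TestPbgAnnotation:
    @pytest.mark.parametrize(
        "locus,exon,expected",
        [("B", 3, True), ("DRB1", 3, False), ("DRB1", 2, True),
         ("A", 2, True), ("C", 4, False), ("DQB1", 2, True)],
    )
    def test_class_exon_rules(self, locus, exon, expected):
        v = h.VariantDef("x", "amino_acid", locus, position=1,
                         residues=frozenset("A"), exon=exon)
        assert h.annotate_pbg(v) is expected

    def test_undefined_for_alleles(self):
        with pytest.raises(ValueError, match="undefined"):
            h.annotate_pbg(h.VariantDef("DRB1*04", "one_field", "DRB1"))

    @given(
        locus=st.sampled_from(sorted(LOCI)),
        exon=st.integers(min_value=1, max_value=8),
    )
    @settings(max_examples=100, deadline=None)
    def test_depends_only_on_class_and_exon(self, locus, exon):
        v = h.VariantDef("x", "amino_acid", locus, position=5,
                         residues=frozenset("Q"), exon=exon)
        oracle = exon in ({2, 3} if locus in ("A", "B", "C") else {2})
        assert h.annotate_pbg(v) is oracle


class TestCisTrans:
    @pytest.mark.parametrize(
        "chrom,start,end,expected",
        [("6", 32_000_000, 32_010_000, "cis"),
         ("12", 32_000_000, 32_010_000, "trans"),
         ("6", 27_900_000, 27_950_000, "trans"),
         ("chr6", 33_999_999, 34_500_000, "cis")],
    )
    def test_region_overlap(self, chrom, start, end, expected):
        assert h.classify_cis_trans(chrom, start, end) == expected

    def test_malformed_coordinates_error(self):
        with pytest.raises(ValueError):
            h.classify_cis_trans("6", 100, 50)


class TestRoundTrips:
    def test_catalog_json_round_trip(self, catalog, tmp_path):
        path = tmp_path / "cat.json"
        h.write_catalog(catalog, path)
        back = h.read_catalog(path)
        assert {a.two_field for a in back} == {a.two_field for a in catalog}
        orig = {a.two_field: a for a in catalog}
        for a in back:
            assert a.sequence == orig[a.two_field].sequence
            assert a.exon_of_position == orig[a.two_field].exon_of_position

    def test_dosage_tsv_round_trip(self, all_variants, tmp_path):
        from hlapqtl.io import read_dosages, write_dosages

        sub = all_variants.subset(all_variants.variant_ids[:8])
        write_dosages(sub, tmp_path / "d.tsv", tmp_path / "m.tsv")
        back = read_dosages(tmp_path / "d.tsv", tmp_path / "m.tsv")
        assert back.variant_ids == sub.variant_ids
        np.testing.assert_allclose(back.dosage, sub.dosage, rtol=1e-9)
        assert [v.kind for v in back.variants] == [v.kind for v in sub.variants]


def test_maf_folding():
    assert compute_maf(np.array([2.0, 2.0, 1.0, 2.0])) == pytest.approx(0.125)
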