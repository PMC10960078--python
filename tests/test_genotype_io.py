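import warnings

import numpy as np
import pytest
from hypothesis import given, settings

from conftest import genotype_matrices, make_matrix
from exsitu.genotype_io import (
    GenotypeFormatError,
    GenotypeMatrix,
    Locus,
    SamplePartition,
    apply_missing_filter,
    drop_samples,
    first_variant_per_group,
    read_genepop,
    read_metadata,
    read_structure,
    read_vcf,
    subset_shared,
    write_genepop,
    write_metadata,
    write_structure,
    write_vcf,
)

GENEPOP_TOY = """toy microsatellite file
L1
L2
L3
POP
ind1 ,  120120 095095 200204
ind2 ,  120124 095099 200200
POP
ind3 ,  124128 099099 204204
ind4 ,  128128 095099 0000 204204
"""


class TestGenepop:
    def test_toy_transcription(self, tmp_path):
        path = tmp_path / "toy.gen"
        path.write_text(GENEPOP_TOY.replace(" 0000 204204", " 204204"))
        gm = read_genepop(path)
        assert gm.individuals == ["ind1", "ind2", "ind3", "ind4"]
        assert [l.locus_id for l in gm.loci] == ["L1", "L2", "L3"]
        assert gm.provisional_populations == {
            "ind1": "pop1", "ind2": "pop1", "ind3": "pop2", "ind4": "pop2",
        }

    def test_all_zero_is_missing(self, tmp_path):
        path = tmp_path / "m.gen"
        path.write_text(
            "t\nL1\nPOP\na ,  0000\nb ,  1212\n"
        )
        gm = read_genepop(path)
        assert gm.missing_mask()[0, 0]
        assert not gm.missing_mask()[1, 0]

    def test_half_zero_collapses_to_missing(self, tmp_path):
        path = tmp_path / "m.gen"
        path.write_text("t\nL1\nPOP\na ,  0012\nb ,  1212\n")
        gm = read_genepop(path)
        assert gm.missing_mask()[0, 0]

    def test_allele_labels_enumerated(self, tmp_path):
        # hand enumeration: codes appearing at L1 are 120, 124, 128
        path = tmp_path / "toy.gen"
        path.write_text(GENEPOP_TOY.replace(" 0000 204204", " 204204"))
        gm = read_genepop(path)
        assert set(gm.loci[0].allele_labels) == {"120", "124", "128"}

    def test_mixed_digit_widths_names_locus(self, tmp_path):
        path = tmp_path / "bad.gen"
        path.write_text("t\nL1\nL2\nPOP\na ,  120120 9599\n")
        with pytest.raises(GenotypeFormatError, match="L2"):
            read_genepop(path)

    def test_odd_length_field_reports_line(self, tmp_path):
        path = tmp_path / "bad.gen"
        path.write_text("t\nL1\nPOP\na ,  12345\n")
        with pytest.raises(GenotypeFormatError, match="line 4"):
            read_genepop(path)

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.gen"
        path.write_text("t\nL1\nPOP\na ,  1212\na ,  1111\n")
        with pytest.raises(GenotypeFormatError, match="duplicate"):
            read_genepop(path)

    @settings(max_examples=25, deadline=None)
    @given(gm=genotype_matrices())
    def test_round_trip(self, gm, tmp_path_factory):
        path = tmp_path_factory.mktemp("gp") / "rt.gen"
        write_genepop(gm, path)
        back = read_genepop(path)
        assert back.individuals == gm.individuals
        assert [l.locus_id for l in back.loci] == [
            l.locus_id for l in gm.loci
        ]
        assert back.label_calls() == gm.label_calls()


STRUCTURE_TWO_ROW = """L1\tL2\tL3\tL4
i1\t1\t2\t3\t4
i1\t1\t2\t3\t4
i2\t2\t2\t-9\t4
i2\t1\t2\t3\t4
i3\t1\t1\t1\t1
i3\t2\t2\t2\t2
"""


class TestStructure:
    def test_two_row_shape(self, tmp_path):
        path = tmp_path / "s.str"
        path.write_text(STRUCTURE_TWO_ROW)
        gm = read_structure(path)
        assert (gm.n_individuals, gm.n_loci) == (3, 4)
        assert [l.locus_id for l in gm.loci] == ["L1", "L2", "L3", "L4"]

    def test_half_call_collapses_to_missing(self, tmp_path):
        path = tmp_path / "s.str"
        path.write_text(STRUCTURE_TWO_ROW)
        gm = read_structure(path)
        # i2 at L3 has alleles (-9, 3): collapsed to MISSING
        assert gm.missing_mask()[1, 2]
        assert not gm.missing_mask()[1, 3]

    def test_odd_row_count_rejected(self, tmp_path):
        path = tmp_path / "s.str"
        path.write_text("i1\t1\t2\ni1\t1\t2\ni2\t1\t1\n")
        with pytest.raises(GenotypeFormatError, match="odd"):
            read_structure(path)

    def test_ragged_rows_report_index(self, tmp_path):
        path = tmp_path / "s.str"
        path.write_text("i1\t1\t2\ni1\t1\n")
        with pytest.raises(GenotypeFormatError, match="row 1"):
            read_structure(path)

    @settings(max_examples=25, deadline=None)
    @given(gm=genotype_matrices())
    def test_round_trip_two_row(self, gm, tmp_path_factory):
        path = tmp_path_factory.mktemp("st") / "rt.str"
        write_structure(gm, path)
        back = read_structure(path)
        assert back.individuals == gm.individuals
        assert back.label_calls() == gm.label_calls()

    @settings(max_examples=25, deadline=None)
    @given(gm=genotype_matrices())
    def test_round_trip_one_row(self, gm, tmp_path_factory):
        path = tmp_path_factory.mktemp("st") / "rt.str"
        write_structure(gm, path, one_row_per_individual=True)
        back = read_structure(path, one_row_per_individual=True)
        assert back.individuals == gm.individuals
        assert back.label_calls() == gm.label_calls()


VCF_TOY = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
chr1\t100\tlocus7\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t./.
chr1\t105\tlocus7\tC\tT\t.\tPASS\t.\tGT\t0|0\t1/1\t0/1
chr2\t50\tlocus9\tG\tA,T\t.\tPASS\t.\tGT\t1/2\t0/0\t0/2
"""


class TestVcf:
    def test_gt_conventions(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(VCF_TOY)
        gm = read_vcf(path)
        assert gm.individuals == ["s1", "s2", "s3"]
        calls = gm.label_calls()
        assert calls[0][0] == ("A", "A")
        assert calls[1][0] == ("A", "G")
        assert calls[2][0] is None
        # phased separator treated like unphased
        assert calls[0][1] == ("C", "C")
        # multiallelic record
        assert calls[0][2] == ("A", "T")

    def test_single_record_two_samples(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\n"
            "1\t1\t.\tA\tC\t.\t.\t.\tGT\t0/1\t1/1\n"
        )
        gm = read_vcf(path)
        assert (gm.n_individuals, gm.n_loci) == (2, 1)

    def test_shared_id_populates_source_group(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(VCF_TOY)
        gm = read_vcf(path)
        assert gm.loci[0].source_group == "locus7"
        assert gm.loci[1].source_group == "locus7"
        assert gm.loci[2].source_group == "locus9"

    def test_write_read_structure_preserved(self, tmp_path):
        gm = make_matrix(
            [[("A", "G"), ("1", "2")], [("G", "G"), None]],
        )
        path = tmp_path / "o.vcf"
        write_vcf(gm, path)
        back = read_vcf(path)
        assert back.n_individuals == 2 and back.n_loci == 2
        assert back.missing_mask()[1, 1]
        # nucleotide labels survive verbatim
        assert back.label_calls()[0][0] == ("A", "G")


class TestFirstVariantPerGroup:
    def test_groups_aab(self):
        gm = make_matrix(
            [[("1", "1"), ("2", "2"), ("1", "2")]],
            source_groups=["A", "A", "B"],
        )
        out = first_variant_per_group(gm)
        assert [l.locus_id for l in out.loci] == ["L1", "L3"]

    def test_all_distinct_is_identity(self):
        gm = make_matrix(
            [[("1", "1"), ("2", "2")]], source_groups=["A", "B"]
        )
        out = first_variant_per_group(gm)
        assert [l.locus_id for l in out.loci] == ["L1", "L2"]

    def test_ten_loci_four_groups_brute_force(self):
        groups = ["g1", "g2", "g1", "g3", "g3", "g2", "g4", "g1", "g4", "g2"]
        gm = make_matrix(
            [[("1", "2")] * 10, [("2", "2")] * 10],
            source_groups=groups,
        )
        out = first_variant_per_group(gm)
        # brute force: first index of each group, in order
        expected = []
        seen = set()
        for i, g in enumerate(groups):
            if g not in seen:
                seen.add(g)
                expected.append(f"L{i + 1}")
        assert [l.locus_id for l in out.loci] == expected
        assert out.n_loci == 4

    @settings(max_examples=20, deadline=None)
    @given(genotype_matrices())
    def test_at_most_one_locus_per_group(self, gm):
        groups = [f"g{i % 3}" for i in range(gm.n_loci)]
        gm2 = make_matrix(gm.label_calls(), individuals=gm.individuals,
                          source_groups=groups)
        out = first_variant_per_group(gm2)
        seen = [l.source_group for l in out.loci]
        assert len(seen) == len(set(seen))


class TestMissingFilter:
    def _matrix_presence_3_of_5(self):
        col = [("1", "2"), ("1", "1"), ("2", "2"), None, None]
        return make_matrix([[c] for c in col])

    def test_threshold_arithmetic(self):
        gm = self._matrix_presence_3_of_5()
        assert apply_missing_filter(gm, 0.0).n_loci == 1
        assert apply_missing_filter(gm, 0.6).n_loci == 1  # 3/5 kept at ==
        assert apply_missing_filter(gm, 0.8).n_loci == 0

    def test_r0_identity(self):
        gm = self._matrix_presence_3_of_5()
        out = apply_missing_filter(gm, 0.0)
        assert out is gm

    def test_random_fixture_against_recount(self):
        r = np.random.default_rng(42)
        calls = []
        for _ in range(20):
            row = []
            for _ in range(50):
                if r.random() < 0.3:
                    row.append(None)
                else:
                    row.append((str(r.integers(1, 4)), str(r.integers(1, 4))))
            calls.append(row)
        gm = make_matrix(calls)
        out = apply_missing_filter(gm, 0.8)
        # independent recount straight off the nested lists
        expected = [
            f"L{l + 1}"
            for l in range(50)
            if sum(calls[i][l] is not None for i in range(20)) >= 0.8 * 20
        ]
        assert [l.locus_id for l in out.loci] == expected

    @settings(max_examples=25, deadline=None)
    @given(genotype_matrices())
    def test_idempotent(self, gm):
        once = apply_missing_filter(gm, 0.8)
        twice = apply_missing_filter(once, 0.8)
        assert [l.locus_id for l in twice.loci] == [
            l.locus_id for l in once.loci
        ]
        assert np.array_equal(twice.calls, once.calls)

    @settings(max_examples=25, deadline=None)
    @given(genotype_matrices())
    def test_never_invents_alleles(self, gm):
        before = {l.locus_id: set(l.allele_labels) for l in gm.loci}
        out = apply_missing_filter(gm, 0.5)
        for locus in out.loci:
            assert set(locus.allele_labels) <= before[locus.locus_id]

    @pytest.mark.parametrize("r", [-0.1, 1.5])
    def test_r_out_of_range(self, r):
        gm = self._matrix_presence_3_of_5()
        with pytest.raises(ValueError):
            apply_missing_filter(gm, r)


class TestSubsetShared:
    def test_intersection(self):
        a = make_matrix([[("1", "1")]] * 3, individuals=["a", "b", "c"])
        b = make_matrix([[("2", "2")]] * 3, individuals=["b", "c", "d"])
        oa, ob = subset_shared(a, b)
        assert oa.individuals == ["b", "c"]
        assert ob.individuals == ["b", "c"]

    def test_identity_on_equal_sets(self):
        a = make_matrix([[("1", "1")]] * 2, individuals=["x", "y"])
        b = make_matrix([[("2", "2")]] * 2, individuals=["x", "y"])
        oa, _ = subset_shared(a, b)
        assert oa.individuals == ["x", "y"]

    def test_toy_study_scale(self):
        # 5 shared of 7 vs 9, verified by set enumeration
        ids_a = [f"s{i}" for i in range(7)]
        ids_b = [f"s{i}" for i in range(2, 11)]
        a = make_matrix([[("1", "1")]] * 7, individuals=ids_a)
        b = make_matrix([[("2", "2")]] * 9, individuals=ids_b)
        oa, ob = subset_shared(a, b)
        expected = [s for s in ids_a if s in set(ids_b)]
        assert oa.individuals == expected
        assert len(expected) == 5

    def test_normalization_case_and_space(self):
        a = make_matrix([[("1", "1")]] * 2, individuals=["Abc ", "zz"])
        b = make_matrix([[("2", "2")]] * 2, individuals=["abc", "q"])
        oa, ob = subset_shared(a, b)
        assert oa.individuals == ["Abc "]
        assert ob.individuals == ["abc"]

    def test_empty_intersection_errors(self):
        a = make_matrix([[("1", "1")]], individuals=["a"])
        b = make_matrix([[("2", "2")]], individuals=["b"])
        with pytest.raises(ValueError, match="no shared"):
            subset_shared(a, b)


class TestDropSamples:
    def test_private_allele_disappears(self):
        gm = make_matrix(
            [[("1", "1")], [("1", "2")], [("1", "1")], [("3", "3")]],
            individuals=["a", "b", "c", "d"],
        )
        part = SamplePartition(
            origin={s: "wild" for s in "abcd"}, excluded={"d"}
        )
        out = drop_samples(gm, part)
        assert out.individuals == ["a", "b", "c"]
        assert set(out.loci[0].allele_labels) == {"1", "2"}

    def test_empty_exclusion_identity(self):
        gm = make_matrix([[("1", "1")]], individuals=["a"])
        part = SamplePartition(origin={"a": "wild"})
        assert drop_samples(gm, part) is gm

    def test_six_of_97(self):
        ids = [f"w{i}" for i in range(97)]
        gm = make_matrix([[("1", "2")]] * 97, individuals=ids)
        part = SamplePartition(
            origin={s: "wild" for s in ids}, excluded=set(ids[:6])
        )
        assert drop_samples(gm, part).n_individuals == 91

    def test_unknown_ids_warn_not_fail(self):
        gm = make_matrix([[("1", "1")]], individuals=["a"])
        part = SamplePartition(origin={"a": "wild"}, excluded={"ghost"})
        with pytest.warns(UserWarning, match="ghost"):
            out = drop_samples(gm, part)
        assert out.individuals == ["a"]


class TestMetadata:
    def test_round_trip(self, tmp_path):
        part = SamplePartition(
            origin={"a": "wild", "b": "garden", "c": "wild"},
            wild_population={"a": "p1", "c": "p2"},
            excluded={"c"},
        )
        path = tmp_path / "meta.tsv"
        write_metadata(part, path, ["a", "b", "c"])
        back = read_metadata(path)
        assert back.origin == part.origin
        assert back.wild_population == part.wild_population
        assert back.excluded == part.excluded

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text("sample_id\tfoo\na\t1\n")
        with pytest.raises(GenotypeFormatError, match="origin"):
            read_metadata(path)


class TestInvariants:
    def test_half_called_cells_rejected(self):
        calls = np.array([[[0, -1]]], dtype=np.int32)
        with pytest.raises(ValueError, match="half-called"):
            GenotypeMatrix(["a"], [Locus("L1", ("x",))], calls)

    @settings(max_examples=20, deadline=None)
    @given(genotype_matrices())
    def test_labels_match_calls_after_subsets(self, gm):
        half = gm.subset_individuals(gm.individuals[: max(1, gm.n_individuals // 2)])
        for l, locus in enumerate(half.loci):
            col = half.calls[:, l, :]
            obs = {locus.allele_labels[i] for i in col[col >= 0]}
            assert obs == set(locus.allele_labels)
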