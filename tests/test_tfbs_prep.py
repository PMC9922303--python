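"""Interval arithmetic, MAF extraction, filters, and group construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import groupacc as ga
from groupacc.tfbs_prep import (
    FastaDirSource,
    GenomicInterval,
    MafSource,
    TFBSGroup,
    concatenate_group,
    count_informative_sites,
    define_composite_groups,
    exclude_regions,
    extract_element_alignment,
    filter_elements,
    read_bed,
    remove_multigroup_overlaps,
)


def brute_force_covered_bases(interval_lists, k, span=200):
    """Per-base oracle: bases covered by >= k of the factors' merged peaks."""
    counts = np.zeros(span, dtype=int)
    for ivs in interval_lists:
        cov = np.zeros(span, dtype=bool)
        for s, e in ivs:
            cov[s:e] = True
        counts += cov
    return counts >= k


class TestReadBed:
    def test_basic_interval(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t300\tFOXP2\n")
        ivs = read_bed(p)
        assert len(ivs) == 1
        assert ivs[0].length == 200
        assert ivs[0].name == "FOXP2"

    def test_inverted_coordinates_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t300\nchr1\t300\t100\n")
        with pytest.raises(ValueError, match=":2"):
            read_bed(p)

    def test_non_numeric_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\txx\t300\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_bed(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert read_bed(p) == []


class TestExcludeRegions:
    def test_one_bp_overlap_drops(self):
        iv = [GenomicInterval("chr1", 100, 300)]
        ex = [GenomicInterval("chr1", 299, 400)]
        assert exclude_regions(iv, ex) == []

    def test_abutting_intervals_kept(self):
        iv = [GenomicInterval("chr1", 100, 300)]
        ex = [GenomicInterval("chr1", 300, 400)]
        assert exclude_regions(iv, ex) == iv

    def test_no_exclusions_is_identity(self):
        iv = [GenomicInterval("chr1", 1, 2), GenomicInterval("chr2", 5, 9)]
        assert exclude_regions(iv, []) == iv

    def test_different_chromosome_kept(self):
        iv = [GenomicInterval("chr1", 100, 300)]
        ex = [GenomicInterval("chr2", 100, 300)]
        assert exclude_regions(iv, ex) == iv


TOY_MAF = """\
##maf version=1
a score=0
s hg.chr1 0 10 + 1000 ACGTACGTAC
s pt.chr1 0 10 + 1000 ACGTACCTAC
s gg.chr1 0 10 + 1000 ACCTACGTAC

a score=0
s hg.chr1 10 8 + 1000 AC--GTACGT
s pt.chr1 10 8 + 1000 ACTTGTACGT

a score=0
s hg.chr1 30 5 + 1000 CCCCC
s gg.chr1 40 5 + 1000 CCCCC
"""


class TestMafExtraction:
    @pytest.fixture
    def source(self, tmp_path):
        p = tmp_path / "toy.maf"
        p.write_text(TOY_MAF)
        return MafSource(p, ref_species="hg", taxa=["hg", "pt", "gg"])

    def test_extraction_inside_one_block(self, source):
        aln = extract_element_alignment(
            source, GenomicInterval("chr1", 2, 6)
        )
        assert aln.n_columns == 4
        assert aln.sequences["hg"] == "GTAC"
        assert aln.sequences["pt"] == "GTAC"
        assert aln.sequences["gg"] == "CTAC"

    def test_reference_gap_columns_dropped(self, source):
        aln = extract_element_alignment(
            source, GenomicInterval("chr1", 10, 18)
        )
        assert aln.n_columns == 8  # 10 MAF columns minus 2 reference gaps
        assert aln.sequences["hg"] == "ACGTACGT"
        assert aln.sequences["pt"] == "ACGTACGT"

    def test_missing_species_becomes_missing_data(self, source):
        aln = extract_element_alignment(
            source, GenomicInterval("chr1", 10, 14)
        )
        assert set(aln.sequences["gg"]) == {"N"}

    def test_interval_spanning_two_blocks(self, source):
        """Columns concatenate in reference order across blocks; matches a
        per-position lookup oracle."""
        aln = extract_element_alignment(
            source, GenomicInterval("chr1", 8, 12)
        )
        assert aln.sequences["hg"] == "ACAC"
        # per-position oracle from the raw MAF text
        assert aln.sequences["pt"] == "ACAC"
        assert aln.sequences["gg"] == "ACNN"

    def test_uncovered_interval_rejected(self, source):
        with pytest.raises(ValueError):
            extract_element_alignment(
                source, GenomicInterval("chr1", 500, 600)
            )


class TestFastaDirSource:
    def test_round_trip(self, tmp_path):
        (tmp_path / "chr1_5-8.fa").write_text(">human\nACG\n>chimp\nACT\n")
        src = FastaDirSource(tmp_path)
        aln = src.extract(GenomicInterval("chr1", 5, 8))
        assert aln.sequences == {"human": "ACG", "chimp": "ACT"}


class TestInformativeSites:
    def test_boundary_exactly_five_of_ten(self):
        taxa = [f"t{i}" for i in range(10)]
        col_five = ["A"] * 5 + ["N"] * 5
        col_four = ["A"] * 4 + ["-"] * 6
        aln = ga.Alignment(
            {t: col_five[i] + col_four[i] for i, t in enumerate(taxa)}
        )
        assert count_informative_sites(aln, min_species=5) == 1

    def test_all_gap_alignment_is_zero(self):
        aln = ga.Alignment({"a": "---", "b": "---"})
        assert count_informative_sites(aln, min_species=1) == 0

    def test_ambiguity_codes_not_informative(self):
        aln = ga.Alignment({"a": "R", "b": "A"})
        assert count_informative_sites(aln, min_species=2) == 0
        assert count_informative_sites(aln, min_species=1) == 1


class TestFilterElements:
    def _group(self, n_informative):
        iv = GenomicInterval("chr1", 0, n_informative, "g")
        seq = "A" * n_informative
        g = TFBSGroup(name="g", intervals=[iv])
        g.alignments[iv.element_id] = ga.Alignment(
            {"human": seq, "chimp": seq, "gorilla": seq,
             "orangutan": seq, "macaque": seq}
        )
        return g

    def test_boundary_at_fifty(self):
        kept_49 = filter_elements([self._group(49)], min_informative=50)
        kept_50 = filter_elements([self._group(50)], min_informative=50)
        assert len(kept_49[0].intervals) == 0
        assert len(kept_50[0].intervals) == 1

    def test_zero_threshold_is_identity(self):
        kept = filter_elements([self._group(10)], min_informative=0)
        assert len(kept[0].intervals) == 1


class TestCompositeGroups:
    def test_two_of_three_rule(self):
        factors = {
            "BDP1": [GenomicInterval("chr1", 100, 200)],
            "BRF1": [GenomicInterval("chr1", 150, 250)],
            "POLR3G": [GenomicInterval("chr1", 400, 500)],
        }
        comp, pruned = define_composite_groups(
            factors, rule="k_of_n", factors=["BDP1", "BRF1", "POLR3G"],
            k=2, name="PolIII",
        )
        assert [(c.start, c.end) for c in comp.intervals] == [(150, 200)]
        # overlapping source peaks are removed, the lone POLR3G peak stays
        assert pruned["BDP1"] == []
        assert pruned["BRF1"] == []
        assert len(pruned["POLR3G"]) == 1

    def test_intersection_rule(self):
        factors = {
            "POU5F1": [GenomicInterval("chr1", 100, 300)],
            "NANOG": [GenomicInterval("chr1", 200, 400)],
        }
        comp, _ = define_composite_groups(
            factors, rule="intersection", factors=["POU5F1", "NANOG"]
        )
        assert [(c.start, c.end) for c in comp.intervals] == [(200, 300)]

    def test_unknown_factor_rejected(self):
        with pytest.raises(ValueError, match="unknown factors"):
            define_composite_groups(
                {"A": []}, rule="k_of_n", factors=["A", "B"], k=2
            )

    @given(
        st.lists(
            st.lists(
                st.tuples(st.integers(0, 190), st.integers(1, 60)),
                min_size=0, max_size=5,
            ),
            min_size=2, max_size=4,
        ),
        st.integers(1, 3),
    )
    @settings(max_examples=60, deadline=None)
    def test_k_of_n_matches_per_base_oracle(self, raw_lists, k):
        interval_lists = [
            [(s, min(s + w, 200)) for s, w in ivs] for ivs in raw_lists
        ]
        factors = {
            f"F{i}": [GenomicInterval("chrX", s, e) for s, e in ivs]
            for i, ivs in enumerate(interval_lists)
        }
        comp, _ = define_composite_groups(
            factors, rule="k_of_n", factors=list(factors), k=k
        )
        got = np.zeros(200, dtype=bool)
        for iv in comp.intervals:
            got[iv.start : iv.end] = True
        expected = brute_force_covered_bases(interval_lists, k)
        np.testing.assert_array_equal(got, expected)


class TestRemoveMultigroupOverlaps:
    def test_cross_group_overlap_removes_both(self):
        g1 = TFBSGroup("X", intervals=[GenomicInterval("chr1", 100, 200)])
        g2 = TFBSGroup("Y", intervals=[GenomicInterval("chr1", 150, 250)])
        out = remove_multigroup_overlaps([g1, g2])
        assert out[0].intervals == [] and out[1].intervals == []

    def test_within_group_overlap_untouched(self):
        g = TFBSGroup(
            "X",
            intervals=[
                GenomicInterval("chr1", 100, 200),
                GenomicInterval("chr1", 150, 250),
            ],
        )
        out = remove_multigroup_overlaps([g])
        assert len(out[0].intervals) == 2

    def test_disjoint_groups_identity(self):
        g1 = TFBSGroup("X", intervals=[GenomicInterval("chr1", 0, 10)])
        g2 = TFBSGroup("Y", intervals=[GenomicInterval("chr1", 10, 20)])
        out = remove_multigroup_overlaps([g1, g2])
        assert len(out[0].intervals) == 1 and len(out[1].intervals) == 1


class TestConcatenateGroup:
    def test_columns_add_up(self):
        ivs = [GenomicInterval("chr1", i * 10, i * 10 + 5) for i in range(3)]
        g = TFBSGroup("g", intervals=ivs)
        for iv in ivs:
            g.alignments[iv.element_id] = ga.Alignment(
                {"a": "ACGTA", "b": "ACGTT"}
            )
        assert concatenate_group(g).n_columns == 15

    def test_taxon_mismatch_rejected(self):
        ivs = [GenomicInterval("chr1", 0, 2), GenomicInterval("chr1", 5, 7)]
        g = TFBSGroup("g", intervals=ivs)
        g.alignments[ivs[0].element_id] = ga.Alignment({"a": "AC", "b": "AC"})
        g.alignments[ivs[1].element_id] = ga.Alignment({"a": "AC", "c": "AC"})
        with pytest.raises(Exception):
            concatenate_group(g)

    def test_concatenation_loglik_is_sum_of_elements(self):
        tree = ga.parse_newick("((A:0.1,B:0.2):0.05,C:0.3);")
        gtr = ga.GTRParams((1.0,) * 6, (0.25,) * 4)
        rates = ga.discretize_gamma(1.0, 4)
        a1 = ga.Alignment({"A": "ACG", "B": "ACT", "C": "GCG"})
        a2 = ga.Alignment({"A": "TT", "B": "TA", "C": "CT"})
        both = ga.Alignment.concatenate([a1, a2])
        ll = ga.alignment_log_likelihood(both, tree, gtr, rates)
        ll_sum = sum(
            ga.alignment_log_likelihood(a, tree, gtr, rates) for a in (a1, a2)
        )
        assert abs(ll - ll_sum) < 1e-9


class TestIntervalProperties:
    @given(
        st.integers(0, 100), st.integers(1, 50),
        st.integers(0, 100), st.integers(1, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_overlap_matches_per_base_oracle(self, s1, w1, s2, w2):
        a = GenomicInterval("c", s1, s1 + w1)
        b = GenomicInterval("c", s2, s2 + w2)
        bases_a = set(range(a.start, a.end))
        bases_b = set(range(b.start, b.end))
        assert a.overlaps(b) == bool(bases_a & bases_b)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
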