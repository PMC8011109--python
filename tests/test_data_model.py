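"""Annotation I/O, region extraction, one-hot encoding, logit transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsplice.data_model import (
    CassetteExon,
    RegionSet,
    chromosome_split,
    delta_tissue_logit,
    encode,
    extract_regions,
    load_exons,
    load_psi_table,
    logit,
    reverse_complement,
    sigmoid,
    tissue_average,
)


class TestLoadExons:
    def test_gtf_coordinates_converted_to_zero_based(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\tsrc\texon\t1001\t1100\t.\t+\t.\tgene_id "g1"; exon_id "e1";\n'
        )
        (exon,) = load_exons(gtf, format="gtf")
        assert (exon.start, exon.end) == (1000, 1100)
        assert exon.length == 100
        assert exon.gene_id == "g1"

    def test_tsv_coordinates_used_verbatim(self, tmp_path):
        tsv = tmp_path / "a.tsv"
        tsv.write_text(
            "exon_id\tchrom\tstart\tend\tstrand\tgene_id\ne1\tchr1\t1000\t1100\t+\tg1\n"
        )
        (exon,) = load_exons(tsv, format="tsv")
        assert (exon.start, exon.end) == (1000, 1100)

    def test_duplicate_exon_ids_rejected(self, tmp_path):
        tsv = tmp_path / "a.tsv"
        tsv.write_text(
            "exon_id\tchrom\tstart\tend\tstrand\tgene_id\n"
            "e1\tchr1\t0\t10\t+\tg1\ne1\tchr1\t20\t30\t+\tg1\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            load_exons(tsv, format="tsv")

    def test_malformed_gtf_line_names_line_number(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text("chr1\tsrc\texon\t1\t100\n")
        with pytest.raises(ValueError, match=":1:"):
            load_exons(gtf, format="gtf")

    def test_unknown_strand_rejected(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text('chr1\tsrc\texon\t1\t100\t.\t*\t.\texon_id "e1";\n')
        with pytest.raises(ValueError, match="strand"):
            load_exons(gtf, format="gtf")


class TestExtractRegions:
    def test_plus_strand_intervals(self, toy_genome, plus_exon):
        regions = extract_regions(plus_exon, toy_genome)
        g = toy_genome["chr1"]
        assert regions.upstream_intron == g[700:1000]
        assert regions.exon_start == g[1000:1100]
        assert regions.exon_end == g[1100:1200]
        assert regions.downstream_intron == g[1200:1500]

    def test_minus_strand_is_mirror_reverse_complement(self, toy_genome, minus_exon):
        regions = extract_regions(minus_exon, toy_genome)
        g = toy_genome["chr1"]
        assert regions.upstream_intron == reverse_complement(g[1200:1500])
        assert regions.exon_start == reverse_complement(g[1100:1200])
        assert regions.exon_end == reverse_complement(g[1000:1100])
        assert regions.downstream_intron == reverse_complement(g[700:1000])

    def test_truncation_at_chromosome_start(self, toy_genome):
        exon = CassetteExon("e", "chr1", 50, 160, "+", "g")
        regions = extract_regions(exon, toy_genome)
        assert len(regions.upstream_intron) == 50
        assert regions.upstream_intron == toy_genome["chr1"][:50]

    def test_missing_chromosome_raises(self, toy_genome, plus_exon):
        exon = CassetteExon("e", "chrZ", 1000, 1200, "+", "g")
        with pytest.raises(KeyError, match="chrZ"):
            extract_regions(exon, toy_genome)

    def test_short_exon_regions_overlap(self, toy_genome):
        exon = CassetteExon("e", "chr1", 1000, 1120, "+", "g")  # 120 nt body
        regions = extract_regions(exon, toy_genome)
        assert len(regions.exon_start) == 100
        assert len(regions.exon_end) == 100
        assert regions.exon_start[20:] == regions.exon_end[:80]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_strand_mirror_property(self, seed):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        genome = {"c": "".join(bases[rng.integers(0, 4, size=1200)])}
        start = int(rng.integers(320, 500))
        end = start + int(rng.integers(50, 300))
        plus = extract_regions(CassetteExon("p", "c", start, end, "+", "g"), genome)
        minus = extract_regions(CassetteExon("m", "c", start, end, "-", "g"), genome)
        # the minus-strand extraction reads the mirror-image intervals
        assert minus.upstream_intron == reverse_complement(
            genome["c"][end : end + 300]
        )
        assert minus.exon_end == reverse_complement(plus.exon_start)
        assert minus.downstream_intron == reverse_complement(
            genome["c"][max(0, start - 300) : start]
        )


class TestEncode:
    def test_one_hot_unit_vectors(self):
        regions = RegionSet("ACGT", "A", "C", "G")
        enc = encode(regions)
        # "ACGT" right-aligned into rows 296-299 of the acceptor branch
        np.testing.assert_array_equal(enc.acceptor_branch[296:300], np.eye(4))

    def test_n_is_zero_row(self):
        regions = RegionSet("N", "A", "C", "G")
        enc = encode(regions)
        assert enc.acceptor_branch[299].sum() == 0

    def test_short_exon_padding(self):
        regions = RegionSet("A" * 300, "C" * 60, "G" * 60, "T" * 300)
        enc = encode(regions)
        # exon_start rows 60-99 (acceptor branch rows 360-399) are padding
        assert enc.acceptor_branch[360:400].sum() == 0
        assert enc.acceptor_branch[300:360].sum() == 60
        # exon_end right-aligned to the donor: rows 0-39 of the donor branch pad
        assert enc.donor_branch[:40].sum() == 0

    def test_row_sums_zero_or_one(self, toy_genome, plus_exon):
        enc = encode(extract_regions(plus_exon, toy_genome))
        for branch in (enc.acceptor_branch, enc.donor_branch):
            sums = branch.sum(axis=1)
            assert set(np.unique(sums)) <= {0.0, 1.0}


class TestPsiTable:
    def test_values_and_missing(self, tmp_path):
        path = tmp_path / "psi.tsv"
        path.write_text("exon_id\tbrain\tliver\ne1\t0.5\tNA\ne2\t0.1\t0.9\n")
        psi = load_psi_table(path)
        assert psi.psi[0, 0] == 0.5
        assert psi.mask[0, 1] == False  # noqa: E712
        assert np.isnan(psi.psi[0, 1])

    def test_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "psi.tsv"
        path.write_text("exon_id\tbrain\ne1\t1.5\n")
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            load_psi_table(path)

    def test_non_numeric_rejected(self, tmp_path):
        path = tmp_path / "psi.tsv"
        path.write_text("exon_id\tbrain\tliver\ne1\toops\t0.5\n")
        with pytest.raises(ValueError, match="non-numeric"):
            load_psi_table(path)


class TestLogitQuantities:
    def test_tissue_average_excludes_missing(self):
        assert tissue_average([0.2, np.nan, 0.8]) == pytest.approx(0.5)
        assert tissue_average([0.2, 0.8]) == pytest.approx(0.5)
        with pytest.raises(ValueError, match="no observed"):
            tissue_average([np.nan, np.nan])

    def test_delta_tissue_logit_identity_and_clipping(self):
        assert delta_tissue_logit(0.5, 0.5) == 0.0
        # logit(1-1e-5) - logit(0.5) = ln(99999)
        assert delta_tissue_logit(1.0, 0.5) == pytest.approx(11.512915464920228, abs=1e-9)
        assert delta_tissue_logit(0.7311, 0.5) == pytest.approx(1.0002106860244513, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            delta_tissue_logit(1.2, 0.5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(1e-5, 1 - 1e-5))
    def test_sigmoid_logit_round_trip(self, p):
        assert abs(sigmoid(logit(p)) - p) < 1e-12


class TestChromosomeSplit:
    def test_assignments(self):
        mk = lambda c: CassetteExon(f"e_{c}", c, 0, 10, "+", "g")
        split = chromosome_split([mk("chr2"), mk("chrX"), mk("chr7"), mk("chr4"), mk("1")])
        assert [e.chrom for e in split["test"]] == ["chr2"]
        assert [e.chrom for e in split["val"]] == ["chr7", "1"]
        assert {e.chrom for e in split["train"]} == {"chrX", "chr4"}

    def test_scaffold_routed_to_train_with_warning(self):
        exon = CassetteExon("e", "scaffold_12", 0, 10, "+", "g")
        with pytest.warns(UserWarning, match="unrecognized"):
            split = chromosome_split([exon])
        assert split["train"] == [exon]

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]), max_size=30))
    def test_partition_is_exhaustive_and_disjoint(self, chroms):
        exons = [CassetteExon(f"e{i}", c, 0, 10, "+", "g") for i, c in enumerate(chroms)]
        split = chromosome_split(exons)
        combined = split["train"] + split["val"] + split["test"]
        assert sorted(e.exon_id for e in combined) == sorted(e.exon_id for e in exons)
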