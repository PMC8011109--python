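"""Variant substitution, the logit-scale effect combination, cohort ΔΨ,
benchmark filtering and variant→exon mapping."""

import numpy as np
import pandas as pd
import pytest

from tsplice.data_model import CassetteExon, RegionSet, extract_regions, sigmoid
from tsplice.network import TSpliceConfig, build_network
from tsplice.variant_effect import (
    CohortPsi,
    PrecomputedScorer,
    VariantRecord,
    ZeroScorer,
    apply_variant,
    benchmark_filter,
    estimate_cohort_delta_psi,
    map_variants_to_exons,
    predict_variant_effect,
    read_vcf,
)


def _variant_at(genome, pos0, alt=None):
    ref = genome["chr1"][pos0]
    if alt is None:
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref]
    return VariantRecord("chr1", pos0 + 1, ref, alt, f"v{pos0}")


class TestApplyVariant:
    def test_plus_strand_upstream_substitution(self, toy_genome, plus_exon):
        v = _variant_at(toy_genome, 950)  # 50 nt upstream of the acceptor
        applied = apply_variant(plus_exon, v, toy_genome)
        assert applied.modeled
        ref, alt = applied.ref, applied.alt
        diffs = [i for i, (a, b) in enumerate(zip(ref.upstream_intron, alt.upstream_intron)) if a != b]
        assert diffs == [250]
        assert alt.upstream_intron[250] == v.alt
        assert (ref.exon_start, ref.exon_end, ref.downstream_intron) == (
            alt.exon_start,
            alt.exon_end,
            alt.downstream_intron,
        )

    def test_minus_strand_substitutes_complement(self, toy_genome, minus_exon):
        v = _variant_at(toy_genome, 1250)  # 50 nt upstream of the minus-strand acceptor
        applied = apply_variant(minus_exon, v, toy_genome)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        diffs = [
            i
            for i, (a, b) in enumerate(
                zip(applied.ref.upstream_intron, applied.alt.upstream_intron)
            )
            if a != b
        ]
        assert diffs == [249]  # mirror position of offset 50 in a 300-nt window
        assert applied.alt.upstream_intron[249] == comp[v.alt]

    def test_deep_exon_interior_unmodeled(self, toy_genome):
        exon = CassetteExon("big", "chr1", 600, 1000, "+", "g")  # 400-nt body
        v = _variant_at(toy_genome, 750)  # position 150 inside the body
        applied = apply_variant(exon, v, toy_genome)
        assert not applied.modeled
        assert applied.ref == applied.alt

    def test_short_exon_variant_hits_both_exon_regions(self, toy_genome):
        exon = CassetteExon("short", "chr1", 1000, 1120, "+", "g")  # 120-nt body
        v = _variant_at(toy_genome, 1050)  # inside both first-100 and last-100
        applied = apply_variant(exon, v, toy_genome)
        assert applied.ref.exon_start != applied.alt.exon_start
        assert applied.ref.exon_end != applied.alt.exon_end

    def test_reference_mismatch_names_position(self, toy_genome, plus_exon):
        base = toy_genome["chr1"][950]
        wrong = {"A": "C", "C": "G", "G": "T", "T": "A"}[base]
        other = {"A": "G", "C": "T", "G": "A", "T": "C"}[base]
        v = VariantRecord("chr1", 951, wrong, other, "bad")
        with pytest.raises(ValueError, match="951"):
            apply_variant(plus_exon, v, toy_genome)

    def test_outside_window_rejected(self, toy_genome, plus_exon):
        v = _variant_at(toy_genome, 1501)  # 301 nt beyond the donor
        with pytest.raises(ValueError, match="window"):
            apply_variant(plus_exon, v, toy_genome)


class TestPredictVariantEffect:
    def _net(self, zero_head=False):
        net = build_network(TSpliceConfig(seed=0, n_tissues=5))
        if zero_head:
            net.w2 = np.zeros_like(net.w2)
            net.b2 = np.zeros_like(net.b2)
        return net

    def _regions(self, toy_genome, plus_exon):
        return extract_regions(plus_exon, toy_genome)

    def test_null_variant_gives_zero_delta_psi(self, toy_genome, plus_exon):
        regions = self._regions(toy_genome, plus_exon)
        for mode in ("mtsplice", "mmsplice_only"):
            res = predict_variant_effect(
                ZeroScorer(), self._net(), regions, regions, 0.4, mode=mode
            )
            np.testing.assert_allclose(res.delta_psi, 0.0, atol=1e-12)

    def test_zero_tissue_network_reduces_to_tissue_agnostic(self, toy_genome, plus_exon):
        regions = self._regions(toy_genome, plus_exon)
        alt = regions.replace(upstream_intron="A" * 300)
        net = self._net(zero_head=True)
        scorer = PrecomputedScorer({"v": -0.8})
        v = VariantRecord("chr1", 1, "A", "G", "v")
        psi_ref = np.array([0.3, 0.5, np.nan, 0.7, 0.2])
        res_mt = predict_variant_effect(
            scorer, net, regions, alt, 0.5, "mtsplice", psi_ref, variant=v
        )
        res_mm = predict_variant_effect(
            scorer, net, regions, alt, 0.5, "mmsplice_only", psi_ref, variant=v
        )
        np.testing.assert_array_equal(res_mt.delta_psi, res_mm.delta_psi)
        assert list(res_mt.psi_ref_source) == ["measured", "measured", "predicted", "measured", "measured"]

    def test_unit_scorer_closed_form(self, toy_genome, plus_exon):
        regions = self._regions(toy_genome, plus_exon)
        alt = regions.replace(upstream_intron="A" * 300)
        net = self._net(zero_head=True)
        scorer = PrecomputedScorer({"v": 1.0})
        v = VariantRecord("chr1", 1, "A", "G", "v")
        res = predict_variant_effect(
            scorer, net, regions, alt, 0.5, "mtsplice", np.full(5, 0.5), variant=v
        )
        np.testing.assert_allclose(res.delta_psi, 0.2310585786300049, atol=1e-9)

    def test_beta_decomposition(self, toy_genome, plus_exon):
        regions = self._regions(toy_genome, plus_exon)
        alt = regions.replace(upstream_intron="A" * 300)
        net = self._net()
        res = predict_variant_effect(ZeroScorer(), net, regions, alt, 0.5)
        from tsplice.data_model import encode

        np.testing.assert_allclose(
            res.beta_alt_x_tissue,
            net.forward(encode(alt)) - net.forward(encode(regions)),
            atol=1e-12,
        )
        assert np.abs(res.delta_psi).max() <= 1.0

    def test_monotone_in_scorer_output(self, toy_genome, plus_exon):
        regions = self._regions(toy_genome, plus_exon)
        alt = regions.replace(upstream_intron="A" * 300)
        net = self._net()
        v = VariantRecord("chr1", 1, "A", "G", "v")
        deltas = []
        for s in (-1.0, 0.0, 1.0):
            res = predict_variant_effect(
                PrecomputedScorer({"v": s}), net, regions, alt, 0.5, variant=v
            )
            deltas.append(res.delta_psi)
        assert (np.diff(np.stack(deltas), axis=0) > 0).all()


class TestCohortEstimator:
    def test_mean_difference(self):
        c = CohortPsi([0.8, 0.6, 0.2, 0.4], [0, 0, 2, 2])
        assert estimate_cohort_delta_psi(c) == pytest.approx(-0.4)

    def test_min_group_size(self):
        c = CohortPsi([0.8, 0.2, 0.4], [0, 2, 2])
        assert estimate_cohort_delta_psi(c) is None

    def test_heterozygotes_excluded(self):
        c = CohortPsi([0.5, 0.5, 0.1, 0.1, 0.1, 0.5, 0.5], [0, 0, 1, 1, 1, 2, 2])
        assert estimate_cohort_delta_psi(c) == pytest.approx(0.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        psi = rng.uniform(0, 1, 12)
        gt = np.array([0, 0, 0, 1, 1, 2, 2, 2, 0, 1, 2, 0])
        ref = estimate_cohort_delta_psi(CohortPsi(psi, gt))
        perm = rng.permutation(12)
        assert estimate_cohort_delta_psi(CohortPsi(psi[perm], gt[perm])) == pytest.approx(ref)


class TestBenchmarkFilter:
    def test_deviation_exactly_at_threshold_dropped(self):
        df = pd.DataFrame([[0.0, 0.0, 0.3]], index=["v1"], columns=list("abc"))
        kept, _ = benchmark_filter(df, min_variants_per_tissue=0)
        assert len(kept) == 0  # max deviation is exactly 0.2, not > 0.2

    def test_deviation_above_threshold_kept(self):
        df = pd.DataFrame([[0.0, 0.0, 0.6]], index=["v1"], columns=list("abc"))
        kept, _ = benchmark_filter(df, min_variants_per_tissue=0)
        assert list(kept.index) == ["v1"]

    def test_min_defined_tissues(self):
        df = pd.DataFrame([[0.0, np.nan, 0.6]], index=["v1"], columns=list("abc"))
        kept, _ = benchmark_filter(df, min_variants_per_tissue=0)
        assert len(kept) == 0

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 0.25, size=(20, 5))
        values[rng.random((20, 5)) < 0.2] = np.nan
        df = pd.DataFrame(values, index=[f"v{i}" for i in range(20)], columns=list("ABCDE"))

        # brute-force: per-variant rule evaluated cell by cell in pure python
        surviving = []
        for vid, row in df.iterrows():
            defined = row.dropna()
            if len(defined) < 3:
                continue
            mean = defined.mean()
            if max(abs(x - mean) for x in defined) > 0.2:
                surviving.append(vid)
        tissue_counts = df.loc[surviving].notna().sum(axis=0)
        expected_tissues = [t for t in df.columns if tissue_counts[t] > 2]

        kept, tissues = benchmark_filter(df, min_variants_per_tissue=2)
        assert sorted(kept.index) == sorted(surviving)
        assert tissues == expected_tissues

    def test_per_cell_mode(self):
        df = pd.DataFrame(
            [[0.0, 0.0, 0.45], [0.0, 0.0, 0.45], [0.1, 0.1, 0.1]],
            index=["v1", "v2", "v3"],
            columns=list("abc"),
        )
        kept, tissues = benchmark_filter(df, mode="per_cell", min_variants_per_tissue=2)
        assert tissues == ["c"]
        assert sorted(kept.index) == ["v1", "v2"]


class TestMapVariantsToExons:
    def _setup(self):
        exons = [
            CassetteExon("e1", "chr1", 1000, 1200, "+", "gA"),
            CassetteExon("e2", "chr1", 1300, 1500, "+", "gB"),
        ]
        v = VariantRecord("chr1", 1250, "A", "G", "v1")  # within ±300 of both
        return exons, v

    def test_largest_magnitude_sign_preserved(self):
        exons, v = self._setup()
        df = map_variants_to_exons([v], exons, {("v1", "e1"): 0.02, ("v1", "e2"): -0.07})
        assert df.loc[0, "score"] == -0.07
        assert df.loc[0, "exon_id"] == "e2"

    def test_threshold_filter(self):
        exons, v = self._setup()
        scores = {("v1", "e1"): 0.02, ("v1", "e2"): -0.07}
        assert len(map_variants_to_exons([v], exons, scores, threshold=0.05)) == 1
        weak = {("v1", "e1"): 0.02, ("v1", "e2"): 0.01}
        assert len(map_variants_to_exons([v], exons, weak, threshold=0.05)) == 0

    def test_window_boundary(self):
        exons = [CassetteExon("e1", "chr1", 1000, 1200, "+", "gA")]
        v = VariantRecord("chr1", 1501, "A", "G", "far")  # 301 nt past the donor
        df = map_variants_to_exons([v], exons, {})
        assert len(df) == 0
        assert df.attrs["n_unmapped"] == 1

    def test_loeuf_grouping(self):
        exons, v = self._setup()
        df = map_variants_to_exons(
            [v],
            exons,
            {("v1", "e1"): 0.02, ("v1", "e2"): -0.07},
            loeuf={"gB": 0.2, "gA": 0.9},
        )
        assert bool(df.loc[0, "lof_intolerant"])


class TestVcfReading:
    def test_snvs_split_and_non_snvs_skipped(self, tmp_path):
        vcf = tmp_path / "x.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t100\tv1\tA\tG,T\t.\tPASS\t.\n"
            "chr1\t200\tv2\tAT\tA\t.\tPASS\t.\n"
        )
        variants, skipped = read_vcf(vcf)
        assert [(v.pos, v.alt) for v in variants] == [(100, "G"), (100, "T")]
        assert skipped == 1

    def test_invalid_variant_records_rejected(self):
        with pytest.raises(ValueError):
            VariantRecord("chr1", 10, "A", "A")
        with pytest.raises(ValueError):
            VariantRecord("chr1", 10, "AT", "A")
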