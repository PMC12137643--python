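import itertools

import numpy as np
import pytest

from orchardpop import array_design as ad
from orchardpop.array_design import (
    FunnelReport,
    QcThresholds,
    SnpCategory,
    annotate_effects,
    annotate_regions,
    classify_performance,
    genotype_concordance,
    integrate_legacy,
    interval_stats,
    probe_uniqueness_filter,
    qc_filter,
    render_percent,
    select_final,
    shared_variant_filter,
)
from orchardpop.datatypes import GeneAnnotation, GenotypeMatrix
import pandas as pd

from conftest import make_genotypes, make_variants


class TestQcFilter:
    def test_missing_rate_boundary_inclusive(self):
        # 10 samples; variant 0 missing in 4/10 (rate 0.4, kept);
        # variant 1 missing in 5/10 (rate 0.5, removed)
        d = np.ones((10, 2))
        d[:4, 0] = np.nan
        d[:5, 1] = np.nan
        g = make_genotypes(d)
        v = make_variants(2, qual=np.full(2, 100.0),
                          depth=np.full((10, 2), 10.0), gq=np.full((10, 2), 40.0))
        keep = qc_filter(v, g)
        assert keep.tolist() == [True, False]
        assert "qc_pass" in v.stage_flags[0]
        assert "qc_pass" not in v.stage_flags[1]

    def test_known_violations_hand_count(self):
        # 20 variants; plant failures: depth (5), gq (3), qual (2), missing (4)
        rng = np.random.default_rng(0)
        m, n = 20, 10
        d = rng.integers(0, 3, size=(n, m)).astype(float)
        depth = np.full((n, m), 10.0)
        gq = np.full((n, m), 40.0)
        qual = np.full(m, 100.0)
        depth[:, 0:5] = 1.0       # mean depth < 2
        gq[:, 5:8] = 5.0          # mean GQ < 10
        qual[8:10] = 10.0         # QUAL < 50
        d[0:5, 10:14] = np.nan    # rate 0.5 > 0.4
        g = make_genotypes(d)
        v = make_variants(m, qual=qual, depth=depth, gq=gq)
        keep = qc_filter(v, g)
        assert keep.sum() == 20 - 5 - 3 - 2 - 4

    def test_absent_metric_fails_all(self):
        g = make_genotypes(np.ones((4, 3)))
        v = make_variants(3, qual=np.full(3, 100.0))  # no depth/gq
        assert qc_filter(v, g).sum() == 0

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            QcThresholds(max_missing=1.5)


class TestSharedVariantFilter:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ([1, 0, 0, 0], False),   # singleton ALT
            ([1, 1, 0, 0], True),    # exactly 2 carriers
            ([0, 0, 0, 0], False),   # all-reference
            ([2, 0, 0, 0], False),   # one carrier, hom
            ([2, 1, 0, 0], True),
        ],
    )
    def test_carrier_rule(self, column, expected):
        g = make_genotypes(np.array(column, dtype=float)[:, None])
        v = make_variants(1)
        assert shared_variant_filter(v, g)[0] == expected


class TestProbeUniqueness:
    def test_duplicated_segment_removed_unique_kept(self):
        rng = np.random.default_rng(1)
        unique = "".join(rng.choice(list("ACGT"), size=300))
        dup = "".join(rng.choice(list("ACGT"), size=80))
        seq = unique[:100] + dup + unique[100:200] + dup + unique[200:]
        ref = {"Chr1": seq}
        # variant inside the first duplicated copy; another in unique part
        pos_dup = 100 + 40
        pos_uni = 40
        from orchardpop.datatypes import VariantTable
        v = VariantTable(
            chrom=np.array(["Chr1", "Chr1"], dtype=object),
            pos=np.array([pos_dup, pos_uni]),
            ref=np.array([seq[pos_dup], seq[pos_uni]], dtype=object),
            alt=np.array(["A" if seq[pos_dup] != "A" else "C",
                          "A" if seq[pos_uni] != "A" else "C"], dtype=object),
        )
        keep = probe_uniqueness_filter(v, ref)
        assert keep.tolist() == [False, True]

    def test_edge_variant_removed(self):
        ref = {"Chr1": "ACGT" * 50}
        from orchardpop.datatypes import VariantTable
        v = VariantTable(chrom=np.array(["Chr1"], dtype=object),
                         pos=np.array([3]), ref=np.array(["T"], dtype=object),
                         alt=np.array(["A"], dtype=object))
        assert probe_uniqueness_filter(v, ref).tolist() == [False]

    def test_neighboring_polymorphism_excludes(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        ref = {"Chr1": seq}
        from orchardpop.datatypes import VariantTable
        v = VariantTable(
            chrom=np.array(["Chr1", "Chr1"], dtype=object),
            pos=np.array([200, 210]),  # within each other's 35 bp window
            ref=np.array([seq[200], seq[210]], dtype=object),
            alt=np.array(["A" if seq[200] != "A" else "C",
                          "A" if seq[210] != "A" else "C"], dtype=object),
        )
        assert probe_uniqueness_filter(v, ref).tolist() == [False, False]
        assert probe_uniqueness_filter(
            v, ref, exclude_polymorphic_window=False
        ).tolist() == [True, True]


class TestClassifyPerformance:
    def _single(self, genos):
        col = np.array(genos, dtype=float)[:, None]
        return classify_performance(make_genotypes(col))[0]

    def test_all_classes_present_poly(self):
        assert self._single([0, 1, 2, 0]) == SnpCategory.POLY_HIGH_RESOLUTION

    def test_no_minor_hom(self):
        assert self._single([0, 0, 1, 1]) == SnpCategory.NO_MINOR_HOM

    def test_monomorphic(self):
        assert self._single([0, 0, 0, 0]) == SnpCategory.MONO_HIGH_RESOLUTION

    def test_both_homs_no_het_is_other(self):
        assert self._single([0, 0, 2, 2]) == SnpCategory.OTHER

    def test_call_rate_below_threshold(self):
        # 97 of 100 called -> call rate 0.97 < 0.975
        col = np.array([0.0, 1.0, 2.0] * 33 + [np.nan])[:, None]
        col = np.vstack([col, [[np.nan], [np.nan]]])
        g = make_genotypes(col)
        assert g.call_rate()[0] < 0.975
        assert classify_performance(g)[0] == SnpCategory.CALL_RATE_BELOW_THRESHOLD

    def test_empty_call_set_other(self):
        assert self._single([np.nan, np.nan]) == SnpCategory.OTHER

    def test_select_final_retains_two_categories(self):
        cats = [SnpCategory.POLY_HIGH_RESOLUTION, SnpCategory.MONO_HIGH_RESOLUTION,
                SnpCategory.NO_MINOR_HOM, SnpCategory.CALL_RATE_BELOW_THRESHOLD,
                SnpCategory.OTHER]
        assert select_final(cats).tolist() == [True, False, True, False, False]


class TestIntegrateLegacy:
    def test_printed_funnel_counts(self):
        final = {("c", i) for i in range(166_416)}
        legacy = [("c", i) for i in range(166_416 - 1_486, 166_416 - 1_486 + 8_995)]
        res = integrate_legacy(final, legacy)
        assert res.n_overlap == 1_486
        assert res.n_merged == 173_925

    def test_disjoint_sets_sum(self):
        res = integrate_legacy({("c", 1)}, [("c", 2)])
        assert res.n_merged == 2 and res.n_overlap == 0

    def test_legacy_subset_of_final(self):
        final = {("c", i) for i in range(10)}
        res = integrate_legacy(final, [("c", 3), ("c", 4)])
        assert res.n_merged == 10

    def test_union_identity_random(self):
        rng = np.random.default_rng(3)
        a = {("c", int(x)) for x in rng.integers(0, 100, 50)}
        b = [("c", int(x)) for x in rng.integers(0, 100, 50)]
        res = integrate_legacy(a, b)
        assert res.n_merged == res.n_final + res.n_legacy - res.n_overlap


class TestAnnotateRegions:
    @pytest.fixture
    def annotation(self):
        genes = pd.DataFrame(
            dict(gene_id=["g1", "g2"], chrom=["Chr1", "Chr1"],
                 start=[10_000, 20_000], end=[15_000, 25_000],
                 strand=["+", "-"]),
        )
        return GeneAnnotation(genes=genes)

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (12_000, "genic"),          # inside g1
            (9_500, "upstream"),        # 500 bp 5' of plus-strand g1
            (15_400, "downstream"),     # 3' of g1 (plus strand)
            (8_000, "intergenic"),      # 2 kb away
            (25_500, "upstream"),       # 5' side of minus-strand g2
            (19_500, "downstream"),     # 3' side of minus-strand g2
        ],
    )
    def test_category(self, annotation, pos, expected):
        from orchardpop.datatypes import VariantTable
        v = VariantTable(chrom=np.array(["Chr1"], dtype=object),
                         pos=np.array([pos]),
                         ref=np.array(["A"], dtype=object),
                         alt=np.array(["G"], dtype=object))
        assert annotate_regions(v, annotation)[0] == expected

    def test_categories_partition(self, annotation):
        v = make_variants(60, spacing=500)
        cats = annotate_regions(v, annotation)
        assert all(c in {"genic", "upstream", "downstream",
                         "upstream_downstream", "intergenic"} for c in cats)

    def test_unknown_chromosome_intergenic(self, annotation):
        from orchardpop.datatypes import VariantTable
        v = VariantTable(chrom=np.array(["Chr9"], dtype=object),
                         pos=np.array([5]), ref=np.array(["A"], dtype=object),
                         alt=np.array(["G"], dtype=object))
        assert annotate_regions(v, annotation)[0] == "intergenic"


class TestAnnotateEffects:
    def _setup(self, seq, strand="+", cds=(0, 9)):
        genes = pd.DataFrame(dict(gene_id=["g1"], chrom=["Chr1"],
                                  start=[cds[0]], end=[cds[1]], strand=[strand]))
        ann = GeneAnnotation(genes=genes, cds={"m1": [(cds[0], cds[1], 0)]},
                             mrna_gene={"m1": "g1"})
        return ann, {"Chr1": seq}

    def test_synonymous_third_position(self):
        # GAA (Glu) -> GAG (Glu)
        ann, ref = self._setup("GAAGCTTAA")
        from orchardpop.datatypes import VariantTable
        v = VariantTable(chrom=np.array(["Chr1"], dtype=object),
                         pos=np.array([2]), ref=np.array(["A"], dtype=object),
                         alt=np.array(["G"], dtype=object))
        assert annotate_effects(v, ann, ref)[0] == "synonymous"

    def test_stop_gain(self):
        # TAC (Tyr) -> TAA (stop)
        ann, ref = self._setup("TACGCTGGG")
        from orchardpop.datatypes import VariantTable
        v = VariantTable(chrom=np.array(["Chr1"], dtype=object),
                         pos=np.array([2]), ref=np.array(["C"], dtype=object),
                         alt=np.array(["A"], dtype=object))
        assert annotate_effects(v, ann, ref)[0] == "stop_gain"

    def test_minus_strand_hand_computed(self):
        # genomic CCCCATGGG on minus strand -> coding CCCATGGGG
        # coding codon 1 = CCC (Pro); genomic SNP at pos 8 (G->A) makes
        # coding pos 0 C->T: codon TCC (Ser) => nonsynonymous, by hand.
        ann, ref = self._setup("CCCCATGGG", strand="-")
        from orchardpop.datatypes import VariantTable
        v = VariantTable(chrom=np.array(["Chr1"], dtype=object),
                         pos=np.array([8]), ref=np.array(["G"], dtype=object),
                         alt=np.array(["A"], dtype=object))
        assert annotate_effects(v, ann, ref)[0] == "nonsynonymous"

    def test_stop_loss(self):
        # TAA (stop) -> CAA (Gln)
        ann, ref = self._setup("TAAGCTGGG")
        from orchardpop.datatypes import VariantTable
        v = VariantTable(chrom=np.array(["Chr1"], dtype=object),
                         pos=np.array([0]), ref=np.array(["T"], dtype=object),
                         alt=np.array(["C"], dtype=object))
        assert annotate_effects(v, ann, ref)[0] == "stop_loss"


class TestIntervalStats:
    def test_hand_gaps(self):
        s = interval_stats(np.array(["c"] * 3, dtype=object),
                           np.array([100, 200, 350]))
        assert s.gaps["c"].tolist() == [100, 150]
        assert s.mean == 125

    def test_single_snp_no_gaps(self):
        s = interval_stats(np.array(["c"], dtype=object), np.array([5]))
        assert len(s.gaps["c"]) == 0

    def test_percentile_matches_brute_force(self):
        rng = np.random.default_rng(4)
        pos = np.sort(rng.integers(0, 1_000_000, 500))
        chrom = np.array(["c"] * 500, dtype=object)
        s = interval_stats(chrom, pos)
        brute = np.sort(np.diff(np.sort(pos)))
        assert s.percentile(90) == pytest.approx(np.percentile(brute, 90))


class TestConcordance:
    def test_identical_matrices(self):
        g = make_genotypes(np.array([[0, 1], [2, 1]], dtype=float))
        rep = genotype_concordance(g, g)
        assert rep.overall == 1.0

    def test_one_mismatch_in_ten(self):
        a = np.zeros((1, 10))
        b = np.zeros((1, 10))
        b[0, 0] = 1
        rep = genotype_concordance(make_genotypes(a, samples=["s"]),
                                   make_genotypes(b, samples=["s"]))
        assert rep.overall == pytest.approx(0.9)

    def test_degraded_calls_match_planted_error_rate(self):
        from orchardpop.simulate import ArtifactModel, SimulationConfig, \
            degrade_calls, simulate_founders
        cfg = SimulationConfig(n_founders=100, n_variants=500, seed=11)
        clean = simulate_founders(cfg)
        _, noisy, _ = degrade_calls(
            clean, None, ArtifactModel(missing_rate=0.05, error_rate=0.03), seed=11
        )
        rep = genotype_concordance(
            make_genotypes(clean.dosages, samples=clean.samples), noisy
        )
        n_joint = np.sum(~np.isnan(noisy.dosages))
        tol = 3 * np.sqrt(0.03 * 0.97 / n_joint)
        assert rep.overall == pytest.approx(0.97, abs=tol)

    def test_empty_intersection_rejected(self):
        a = make_genotypes(np.zeros((1, 2)), samples=["x"])
        b = make_genotypes(np.zeros((1, 2)), samples=["y"])
        with pytest.raises(ValueError):
            genotype_concordance(a, b)


class TestFunnelReport:
    @pytest.mark.parametrize(
        "count,total,expected",
        [
            (61_924, 173_925, "35.60%"),  # exact half-up of 35.6038...
            (151_292, 173_925, "86.99%"),
            (36_348, 173_925, "20.90%"),
            (0, 173_925, "0.00%"),
        ],
    )
    def test_percent_rendering(self, count, total, expected):
        assert render_percent(count, total) == expected

    def test_counts_non_increasing_and_removed_sum(self):
        stages = [("raw", 100), ("qc", 80), ("shared", 70)]
        rep = FunnelReport.from_counts(stages)
        counts = [c for _, c, _ in rep.stages]
        assert counts == sorted(counts, reverse=True)
        assert sum(r for _, _, r in rep.stages) == 100 - 70

    def test_order_insensitive_commuting_filters(self):
        rng = np.random.default_rng(6)
        d = rng.integers(0, 3, size=(10, 40)).astype(float)
        d[rng.random((10, 40)) < 0.2] = np.nan
        g = make_genotypes(d)
        v1 = make_variants(40, qual=np.full(40, 100.0),
                           depth=np.full((10, 40), 10.0),
                           gq=np.full((10, 40), 40.0))
        m_qc = qc_filter(v1, g)
        m_sh = shared_variant_filter(v1, g)
        both_a = m_qc & m_sh
        both_b = m_sh & m_qc
        np.testing.assert_array_equal(both_a, both_b)
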