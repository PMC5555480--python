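"""Metaplots, TSD-length histograms, tRNA-region enrichment."""

import math

import numpy as np
import pytest

from tebench.formats import FeatureInterval, read_bedgraph
from tebench.genome_sim import InsertionTruth, TrnaGene
from tebench.profiles import (
    anchored_profile,
    expected_random_proportion,
    profile_to_bedgraph,
    trna_profile,
    trna_region,
    trna_region_table,
    tsd_length_histogram,
    tsd_profile,
)
from tebench.standardize import StandardPrediction


def truth(sample, start, strand="+", chrom="chr1"):
    return InsertionTruth(
        sample_id=sample, family="Ty1", te_strand=strand,
        tsd=FeatureInterval(chrom, start, start + 5, "."), trna_name="t",
    )


def pred(start, end, sample="s1", family="Ty1", chrom="chr1", category="nonreference"):
    return StandardPrediction(
        interval=FeatureInterval(chrom, start, end, "."),
        family=family, category=category, sample_id=sample, method="mock",
        evidence="sr",
    )


def trna(start, strand="+", chrom="chr1", name="t1"):
    return TrnaGene(FeatureInterval(chrom, start, start + 72, strand, name))


class TestAnchoredProfile:
    def test_perfect_exact_predictions_give_unit_delta(self):
        truths = [truth(f"s{i}", 1000 + i * 3000) for i in range(20)]
        by_sample = {t.sample_id: [pred(t.tsd.start, t.tsd.end, t.sample_id)]
                     for t in truths}
        prof = tsd_profile(by_sample, truths, flank=10)
        assert prof.values.shape == (25,)
        inside = (prof.offsets >= 0) & (prof.offsets < 5)
        assert np.all(prof.values[inside] == 1.0)
        assert np.all(prof.values[~inside] == 0.0)

    def test_no_predictions_all_zero(self):
        truths = [truth("s1", 1000)]
        prof = tsd_profile({}, truths, flank=10)
        assert np.all(prof.values == 0.0)

    def test_indicator_bounded_by_one_multiplicity_not(self):
        truths = [truth("s1", 1000)]
        by_sample = {"s1": [pred(1000, 1005), pred(999, 1006)]}
        ind = tsd_profile(by_sample, truths, flank=5, mode="indicator")
        mult = tsd_profile(by_sample, truths, flank=5, mode="multiplicity")
        assert ind.values.max() == 1.0
        assert mult.values.max() == 2.0

    def test_minus_strand_batch_mirrored(self):
        # one asymmetric prediction: covers TSD plus 3 bp to the genomic right
        t_plus = truth("sp", 1000, "+")
        t_minus = truth("sm", 1000, "-")
        by_sample = {"sp": [pred(1000, 1008, "sp")], "sm": [pred(1000, 1008, "sm")]}
        p_plus = tsd_profile(by_sample, [t_plus], flank=10)
        p_minus = tsd_profile(by_sample, [t_minus], flank=10)
        assert np.array_equal(p_plus.values, p_minus.values[::-1])

    def test_orientation_equivariance_of_trna_profile(self):
        # mirror-symmetric scene: flipping all strands and coordinates
        # leaves the oriented profile unchanged
        L = 10_000
        g_fwd = trna(4000, "+")
        preds_fwd = [pred(3800, 3810)]
        g_rev = TrnaGene(FeatureInterval("chr1", L - 4072, L - 4000, "-", "t1"))
        preds_rev = [pred(L - 3810, L - 3800)]
        prof_fwd = trna_profile(preds_fwd, [g_fwd], upstream=300, downstream=100)
        prof_rev = trna_profile(preds_rev, [g_rev], upstream=300, downstream=100)
        assert np.array_equal(prof_fwd.values, prof_rev.values)

    def test_anchor_window_beyond_chromosome_contributes_nothing(self):
        anchor = FeatureInterval("chr1", 2, 7, "+")
        prof = anchored_profile(
            [(anchor, [pred(0, 5)])], flank_up=10, flank_down=10,
            chrom_lengths={"chr1": 50},
        )
        assert prof.values.sum() == 5.0  # the 5 covered in-genome positions

    def test_positional_jitter_mass_within_three_sigma(self):
        rng = np.random.default_rng(99)
        sd = 50
        truths, by_sample = [], {}
        for i in range(400):
            t = truth(f"s{i}", 2000 + i * 2000)
            truths.append(t)
            shift = int(np.rint(rng.normal(0, sd)))
            by_sample[t.sample_id] = [
                pred(t.tsd.start + shift, t.tsd.end + shift, t.sample_id)
            ]
        prof = tsd_profile(by_sample, truths, flank=500)
        total = prof.values.sum()
        within = prof.values[np.abs(prof.offsets) <= 150].sum()
        assert within / total > 0.99  # ~0.997 expected at 3 sigma


class TestTsdHistogram:
    def test_identical_calls_across_samples_count_once(self):
        preds = [pred(800, 805, f"s{i}") for i in range(3)]
        hist = tsd_length_histogram(preds, unique_sites_only=True)
        assert hist["Ty1"] == {5: 1}

    def test_different_lengths_at_same_locus_are_distinct_sites(self):
        preds = [pred(800, 805, "s1"), pred(800, 807, "s2")]
        hist = tsd_length_histogram(preds)
        assert hist["Ty1"] == {5: 1, 7: 1}

    def test_exact_caller_concentrates_at_five(self):
        preds = [pred(1000 + i * 100, 1005 + i * 100, f"s{i}") for i in range(50)]
        hist = tsd_length_histogram(preds)
        assert set(hist["Ty1"]) == {5} and hist["Ty1"][5] == 50


class TestTrnaRegions:
    def test_region_geometry_plus_and_minus(self):
        g_plus = trna(5000, "+")
        r = trna_region(g_plus)
        assert (r.start, r.end) == (4000, 5500) and len(r) == 1500
        g_minus = trna(5000, "-")  # tss = 5071
        r = trna_region(g_minus)
        assert len(r) == 1500
        assert r.start == 5071 - 499 and r.end == 5071 + 1001

    def test_membership_boundaries(self):
        g = trna(5000, "+")
        table = trna_region_table([pred(5600, 5605)], [g])  # tss+600: outside
        assert table.loc[0, "in_region"] == 0
        table = trna_region_table([pred(5499, 5504)], [g])  # 1 bp inside
        assert table.loc[0, "in_region"] == 1

    def test_overlapping_two_regions_counts_once_and_totals_conserved(self):
        genes = [trna(5000, "+", name="a"), trna(6200, "+", name="b")]
        preds = [pred(5400, 5410), pred(50_000, 50_005, family="Ty2")]
        table = trna_region_table(preds, genes).set_index("family")
        assert table.loc["Ty1", "in_region"] == 1
        assert int(table["total"].sum()) == len(preds)

    def test_uniform_random_placement_matches_analytic_expectation(self):
        rng = np.random.default_rng(17)
        L, n_genes = 200_000, 10
        genes = [trna(8000 + i * 16_000, "+-"[i % 2], name=f"t{i}")
                 for i in range(n_genes)]
        n = 20_000
        starts = rng.integers(0, L - 1, size=n)
        preds = [pred(int(s), int(s) + 1, f"s{i}") for i, s in enumerate(starts)]
        table = trna_region_table(preds, genes)
        frac = table["in_region"].sum() / table["total"].sum()
        expected = expected_random_proportion(n_genes, 1500, L)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se


class TestExpectedRandomProportion:
    def test_published_scale_value(self):
        got = expected_random_proportion(299, 1500, 12_162_995)
        assert round(got, 4) == 0.0369
        assert float(f"{got:.2g}") == 0.037

    def test_small_examples(self):
        assert expected_random_proportion(1, 100, 1000) == 0.1
        assert expected_random_proportion(1, 1000, 1000) == 1.0

    def test_clamped_above_one(self):
        assert expected_random_proportion(10, 1000, 1000) == 1.0

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            expected_random_proportion(0, 1500, 100)


def test_profile_bedgraph_round_trip(tmp_path):
    truths = [truth("s1", 1000)]
    prof = tsd_profile({"s1": [pred(1000, 1005, "s1")]}, truths, flank=10, label="plus")
    path = tmp_path / "p.bedgraph"
    profile_to_bedgraph(prof, path)
    back = read_bedgraph(path)["plus"]
    assert np.array_equal(back, prof.values)
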