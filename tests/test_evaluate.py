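"""Threshold scoring, recurrent-FP filtering, and concordance counting."""

import math

import numpy as np
import pytest

from tebench.evaluate import (
    ConcordanceConfig,
    ThresholdConfig,
    concordance_sets,
    match_prediction,
    recurrent_site_filter,
    score_sample_set,
)
from tebench.formats import FeatureInterval
from tebench.genome_sim import InsertionTruth
from tebench.standardize import StandardPrediction


def truth(chrom="chr1", start=800, end=805, family="Ty1", sample="s1", strand="+"):
    return InsertionTruth(
        sample_id=sample, family=family, te_strand=strand,
        tsd=FeatureInterval(chrom, start, end, "."), trna_name="t1",
    )


def pred(chrom="chr1", start=800, end=805, family="Ty1", sample="s1",
         method="mock", category="nonreference", evidence="sr"):
    return StandardPrediction(
        interval=FeatureInterval(chrom, start, end, "."),
        family=family, category=category, sample_id=sample,
        method=method, evidence=evidence,
    )


def brute_force_match(p_start, p_end, t_start, t_end, window):
    """Independent oracle: any predicted base within window bp of the TSD."""
    if window == "exact":
        return (p_start, p_end) == (t_start, t_end)
    region = set(range(max(0, t_start - window), t_end + window))
    return any(pos in region for pos in range(p_start, p_end))


class TestMatchPrediction:
    def test_exact_match_requires_interval_equality(self):
        assert match_prediction(pred(), truth(), "exact")
        assert not match_prediction(pred(start=804, end=806), truth(), "exact")
        assert match_prediction(pred(start=804, end=806), truth(), 100)

    def test_window_transition_points(self):
        # [700,701) touches the 100-bp region [700,905); [699,700) does not
        assert match_prediction(pred(start=700, end=701), truth(), 100)
        assert not match_prediction(pred(start=699, end=700), truth(), 100)
        for off in range(-600, 601):
            got = match_prediction(pred(start=800 + off, end=805 + off), truth(), 100)
            assert got == brute_force_match(800 + off, 805 + off, 800, 805, 100)

    def test_family_mismatch_fails_when_required(self):
        assert not match_prediction(pred(family="Ty2"), truth(), "exact")
        assert match_prediction(pred(family="Ty2"), truth(), "exact", family_required=False)

    def test_different_chromosome_never_matches(self):
        assert not match_prediction(pred(chrom="chr2"), truth(), 500)

    def test_agrees_with_brute_force_on_random_cases(self):
        rng = np.random.default_rng(123)
        for _ in range(10_000):
            ts = int(rng.integers(0, 2000))
            te = ts + int(rng.integers(1, 20))
            ps = int(rng.integers(0, 2000))
            pe = ps + int(rng.integers(1, 50))
            w = ["exact", 100, 300, 500, int(rng.integers(1, 700))][rng.integers(0, 5)]
            expected = brute_force_match(ps, pe, ts, te, w)
            got = match_prediction(
                pred(start=ps, end=pe), truth(start=ts, end=te), w
            )
            assert got == expected, (ps, pe, ts, te, w)


class TestScoring:
    def test_perfect_caller_scores_one_everywhere(self):
        truths = [truth(sample=f"s{i}", start=800 + i * 3000, end=805 + i * 3000)
                  for i in range(10)]
        preds = {t.sample_id: [pred(sample=t.sample_id, start=t.tsd.start, end=t.tsd.end)]
                 for t in truths}
        summary, _ = score_sample_set(preds, truths)
        row = summary.loc[("mock", "+")]
        assert row["mean_nonreference"] == 1.0
        for w in ("exact", 100, 300, 500):
            assert row[f"correct_{w}"] == 1.0

    def test_empty_predictions_score_zero(self):
        truths = [truth(sample="s1")]
        summary, _ = score_sample_set({}, truths, method="mock")
        row = summary.loc[("mock", "+")]
        assert row["mean_nonreference"] == 0.0 and row["correct_500"] == 0.0

    def test_monotonic_across_windows(self):
        rng = np.random.default_rng(7)
        truths, preds = [], {}
        for i in range(200):
            t = truth(sample=f"s{i}", start=1000 + i * 2000, end=1005 + i * 2000)
            truths.append(t)
            shift = int(rng.normal(0, 120))
            preds[t.sample_id] = [
                pred(sample=t.sample_id, start=max(0, t.tsd.start + shift),
                     end=max(0, t.tsd.start + shift) + 5)
            ]
        summary, _ = score_sample_set(preds, truths)
        row = summary.loc[("mock", "+")]
        vals = [row[f"correct_{w}"] for w in ("exact", 100, 300, 500)]
        assert vals == sorted(vals)

    def test_capped_vs_raw_match_counts(self):
        t = truth(sample="s1")
        preds = {"s1": [pred(sample="s1"), pred(sample="s1", start=801, end=806)]}
        summary, details = score_sample_set(preds, [t])
        row = summary.loc[("mock", "+")]
        assert row["correct_100"] == 1.0      # capped headline
        assert row["matches_100"] == 2.0      # raw mean
        assert details[0].matches[100] == 2

    def test_detection_probability_recovered(self):
        rng = np.random.default_rng(42)
        p_detect, n = 0.9, 500
        truths, preds = [], {}
        for i in range(n):
            t = truth(sample=f"s{i}", start=500 + i * 1500, end=505 + i * 1500)
            truths.append(t)
            if rng.random() < p_detect:
                preds[t.sample_id] = [pred(sample=t.sample_id, start=t.tsd.start,
                                           end=t.tsd.end)]
        summary, _ = score_sample_set(preds, truths, method="mock")
        got = summary.loc[("mock", "+")]["correct_exact"]
        ci = 2.576 * math.sqrt(p_detect * (1 - p_detect) / n)
        assert abs(got - p_detect) < ci


class TestRecurrentFilter:
    def test_recurrent_site_flagged_and_removed(self):
        preds = [pred(sample=f"s{i}", start=4000, end=4005) for i in range(149)]
        preds += [pred(sample="s0", start=800, end=805)]
        kept, flagged = recurrent_site_filter(preds)
        assert len(flagged) == 1 and flagged[0][-1] == 149
        assert len(kept) == 1 and kept[0].interval.start == 800

    def test_singleton_kept_and_conservation(self):
        preds = [pred(sample="s1"), pred(sample="s2", start=900, end=905),
                 pred(sample="s1", category="reference")]
        kept, flagged = recurrent_site_filter(preds)
        assert len(kept) == 3 and not flagged

    def test_reference_predictions_untouched(self):
        preds = [pred(sample=f"s{i}", category="reference", evidence="nonab")
                 for i in range(5)]
        kept, flagged = recurrent_site_filter(preds)
        assert len(kept) == 5 and not flagged


class TestConcordance:
    def _truths(self, n):
        return [truth(sample=f"s{i}", start=500 + i * 2000, end=505 + i * 2000)
                for i in range(n)]

    def test_all_methods_perfect_single_region(self):
        truths = self._truths(10)
        by_method = {
            m: {t.sample_id: [pred(sample=t.sample_id, method=m,
                                   start=t.tsd.start, end=t.tsd.end)]
                for t in truths}
            for m in ("a", "b", "c")
        }
        config = ConcordanceConfig({"a": 0, "b": 100, "c": 500})
        counts = concordance_sets(by_method, truths, config)
        assert counts == {frozenset({"a", "b", "c"}): 10}

    def test_regions_total_sample_count(self):
        rng = np.random.default_rng(3)
        truths = self._truths(200)
        by_method = {}
        for m in ("x", "y"):
            by_method[m] = {
                t.sample_id: [pred(sample=t.sample_id, method=m,
                                   start=t.tsd.start, end=t.tsd.end)]
                for t in truths if rng.random() < 0.6
            }
        counts = concordance_sets(by_method, truths, ConcordanceConfig({"x": 0, "y": 0}))
        assert sum(counts.values()) == 200

    def test_family_is_ignored(self):
        truths = self._truths(1)
        by_method = {"m": {truths[0].sample_id: [
            pred(sample=truths[0].sample_id, method="m", family="WrongFam",
                 start=truths[0].tsd.start, end=truths[0].tsd.end)
        ]}}
        counts = concordance_sets(by_method, truths, ConcordanceConfig({"m": 0}))
        assert counts == {frozenset({"m"}): 1}

    def test_independent_callers_intersection_within_ci(self):
        rng = np.random.default_rng(11)
        n, p = 1000, 0.5
        truths = self._truths(n)
        by_method = {}
        for m in ("u", "v"):
            by_method[m] = {
                t.sample_id: [pred(sample=t.sample_id, method=m,
                                   start=t.tsd.start, end=t.tsd.end)]
                for t in truths if rng.random() < p
            }
        counts = concordance_sets(by_method, truths, ConcordanceConfig({"u": 0, "v": 0}))
        both = counts.get(frozenset({"u", "v"}), 0)
        exp = n * p * p
        ci = 2.576 * math.sqrt(n * p * p * (1 - p * p))
        assert abs(both - exp) < ci
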