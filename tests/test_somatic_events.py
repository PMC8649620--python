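import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pairedprog import somatic_events as se
from pairedprog.synthetic_data import SimulationConfig, generate_cohort, generate_somatic_tables


def ann_row(gene="TP53", role="tumor_suppressor", cosmic=True, sign="none",
            chrom="chr1", start=1_000_000):
    return pd.Series(
        {
            "gene_id": gene,
            "chrom": chrom,
            "start": start,
            "role": role,
            "cosmic": cosmic,
            "sv_association_sign": sign,
            "hotspot_residues": frozenset({100}),
        }
    )


def variant(cls, hotspot=False, sample="s1"):
    return {"sample_id": sample, "variant_classification": cls, "is_hotspot": hotspot}


class TestClassifySnvIndel:
    def test_oncogene_hotspot_missense_is_event(self):
        ev = se.classify_snv_indel(variant("missense", hotspot=True), ann_row(role="oncogene"))
        assert ev.event_type == "snv_hotspot"

    def test_oncogene_nonhotspot_nonsense_is_no_event(self):
        assert se.classify_snv_indel(variant("nonsense"), ann_row(role="oncogene")) is None

    @pytest.mark.parametrize("cls", ["nonsense", "nonstop", "frameshift_indel", "inframe_indel"])
    def test_tumor_suppressor_inactivating_classes(self, cls):
        ev = se.classify_snv_indel(variant(cls), ann_row(role="tumor_suppressor"))
        assert ev.event_type == "inactivating"

    def test_tumor_suppressor_hotspot_takes_precedence(self):
        ev = se.classify_snv_indel(
            variant("missense", hotspot=True), ann_row(role="tumor_suppressor")
        )
        assert ev.event_type == "snv_hotspot"

    def test_silent_and_other_role_never_yield_events(self):
        for role in ("oncogene", "tumor_suppressor", "other"):
            assert se.classify_snv_indel(variant("silent", hotspot=False), ann_row(role=role)) is None
        for cls in ("missense", "nonsense", "frameshift_indel", "other"):
            assert se.classify_snv_indel(variant(cls), ann_row(role="other")) is None
        # non-hotspot missense on a tumor suppressor is not inactivating
        assert se.classify_snv_indel(variant("missense"), ann_row(role="tumor_suppressor")) is None

    def test_unknown_classification_named_in_error(self):
        with pytest.raises(ValueError, match="splice_site"):
            se.classify_snv_indel(variant("splice_site"), ann_row())


class TestCnaEvents:
    @pytest.fixture()
    def annotation(self):
        return pd.DataFrame(
            [
                ann_row("COS1", role="oncogene", cosmic=True),
                ann_row("COS2", role="tumor_suppressor", cosmic=True),
                ann_row("NOT1", role="other", cosmic=False),
            ]
        ).set_index("gene_id", drop=False)

    def test_threshold_calls(self, annotation):
        cna = pd.DataFrame(
            {"s1": [2, -2, 2], "s2": [1, 0, -1]}, index=["COS1", "COS2", "NOT1"]
        )
        events = se.call_cna_events(cna, annotation)
        keys = {(e.sample_id, e.gene_id, e.event_type) for e in events}
        assert keys == {
            ("s1", "COS1", "amplification"),
            ("s1", "COS2", "deep_deletion"),
        }  # +1/-1 below threshold; NOT1 not COSMIC

    def test_all_zero_matrix_gives_no_events(self, annotation):
        cna = pd.DataFrame(0, index=["COS1", "COS2"], columns=["s1", "s2"])
        assert se.call_cna_events(cna, annotation) == []

    def test_out_of_range_call_rejected(self, annotation):
        cna = pd.DataFrame({"s1": [3]}, index=["COS1"])
        with pytest.raises(ValueError):
            se.call_cna_events(cna, annotation)

    def test_non_integer_call_rejected(self, annotation):
        cna = pd.DataFrame({"s1": [1.5]}, index=["COS1"])
        with pytest.raises(ValueError):
            se.call_cna_events(cna, annotation)


class TestSvExpressionEvents:
    @pytest.fixture()
    def setup(self):
        ann = pd.DataFrame(
            [ann_row("SVG", role="oncogene", sign="positive", chrom="chr2", start=5_000_000)]
        ).set_index("gene_id", drop=False)
        # reference cohort of 5 samples: median 10, sd 1 by construction
        expr = pd.DataFrame(
            {"s1": [10.0], "s2": [9.0], "s3": [11.0], "s4": [10.0], "s5": [10.0]},
            index=["SVG"],
        )
        stats_ = se.cohort_reference_stats(expr)
        return ann, expr, stats_

    def bp(self, pos, sample="s3"):
        return pd.DataFrame(
            {"sample_id": [sample], "chrom": ["chr2"], "pos_1based": [pos], "sv_type": ["BND"]}
        )

    def test_in_window_with_large_positive_deviation_is_event(self, setup):
        ann, expr, stats_ = setup
        sd = stats_.loc["SVG", "sd"]
        expr.loc["SVG", "s3"] = 10.0 + 0.6 * sd
        events = se.call_sv_expression_events(self.bp(5_000_000 + 500_000), expr, ann, stats_)
        assert len(events) == 1
        assert events[0].event_type == "sv_altered_expression"

    def test_window_boundary_inclusive_and_exclusive(self, setup):
        ann, expr, stats_ = setup
        sd = stats_.loc["SVG", "sd"]
        expr.loc["SVG", "s3"] = 10.0 + 2.0 * sd
        at_boundary = se.call_sv_expression_events(self.bp(5_000_000 + 1_000_000), expr, ann, stats_)
        past_boundary = se.call_sv_expression_events(self.bp(5_000_000 + 1_000_001), expr, ann, stats_)
        assert len(at_boundary) == 1
        assert past_boundary == []

    def test_below_deviation_threshold_no_event(self, setup):
        ann, expr, stats_ = setup
        sd = stats_.loc["SVG", "sd"]
        expr.loc["SVG", "s3"] = 10.0 + 0.2 * sd
        assert se.call_sv_expression_events(self.bp(5_000_000), expr, ann, stats_) == []

    def test_negative_sign_requires_negative_deviation(self, setup):
        ann, expr, stats_ = setup
        ann.loc["SVG", "sv_association_sign"] = "negative"
        sd = stats_.loc["SVG", "sd"]
        expr.loc["SVG", "s3"] = 10.0 - 0.6 * sd
        up = expr.copy()
        up.loc["SVG", "s3"] = 10.0 + 0.6 * sd
        assert len(se.call_sv_expression_events(self.bp(5_000_000), expr, ann, stats_)) == 1
        assert se.call_sv_expression_events(self.bp(5_000_000), up, ann, stats_) == []

    def test_zero_sd_gene_skipped(self, setup):
        ann, expr, _ = setup
        const = pd.DataFrame({c: [10.0] for c in expr.columns}, index=["SVG"])
        stats_ = se.cohort_reference_stats(const)
        assert se.call_sv_expression_events(self.bp(5_000_000), const, ann, stats_) == []


def pairing_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["patient_id", "initial_sample_id", "recurrent_sample_id", "tumor_status", "histology"],
    )


class TestTabulatePairedEvents:
    def test_simple_gain(self):
        pairing = pairing_frame([("p1", "i", "r", "recurrence", "x")])
        events = [
            se.SomaticEvent("i", "A", "amplification"),
            se.SomaticEvent("r", "A", "amplification"),
            se.SomaticEvent("r", "B", "amplification"),
        ]
        [summary] = se.tabulate_paired_events(events, pairing)
        assert summary.gained == {("B", "amplification")}
        assert summary.lost == frozenset()

    def test_loss_requires_absence_from_all_recurrents(self):
        pairing = pairing_frame(
            [("p1", "i", "r1", "recurrence", "x"), ("p1", "i", "r2", "progressive", "x")]
        )
        events = [
            se.SomaticEvent("i", "A", "amplification"),
            se.SomaticEvent("r2", "A", "amplification"),
        ]
        [summary] = se.tabulate_paired_events(events, pairing)
        assert summary.lost == frozenset()  # retained in at least one recurrent
        assert summary.gained == frozenset()

    def test_identical_event_sets_give_empty_summary(self):
        pairing = pairing_frame([("p1", "i", "r", "recurrence", "x")])
        events = [
            se.SomaticEvent("i", "A", "snv_hotspot"),
            se.SomaticEvent("r", "A", "snv_hotspot"),
        ]
        [summary] = se.tabulate_paired_events(events, pairing)
        assert summary.gained_count == 0 and summary.lost_count == 0

    def test_duplicate_rows_do_not_inflate_counts(self):
        pairing = pairing_frame([("p1", "i", "r", "recurrence", "x")])
        events = [se.SomaticEvent("r", "B", "amplification")] * 5
        [summary] = se.tabulate_paired_events(events, pairing)
        assert summary.gained_count == 1

    def test_unknown_sample_rejected(self):
        pairing = pairing_frame([("p1", "i", "r", "recurrence", "x")])
        with pytest.raises(KeyError, match="mystery"):
            se.tabulate_paired_events(
                [se.SomaticEvent("mystery", "A", "amplification")], pairing
            )

    def test_event_calling_order_invariance(self, rng):
        pairing = pairing_frame(
            [("p1", "i1", "r1", "recurrence", "x"), ("p2", "i2", "r2", "recurrence", "x")]
        )
        events = [
            se.SomaticEvent(s, g, t)
            for s in ("i1", "r1", "i2", "r2")
            for g, t in (("A", "amplification"), ("B", "snv_hotspot"))
            if rng.random() < 0.6
        ]
        a = se.tabulate_paired_events(events, pairing)
        shuffled = list(events)
        rng.shuffle(shuffled)
        b = se.tabulate_paired_events(shuffled, pairing)
        assert {(s.patient_id, s.gained, s.lost) for s in a} == {
            (s.patient_id, s.gained, s.lost) for s in b
        }


class TestPairedCountTest:
    def test_identical_vectors_null(self):
        res = se.paired_count_test([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0 and res.p == 1.0

    def test_constant_nonzero_differences_degenerate_minimal_p(self):
        res = se.paired_count_test([0, 0, 0, 0], [1, 1, 1, 1])
        assert res.degenerate
        assert math.isinf(res.t)
        assert 0 < res.p < 1e-300

    def test_matches_direct_formula(self):
        d = np.array([2.0, -1.0, 3.0, 0.0, 1.0, 2.0, -2.0, 4.0])
        res = se.paired_count_test(np.zeros_like(d), d)
        t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        p_hand = 2 * stats.t.sf(abs(t_hand), len(d) - 1)
        assert res.t == pytest.approx(t_hand, rel=1e-12)
        assert res.p == pytest.approx(p_hand, rel=1e-12)
        assert res.mean_recurrent == pytest.approx(d.mean())

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            se.paired_count_test([1], [2])


class TestTruthRecovery:
    """Constructive consistency between the generator and the callers."""

    @pytest.fixture(scope="class")
    def generated(self):
        cfg = SimulationConfig(seed=7)
        cohort = generate_cohort(cfg)
        somatic = generate_somatic_tables(cfg, cohort.pairing, cohort.expression)
        return cfg, cohort, somatic

    def call_all(self, somatic):
        ann = somatic.annotation
        stats_ = se.cohort_reference_stats(somatic.expression)
        return (
            se.call_snv_events(somatic.variants, ann)
            + se.call_cna_events(somatic.cna, ann)
            + se.call_sv_expression_events(somatic.breakpoints, somatic.expression, ann, stats_)
        )

    def test_called_events_equal_truth_exactly(self, generated):
        _, _, somatic = generated
        called = {}
        for ev in self.call_all(somatic):
            called.setdefault(ev.sample_id, set()).add(ev.key)
        truth = somatic.truth.events_by_sample
        assert set(called) <= set(truth)
        for sample, expected in truth.items():
            assert called.get(sample, set()) == expected, sample

    def test_tabulated_gains_and_losses_match_truth(self, generated):
        _, cohort, somatic = generated
        events = self.call_all(somatic)
        wgs = set(somatic.cna.columns)
        pairing = cohort.pairing[cohort.pairing["initial_sample_id"].isin(wgs)]
        summaries = se.tabulate_paired_events(events, pairing)
        for s in summaries:
            assert set(s.gained) == somatic.truth.gained_by_patient[s.patient_id]
            assert set(s.lost) == somatic.truth.lost_by_patient[s.patient_id]

    def test_event_matrix_covers_called_genes(self, generated):
        _, _, somatic = generated
        events = self.call_all(somatic)
        matrix = se.event_matrix(events)
        assert set(matrix.index) == {e.gene_id for e in events}
        assert (matrix != "").sum().sum() == len({(e.gene_id, e.sample_id) for e in events})
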