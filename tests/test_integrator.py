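"""Binned likelihood-ratio fitting, product combination and posteriors."""

import numpy as np
import pytest

from gofuse.integrate import (
    ComponentScoreSet, LikelihoodRatioTable, LrFitError, combine,
    fit_lr_table, posterior_from_lr, read_lr_tables, threshold_annotations,
    write_lr_tables,
)
from gofuse.ontology import AnnotationSet
from gofuse.simulate import analytic_bin_lrs, binned_calibration_sample

from conftest import go


def make_table(lrs, method="Str", aspect="MF", absent=1.0, prior=1.0):
    edges = np.linspace(0, 1, len(lrs) + 1)
    return LikelihoodRatioTable(method, aspect, edges, np.asarray(lrs, float),
                                absent, prior)


class TestBinIndex:
    def test_left_closed_right_open_last_closed(self):
        t = make_table([1.0] * 10)
        assert t.bin_index(0.0) == 0
        assert t.bin_index(0.1) == 1       # boundary goes right
        assert t.bin_index(0.999) == 9
        assert t.bin_index(1.0) == 9       # last bin closed


class TestFitLrTable:
    def _scores_and_gold(self, flat_onto, pos_scores, neg_scores):
        s = ComponentScoreSet("Str")
        gold = AnnotationSet()
        terms = [go(i) for i in range(2, 22)]
        i = 0
        for sc in pos_scores:
            d, t = f"d{i // 20}", terms[i % 20]
            s.add(d, t, sc)
            gold.add(d, t)
            i += 1
        for sc in neg_scores:
            d, t = f"d{i // 20}", terms[i % 20]
            s.add(d, t, sc)
            i += 1
        return s, gold

    def test_hand_case_lr_36(self, flat_onto):
        # one bin with 8 pos / 2 neg against totals 100 pos / 900 neg:
        # bin odds 4, prior odds 1/9 -> LR = 36 (no smoothing)
        rng = np.random.default_rng(0)
        pos = [0.95] * 8 + list(rng.uniform(0.0, 0.9, 92))
        neg = [0.95] * 2 + list(rng.uniform(0.0, 0.9, 898))
        s, gold = self._scores_and_gold(flat_onto, pos, neg)
        table = fit_lr_table(s, gold, flat_onto, "MF", bins=10, smoothing=0.0)
        assert table.lr_per_bin[9] == pytest.approx(36.0, abs=1e-9)
        assert table.prior_odds == pytest.approx(1 / 9)

    def test_shuffled_labels_drive_lrs_to_one(self, flat_onto):
        rng = np.random.default_rng(1)
        n = 10_000
        scores = rng.uniform(0, 1, n)
        labels = rng.random(n) < 0.3   # independent of score
        s, gold = self._scores_and_gold(
            flat_onto, scores[labels], scores[~labels])
        table = fit_lr_table(s, gold, flat_onto, "MF")
        assert np.all(np.abs(np.log(table.lr_per_bin)) < 0.35)

    def test_recovers_analytic_lrs(self, flat_onto):
        rng = np.random.default_rng(2)
        rates = [0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
        scores, labels = binned_calibration_sample(rates, 100_000, rng)
        s, gold = self._scores_and_gold(
            flat_onto, scores[labels == 1], scores[labels == 0])
        table = fit_lr_table(s, gold, flat_onto, "MF")
        np.testing.assert_allclose(table.lr_per_bin, analytic_bin_lrs(rates),
                                   rtol=0.10)

    def test_zero_positives_is_fit_error(self, flat_onto):
        s, gold = self._scores_and_gold(flat_onto, [], [0.5, 0.6])
        with pytest.raises(LrFitError):
            fit_lr_table(s, gold, flat_onto, "MF")

    def test_absent_pseudo_bin_from_candidates(self, flat_onto):
        s, gold = self._scores_and_gold(flat_onto, [0.9] * 10, [0.1] * 10)
        # 5 extra gold pairs the method never scored
        extra = {(f"x{i}", go(2)) for i in range(5)}
        for d, t in extra:
            gold.add(d, t)
        table = fit_lr_table(s, gold, flat_onto, "MF",
                             candidates=set(s.scores) | extra, smoothing=1.0)
        # absent bin: 5 pos, 0 neg -> LR > 1 with smoothing
        assert table.absent_lr > 1.0

    def test_round_trip_tsv(self, flat_onto):
        import io

        s, gold = self._scores_and_gold(flat_onto, [0.9] * 30, [0.1] * 70)
        t = fit_lr_table(s, gold, flat_onto, "MF")
        buf = io.StringIO()
        write_lr_tables({("Str", "MF"): t}, buf)
        buf.seek(0)
        back = read_lr_tables(buf)[("Str", "MF")]
        np.testing.assert_allclose(back.lr_per_bin, t.lr_per_bin, rtol=1e-9)
        assert back.absent_lr == pytest.approx(t.absent_lr)
        assert back.prior_odds == pytest.approx(t.prior_odds)


class TestCombine:
    def test_hand_case_posterior_08(self, flat_onto):
        # LRs {36, 1, 1, 1}, prior odds 1/9 -> posterior 4/(1+4) = 0.8
        tables = {}
        for i, m in enumerate(("Str", "IPR", "PSSM", "Seq")):
            lrs = [36.0 if (m == "Str" and b == 9) else 1.0 for b in range(10)]
            tables[(m, "MF")] = make_table(lrs, m, prior=1 / 9)
        sets = [ComponentScoreSet(m, {("d1", go(2)): 0.95}) for m in
                ("Str", "IPR", "PSSM", "Seq")]
        results = combine(sets, tables, flat_onto)
        assert len(results) == 1
        assert results[0].combined_lr == pytest.approx(36.0)
        assert results[0].posterior == pytest.approx(0.8, abs=1e-12)

    def test_all_absent_gives_prior(self, flat_onto):
        tables = {(m, "MF"): make_table([2.0] * 10, m, absent=1.0, prior=0.25)
                  for m in ("Str", "IPR")}
        sets = [ComponentScoreSet("Str", {("d1", go(2)): 0.5}),
                ComponentScoreSet("IPR", {})]
        # IPR absent with absent_lr 1: posterior driven by Str only;
        # make Str absent too by scoring a pair only IPR knows
        sets2 = [ComponentScoreSet("Str", {}),
                 ComponentScoreSet("IPR", {("d1", go(2)): 0.5})]
        tables2 = {(m, "MF"): make_table([1.0] * 10, m, absent=1.0, prior=0.25)
                   for m in ("Str", "IPR")}
        results = combine(sets2, tables2, flat_onto)
        assert results[0].posterior == pytest.approx(0.25 / 1.25, abs=1e-12)

    def test_matches_odds_form_naive_bayes_oracle(self, flat_onto):
        rng = np.random.default_rng(3)
        methods = ("Str", "IPR", "PSSM", "Seq")
        prior = 0.2
        tables = {}
        lr_by_method = {}
        for m in methods:
            lrs = np.exp(rng.normal(0, 1, 10))
            tables[(m, "MF")] = make_table(lrs, m, absent=0.7, prior=prior)
            lr_by_method[m] = lrs
        sets = []
        pairs = [(f"d{i}", go(2 + i % 20)) for i in range(50)]
        scored = {}
        for m in methods:
            s = ComponentScoreSet(m)
            for pair in pairs:
                if rng.random() < 0.7:
                    sc = float(rng.uniform(0, 1))
                    s.add(*pair, sc)
                    scored[(m, pair)] = sc
            sets.append(s)
        results = combine(sets, tables, flat_onto)
        for r in results:
            pair = (r.domain_id, r.term)
            odds = prior
            for m in methods:
                sc = scored.get((m, pair))
                if sc is None:
                    odds *= 0.7
                else:
                    odds *= lr_by_method[m][min(int(sc * 10), 9)]
            assert r.posterior == pytest.approx(odds / (1 + odds), abs=1e-12)

    def test_method_order_irrelevant(self, flat_onto):
        rng = np.random.default_rng(4)
        methods = ("Str", "IPR", "PSSM", "Seq")
        tables = {(m, "MF"): make_table(np.exp(rng.normal(0, 1, 10)), m)
                  for m in methods}
        sets = [ComponentScoreSet(m, {("d1", go(2)): float(rng.uniform())})
                for m in methods]
        fwd = combine(sets, tables, flat_onto)[0].combined_lr
        rev = combine(sets[::-1], tables, flat_onto)[0].combined_lr
        assert fwd == pytest.approx(rev, rel=1e-12)

    def test_score_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ComponentScoreSet("Str", {("d1", go(2)): 1.5})


class TestThreshold:
    def _results(self, posteriors):
        from gofuse.integrate import AnnotationResult

        return [AnnotationResult(f"d{i}", go(2), "MF", 1.0, p, {})
                for i, p in enumerate(posteriors)]

    def test_inclusive_at_cutoff(self):
        kept = threshold_annotations(self._results([0.4, 0.5, 0.9]), 0.5)
        assert [r.posterior for r in kept] == [0.5, 0.9]

    def test_zero_cutoff_keeps_all(self):
        assert len(threshold_annotations(self._results([0.1, 0.2]), 0.0)) == 2

    def test_retained_count_monotone_in_cutoff(self):
        rng = np.random.default_rng(5)
        res = self._results(rng.uniform(0, 1, 200))
        counts = [len(threshold_annotations(res, c))
                  for c in np.linspace(0, 1, 21)]
        assert counts == sorted(counts, reverse=True)


def test_posterior_identity():
    assert posterior_from_lr(1 / 9, 36.0) == pytest.approx(0.8)
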