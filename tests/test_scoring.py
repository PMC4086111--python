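import math

import numpy as np
import pytest

from srnatarget.accessibility import fold_partition
from srnatarget.conservation import ConservationProfile
from srnatarget.scoring import (InteractionScore, ScanConfig, TargetPrediction,
                                calibrate_pvalues, gumbel_fit_moments,
                                rank_targets, score_candidate)
from srnatarget.sequence_io import NucleotideSequence as NS
from srnatarget.thermo import DuplexHit


def flat_conservation(n, weight=1.0):
    w = np.full(n, weight)
    return ConservationProfile(entropy=1.0 - w, weight=w, n_rows=4)


class TestScoreCandidate:
    def test_fully_accessible_gives_e_total_equal_e_hyb(self):
        # G-only sRNA and C-only window cannot fold intramolecularly, so
        # both opening energies vanish exactly
        srna, window = NS("GGGGGGGG"), NS("CCCCCCCC")
        sa, wa = fold_partition(srna), fold_partition(window)
        hit, score = score_candidate(srna, sa, flat_conservation(8), window, wa,
                                     config=ScanConfig(min_seed=4))
        assert score.ed_srna == 0.0 and score.ed_mrna == 0.0
        assert score.e_total == pytest.approx(score.e_hyb)
        assert score.e_total == pytest.approx(hit.e_hyb)
        assert score.cons_mean == pytest.approx(1.0)

    def test_sequestered_site_scores_worse_than_open_site(self):
        srna = NS("GGGGGGGG")
        open_win = NS("AAAAA" + "CCCCCCCC" + "AAAAA")
        # same site, now base-paired inside a planted hairpin stem
        stem_win = NS("AAAAA" + "CCCCCCCC" + "AAAAA" + "GGGGGGGG" + "AAAAA")
        cfg = ScanConfig(min_seed=4)
        sa = fold_partition(srna)
        cons = flat_conservation(8)
        _, s_open = score_candidate(srna, sa, cons, open_win,
                                    fold_partition(open_win), config=cfg)
        res = score_candidate(srna, sa, cons, stem_win,
                              fold_partition(stem_win), config=cfg)
        if res is None:  # opening cost can push e_total over 0 entirely
            assert s_open.e_total < 0
        else:
            assert res[1].e_total > s_open.e_total
            assert res[1].ed_mrna > s_open.ed_mrna

    def test_unconserved_complement_region_is_rejected(self):
        srna, window = NS("GGGGGGGG"), NS("CCCCCCCC")
        sa, wa = fold_partition(srna), fold_partition(window)
        cons = flat_conservation(8, weight=0.1)  # below w_min everywhere
        assert score_candidate(srna, sa, cons, window, wa,
                               config=ScanConfig(min_seed=4)) is None

    def test_inaccessible_srna_anchor_is_rejected(self):
        srna, window = NS("GGGGGGGG"), NS("CCCCCCCC")
        sa, wa = fold_partition(srna), fold_partition(window)
        cfg = ScanConfig(min_seed=4, p_min=1.1)  # impossible anchor bar
        assert score_candidate(srna, sa, None, window, wa, config=cfg) is None


class TestCalibratePvalues:
    def _scores(self, rng, n=100):
        return {f"g{i:03d}": float(-x) for i, x in
                enumerate(rng.gumbel(10.0, 2.0, size=n))}

    def test_gumbel_tail_formula_and_identity(self):
        rng = np.random.default_rng(21)
        scores = self._scores(rng)
        pvals = calibrate_pvalues(scores)
        x = -np.array([scores[g] for g in sorted(scores)])
        mu, beta = gumbel_fit_moments(x)
        expect = -np.expm1(-np.exp(-(x - mu) / beta))
        got = np.array([pvals[g] for g in sorted(scores)])
        assert got == pytest.approx(expect)
        # algebraic identity: at x = mu the upper tail is 1 - 1/e
        assert -np.expm1(-np.exp(0.0)) == pytest.approx(0.6321205588285577)

    def test_best_score_has_smallest_p_and_monotone(self):
        rng = np.random.default_rng(22)
        scores = self._scores(rng)
        pvals = calibrate_pvalues(scores)
        order_e = sorted(scores, key=scores.get)  # ascending e_total
        ps = [pvals[g] for g in order_e]
        assert ps == sorted(ps)
        assert all(0 < p <= 1 for p in ps)

    def test_no_hit_genes_get_p_one(self):
        rng = np.random.default_rng(23)
        scores = self._scores(rng, 30)
        scores["empty1"] = None
        scores["empty2"] = math.inf
        pvals = calibrate_pvalues(scores)
        assert pvals["empty1"] == 1.0 and pvals["empty2"] == 1.0

    def test_rank_fallback_uses_whole_candidate_set(self, caplog):
        # 10 finite scores among 200 genes: the strongest candidate beat
        # 199 others, so its empirical p is 1/201, not 1/11
        scores = {f"g{i}": None for i in range(190)}
        for i, e in enumerate(np.linspace(-20, -2, 10)):
            scores[f"hit{i}"] = float(e)
        with caplog.at_level("WARNING"):
            pvals = calibrate_pvalues(scores)
        assert "falling back" in caplog.text
        assert pvals["hit0"] == pytest.approx(1 / 201)
        assert pvals["hit9"] == pytest.approx(10 / 201)

    def test_zero_variance_falls_back(self):
        scores = {f"g{i}": -5.0 for i in range(40)}
        pvals = calibrate_pvalues(scores)
        assert all(p == pytest.approx(1 / 41) for p in pvals.values())


def _pred(gene, p, e):
    hit = DuplexHit((1, 4), (1, 4), ((1, 4), (2, 3), (3, 2), (4, 1)), e, 4)
    score = InteractionScore(e, 0.0, 0.0, e, 1.0)
    return TargetPrediction(gene, gene, "", hit, score, p)


class TestRankTargets:
    def test_empty_input(self):
        assert rank_targets([]) == []

    def test_sort_filter_and_tie_break(self):
        preds = [_pred("b", 0.01, -5.0), _pred("a", 0.01, -5.0),
                 _pred("c", 0.001, -9.0), _pred("d", 0.5, -2.0)]
        out = rank_targets(preds, threshold=0.05)
        assert [t.gene_id for t in out] == ["c", "a", "b"]
        assert [t.rank for t in out] == [1, 2, 3]

    def test_threshold_zero_reports_nothing(self):
        assert rank_targets([_pred("a", 1e-9, -20.0)], threshold=0.0) == []
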