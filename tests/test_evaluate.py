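"""Ranking scores, rank-enrichment voting, nearest-neighbor baseline,
classification benchmark and grid search."""

import numpy as np
import pytest

from structmotif.evaluate import (BenchmarkSpec, GRID_AXES, grid_points,
                                  grid_search, gc_matched_negatives,
                                  kmer_classification_benchmark,
                                  nearest_neighbor_predict,
                                  normalized_rank_score, rank_enrichment,
                                  rank_motif)
from structmotif.compare import NullModel
from structmotif.fixtures import make_motif_db, make_tf_family
from structmotif.potentials import FamilyConfig
from structmotif.pwm import Pwm


class TestNormalizedRankScore:
    def test_best_rank_in_cisbp_sized_database_scores_100(self):
        assert normalized_rank_score(1, 2638) == 100.0

    def test_mid_rank_scores_exactly_50(self):
        assert normalized_rank_score(1320, 2638) == 50.0

    def test_worst_rank(self):
        assert normalized_rank_score(2638, 2638) == pytest.approx(100 / 2638)

    def test_strictly_decreasing_in_rank(self):
        scores = [normalized_rank_score(r, 50) for r in range(1, 51)]
        assert all(a > b for a, b in zip(scores, scores[1:]))
        assert scores[0] == 100.0 and all(s < 100 for s in scores[1:])

    def test_out_of_range_rank_rejected(self):
        with pytest.raises(ValueError):
            normalized_rank_score(0, 10)
        with pytest.raises(ValueError):
            normalized_rank_score(11, 10)


class TestRankMotif:
    def test_true_motif_identical_to_prediction_ranks_first(
            self, motif_db, null_model):
        res = rank_motif(motif_db[3], motif_db, motif_db[3].id, null_model)
        assert res.rank == 1
        assert res.normalized == 100.0
        assert res.significant

    def test_nonsignificant_comparison_nulls_the_score(self, motif_db):
        null = NullModel(motif_db, m_null=200, seed=1)
        res = rank_motif(motif_db[0], motif_db, motif_db[5].id, null,
                         alpha=1e-9)
        assert not res.significant
        assert res.normalized == 0.0


class TestRankEnrichment:
    def test_unanimous_ensemble_returns_embedded_motif_at_100(
            self, motif_db, null_model):
        predicted = [motif_db[2]] * 100
        res = rank_enrichment(predicted, motif_db, true_id=motif_db[2].id,
                              top_k=1, alpha=0.5, null_model=null_model)
        assert res.winner == motif_db[2].id
        assert res.counts[motif_db[2].id] == 100
        assert res.normalized == 100.0
        assert res.coverage

    def test_true_motif_outside_topk_flags_no_coverage(self, motif_db,
                                                       null_model):
        predicted = [motif_db[2]] * 5
        res = rank_enrichment(predicted, motif_db, true_id="absent",
                              top_k=1, alpha=0.5, null_model=null_model)
        assert not res.coverage
        assert res.normalized is None

    def test_count_tie_broken_by_mean_similarity(self, motif_db,
                                                 null_model):
        # a single prediction puts every selected motif at count 1; the
        # winner must then be the most similar target (the query itself)
        res = rank_enrichment([motif_db[4]], motif_db,
                              true_id=motif_db[4].id, top_k=3, alpha=0.5,
                              null_model=null_model)
        assert res.winner == motif_db[4].id
        assert res.normalized == 100.0

    def test_single_prediction_degenerates_to_ranking(self, motif_db,
                                                      null_model):
        res = rank_enrichment([motif_db[1]], motif_db,
                              true_id=motif_db[1].id,
                              top_k=len(motif_db), alpha=0.5,
                              null_model=null_model)
        plain = rank_motif(motif_db[1], motif_db, motif_db[1].id,
                           null_model, alpha=0.5)
        assert res.true_rank == plain.rank == 1

    def test_empty_database_is_error(self):
        with pytest.raises(ValueError):
            rank_enrichment([Pwm(np.full((4, 4), 0.25))], [], true_id="x")


class TestNearestNeighbor:
    BASE = "MKRQWFDESAVLIHGNPTYC" * 3  # 60 residues

    def _mutant(self, n_diff, block=0):
        s = list(self.BASE)
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        for i in range(n_diff):
            pos = (7 * i + 3 + block) % len(s)
            cur = s[pos]
            s[pos] = alphabet[(alphabet.index(cur) + 1 + block) % 20]
        return "".join(s)

    def test_target_in_database_top_bin_returns_own_pwm(self):
        pwm = Pwm(np.full((8, 4), 0.25), id="own")
        db = [("self", self.BASE, pwm)]
        got = nearest_neighbor_predict(self.BASE, db, identity_bin=95)
        assert got is pwm

    def test_no_neighbor_in_bin_gives_no_prediction(self):
        pwm = Pwm(np.full((8, 4), 0.25), id="own")
        db = [("self", self.BASE, pwm)]
        assert nearest_neighbor_predict(self.BASE, db,
                                        identity_bin=45) is None
        assert nearest_neighbor_predict(self.BASE, db, identity_bin=45,
                                        mode="enrichment") == []

    def test_higher_identity_neighbor_wins_single_mode(self):
        from structmotif.pbm import sequence_identity
        near = self._mutant(23)        # ~62% identity
        far = self._mutant(25, block=1)  # ~58% identity
        id_near = sequence_identity(self.BASE, near)
        id_far = sequence_identity(self.BASE, far)
        assert 55 < id_far < id_near <= 65
        pwm_near = Pwm(np.full((8, 4), 0.25), id="near")
        pwm_far = Pwm(np.full((8, 4), 0.25), id="far")
        got = nearest_neighbor_predict(
            self.BASE, [("far", far, pwm_far), ("near", near, pwm_near)],
            identity_bin=65)
        assert got.id == "near"


@pytest.fixture(scope="module")
def family():
    return make_tf_family("FamA", 12, "ACGTGCAT", seed=7)


class TestClassificationBenchmark:
    def test_planted_family_separates_positives(self, family):
        spec = BenchmarkSpec(ratio=1 / 100, gc_matched=True, repeats=3,
                             folds=5, seed=11)
        out = kmer_classification_benchmark(family, spec)
        assert out["FamA"]["auroc_mean"] > 0.95

    def test_shuffled_labels_are_chance_level(self, family):
        spec = BenchmarkSpec(ratio=1 / 100, gc_matched=True, repeats=3,
                             folds=5, seed=11)
        out = kmer_classification_benchmark(family, spec,
                                            shuffle_labels=True)
        assert 0.45 <= out["FamA"]["auroc_mean"] <= 0.55

    def test_small_family_excluded_with_warning(self, family):
        spec = BenchmarkSpec(repeats=1, seed=1)
        with pytest.warns(UserWarning, match="fewer than 10"):
            out = kmer_classification_benchmark(family[:5], spec)
        assert out == {}

    def test_gc_matched_sampler_tracks_positive_composition(self):
        rng = np.random.default_rng(9)
        positives = {"GCGCGCGC", "GCGCATAT", "GGGGCCCC", "GCATGCAT"}
        negs = gc_matched_negatives(positives, 400, rng)
        gc_pos = np.mean([sum(b in "GC" for b in k) / 8
                          for k in positives])
        gc_neg = np.mean([sum(b in "GC" for b in k) / 8 for k in negs])
        assert abs(gc_pos - gc_neg) < 0.02

    def test_cv_folds_are_disjoint(self):
        from structmotif.evaluate import _cv_folds
        rng = np.random.default_rng(0)
        ids = [f"tf{i}" for i in range(17)]
        folds = _cv_folds(ids, 5, rng)
        seen = [t for f in folds for t in f]
        assert sorted(seen) == sorted(ids)  # every TF in exactly one fold


class TestGridSearch:
    def test_full_grid_has_1488_points(self):
        pts = grid_points()
        assert len(pts) == 2 * 2 * 2 * 2 * 3 * 31 == 1488
        assert len({(p.binning, p.taylor, p.contacts_db, p.specificity,
                     p.radius, p.threshold) for p in pts}) == 1488

    def test_uniform_accuracy_selects_lowest_threshold(self):
        best = grid_search(None, evaluate=lambda cfg, d: (5, 1.0))
        assert best.threshold == 0.70

    def test_single_point_grid_returned_unchanged(self):
        grid = {k: (v[0],) for k, v in GRID_AXES.items()}
        best = grid_search(None, grid=grid,
                           evaluate=lambda cfg, d: (0, 0.0))
        assert (best.binning, best.taylor, best.contacts_db,
                best.specificity, best.radius, best.threshold) == \
            ("bins", False, "pdb", "family", 15.0, 0.70)

    def test_accuracy_dominates_similarity_and_threshold(self):
        def ev(cfg, d):
            if cfg.radius == 22.0 and cfg.threshold == 0.90:
                return (9, 0.1)
            return (3, 5.0)
        best = grid_search(None, evaluate=ev)
        assert best.radius == 22.0 and best.threshold == 0.90

    def test_similar_counts_resolved_by_similarity(self):
        def ev(cfg, d):
            if cfg.threshold == 0.80:
                return (5, 2.0)   # within 1 of the max count
            if cfg.threshold == 0.90:
                return (6, 1.0)
            return (1, 9.9)
        best = grid_search(None, evaluate=ev)
        assert best.threshold == 0.80  # count 5 ~ 6, better similarity
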