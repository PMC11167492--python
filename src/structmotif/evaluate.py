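"""Benchmarking machinery: normalized ranking, rank-enrichment
(majority-vote) prediction, the nearest-neighbor baseline, the
positive/negative 8-mer classification protocol and the per-family
parameter grid search.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc, precision_recall_curve, roc_curve

from .compare import NullModel, compare_pwms, is_significant
from .pbm import sequence_identity
from .potentials import (FamilyConfig, Potential, build_potential,
                         contact_identity)
from .pwm import Pwm

# --------------------------------------------------------------------------
# normalized ranking
# --------------------------------------------------------------------------


def normalized_rank_score(rank: int, M: int) -> float:
    """normal score = 100 * (M - rank + 1) / M; rank 1 scores exactly 100."""
    if not 1 <= rank <= M:
        raise ValueError("rank must lie in [1, M]")
    return 100.0 * (M - rank + 1) / M


@dataclass
class RankingResult:
    target_tf: str
    M: int
    rank: int | None
    normalized: float
    significant: bool


def rank_motif(predicted: Pwm, database: list[Pwm], true_id: str,
               null_model: NullModel | None = None,
               alpha: float = 0.05) -> RankingResult:
    """Rank the true experimental motif among all database motifs by
    similarity to the predicted PWM.

    The normalized score is nulled (0, non-significant) when the
    comparison with the true motif itself fails the significance test.
    """
    if not database:
        raise ValueError("empty motif database")
    null_model = null_model or NullModel(database)
    matches = [compare_pwms(predicted, t, null_model) for t in database]
    matches.sort(key=lambda m: (-m.similarity_score, m.p_value, m.target_id))
    rank = next(i for i, m in enumerate(matches, 1)
                if m.target_id == true_id)
    true_match = next(m for m in matches if m.target_id == true_id)
    sig = is_significant(true_match, alpha)
    score = normalized_rank_score(rank, len(database)) if sig else 0.0
    return RankingResult(true_id, len(database), rank, score, sig)


# --------------------------------------------------------------------------
# rank-enrichment (majority-vote) prediction
# --------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    counts: dict[str, int]
    winner: str | None
    true_rank: int | None
    normalized: float | None
    coverage: bool
    significant: bool = True


def rank_enrichment(predicted_pwms: list[Pwm], database: list[Pwm],
                    true_id: str | None = None, top_k: int = 10,
                    alpha: float = 0.05,
                    null_model: NullModel | None = None) -> EnrichmentResult:
    """Majority-vote motif prediction over an ensemble of predicted PWMs.

    Every predicted PWM is compared with the whole database;
    non-significant alignments are dropped and the ``top_k`` best targets
    by similarity are selected.  Selection counts accumulate per database
    motif; the winner is the most-often-selected one (ties: higher mean
    similarity, then lexical id).  When a true motif id is given, its rank
    among the counts yields the normalized rank-enrichment; if it never
    enters any top-k the prediction has no coverage and is neglected.
    """
    if not database:
        raise ValueError("empty motif database")
    if not predicted_pwms:
        raise ValueError("need at least one predicted PWM")
    null_model = null_model or NullModel(database)
    counts: Counter[str] = Counter()
    sims: defaultdict[str, list[float]] = defaultdict(list)
    for q in predicted_pwms:
        matches = [compare_pwms(q, t, null_model) for t in database]
        matches = [m for m in matches if is_significant(m, alpha)]
        matches.sort(key=lambda m: (-m.similarity_score, m.target_id))
        for m in matches[:top_k]:
            counts[m.target_id] += 1
            sims[m.target_id].append(m.similarity_score)
    def sort_key(tid):
        return (-counts[tid], -float(np.mean(sims[tid])), tid)
    ranked = sorted(counts, key=sort_key)
    winner = ranked[0] if ranked else None
    if true_id is None:
        return EnrichmentResult(dict(counts), winner, None, None,
                                coverage=bool(ranked))
    if true_id not in counts:
        return EnrichmentResult(dict(counts), winner, None, None,
                                coverage=False)
    rank = ranked.index(true_id) + 1
    return EnrichmentResult(dict(counts), winner, rank,
                            normalized_rank_score(rank, len(database)),
                            coverage=True)


# --------------------------------------------------------------------------
# nearest-neighbor baseline
# --------------------------------------------------------------------------

IDENTITY_BINS = tuple(range(15, 96, 10))  # 15, 25, ..., 95 (% identity)


def nearest_neighbor_predict(target_seq: str,
                             database: list[tuple[str, str, Pwm]],
                             identity_bin: int,
                             mode: str = "single"):
    """Motif transfer from the most sequence-similar TF(s).

    ``database`` holds (tf_id, protein sequence, experimental PWM).
    Identity = identical residues / global-alignment length (percent).
    Bin x covers identities in (x - 10, x]; the top bin (95) extends to
    100 so a perfect match to itself stays predictable.  ``single`` mode
    returns the in-bin neighbor of highest identity; ``enrichment`` mode
    returns all in-bin motifs (to feed the rank-enrichment vote).
    Returns None / empty list when no neighbor falls in the bin.
    """
    if not database:
        raise ValueError("empty nearest-neighbor database")
    lo, hi = identity_bin - 10, identity_bin
    if identity_bin >= 95:
        hi = 100.0
    in_bin = []
    for tf_id, seq, pwm in database:
        ident = sequence_identity(target_seq, seq)
        if lo < ident <= hi:
            in_bin.append((ident, tf_id, pwm))
    if not in_bin:
        return None if mode == "single" else []
    if mode == "single":
        in_bin.sort(key=lambda t: (-t[0], t[1]))
        return in_bin[0][2]
    return [pwm for _, _, pwm in sorted(in_bin, key=lambda t: (-t[0], t[1]))]


# --------------------------------------------------------------------------
# positive/negative 8-mer classification benchmark
# --------------------------------------------------------------------------


@dataclass
class BenchmarkSpec:
    ratio: float = 1 / 100      # positives : negatives
    gc_matched: bool = True
    repeats: int = 10
    folds: int = 5
    seed: int = 0


@dataclass
class SyntheticTf:
    """One synthetic TF for the classification benchmark: its family, the
    interface template used to thread 8-mers, its training contact table
    and its positive 8-mers."""
    tf_id: str
    family: str
    template: list[tuple[str, object, float, int]]  # (aa, env, distance, step)
    table: object                                   # ContactTable
    positives: set[str]


def score_kmer(potential: Potential, template, kmer: str) -> float:
    """Thread an 8-mer onto a TF interface template and sum per-contact
    Z-scores (lower = stronger predicted binding)."""
    z = 0.0
    for aa, env, distance, step in template:
        if distance >= potential.max_radius:
            continue
        dinuc = kmer[step:step + 2]
        z += potential.zscore(aa, dinuc, env, distance)
    return z


def _random_kmers(n: int, rng: np.random.Generator,
                  exclude: set[str]) -> list[str]:
    out: list[str] = []
    seen = set(exclude)
    while len(out) < n:
        k = "".join("ACGT"[i] for i in rng.integers(0, 4, 8))
        if k not in seen:
            seen.add(k)
            out.append(k)
    return out


def gc_matched_negatives(positives: set[str], n: int,
                         rng: np.random.Generator) -> list[str]:
    """Random 8-mers whose G+C counts are drawn from the positives' G+C
    distribution (so the negative set matches the positives' composition)."""
    gc_counts = sorted(sum(b in "GC" for b in k) for k in positives)
    out: list[str] = []
    seen = set(positives)
    # fix the G+C classes by quota from the positives' distribution, then
    # draw a novel 8-mer within each class, so neither duplicate rejection
    # nor class sampling noise can bias the composition
    classes = np.array(gc_counts * (n // len(gc_counts)) +
                       list(rng.choice(gc_counts, n % len(gc_counts),
                                       replace=False))
                       if n % len(gc_counts) else
                       gc_counts * (n // len(gc_counts)))
    rng.shuffle(classes)
    for gc in classes:
        gc = int(gc)
        for _ in range(10000):
            pos = list(rng.permutation(8))
            k = ["A"] * 8
            for p in pos[:gc]:
                k[p] = "GC"[rng.integers(0, 2)]
            for p in pos[gc:]:
                k[p] = "AT"[rng.integers(0, 2)]
            kmer = "".join(k)
            if kmer not in seen:
                seen.add(kmer)
                out.append(kmer)
                break
        else:
            raise RuntimeError(f"G+C class {gc} exhausted while sampling "
                               "negatives")
    return out


def _cv_folds(ids: list[str], n_folds: int,
              rng: np.random.Generator) -> list[list[str]]:
    perm = list(rng.permutation(ids))
    return [perm[i::n_folds] for i in range(n_folds)]


def kmer_classification_benchmark(tfs: list[SyntheticTf],
                                  spec: BenchmarkSpec,
                                  config: FamilyConfig | None = None,
                                  identity_cutoff: float = 0.70,
                                  shuffle_labels: bool = False) -> dict:
    """AUROC / AUPRC of the potential at separating positive from negative
    8-mers, per family.

    Per repeat, negatives are sampled at the requested positive:negative
    ratio (G+C-matched or random); a cross-validation over TFs trains the
    potential on the other folds only, additionally excluding any training
    TF whose contact fingerprint is more than ``identity_cutoff`` identical
    to a test TF.  Families with fewer than 10 TFs are excluded.  Scores
    are the negated summed Z-scores; areas use trapezoidal integration.
    ``shuffle_labels`` permutes the labels within each evaluation as a null
    control.
    """
    config = config or FamilyConfig(binning="bins", radius=30.0,
                                    contacts_db="pdb", threshold=0.95)
    by_family: defaultdict[str, list[SyntheticTf]] = defaultdict(list)
    for tf in tfs:
        by_family[tf.family].append(tf)
    results = {}
    for family, members in sorted(by_family.items()):
        if len(members) < 10:
            warnings.warn(f"family {family}: fewer than 10 TFs, excluded")
            continue
        tf_by_id = {t.tf_id: t for t in members}
        fps = {t.tf_id: t.table.fingerprint() for t in members}
        aurocs, auprcs = [], []
        for rep in range(spec.repeats):
            rng = np.random.default_rng(
                (spec.seed * 7919 + rep * 104729) % (2 ** 31))
            folds = _cv_folds(sorted(tf_by_id), spec.folds, rng)
            y_true_all, y_score_all = [], []
            for f, test_ids in enumerate(folds):
                train_ids = [t for ff, fold in enumerate(folds) if ff != f
                             for t in fold]
                table = None
                for tid in train_ids:
                    if any(contact_identity(fps[tid], fps[s]) >
                           identity_cutoff for s in test_ids):
                        continue
                    if table is None:
                        table = tf_by_id[tid].table.copy()
                    else:
                        table += tf_by_id[tid].table
                if table is None or table.total == 0:
                    continue
                potential = build_potential(table, config)
                for tid in test_ids:
                    tf = tf_by_id[tid]
                    n_neg = max(int(round(len(tf.positives) / spec.ratio)), 1)
                    if spec.gc_matched:
                        negs = gc_matched_negatives(tf.positives, n_neg, rng)
                    else:
                        negs = _random_kmers(n_neg, rng, tf.positives)
                    kmers = sorted(tf.positives) + negs
                    labels = [1] * len(tf.positives) + [0] * len(negs)
                    scores = [-score_kmer(potential, tf.template, k)
                              for k in kmers]
                    y_true_all.extend(labels)
                    y_score_all.extend(scores)
            if not y_true_all or len(set(y_true_all)) < 2:
                continue
            y = np.asarray(y_true_all)
            s = np.asarray(y_score_all)
            if shuffle_labels:
                y = rng.permutation(y)
            fpr, tpr, _ = roc_curve(y, s)
            aurocs.append(auc(fpr, tpr))
            prec, rec, _ = precision_recall_curve(y, s)
            order = np.argsort(rec)
            auprcs.append(auc(rec[order], prec[order]))
        results[family] = {
            "auroc_mean": float(np.mean(aurocs)),
            "auroc_sd": float(np.std(aurocs)),
            "auprc_mean": float(np.mean(auprcs)),
            "auprc_sd": float(np.std(auprcs)),
            "n_tfs": len(members),
            "n_repeats": len(aurocs),
        }
    return results


# --------------------------------------------------------------------------
# grid search
# --------------------------------------------------------------------------

GRID_AXES = {
    "binning": ("bins", "acc"),
    "taylor": (False, True),
    "contacts_db": ("pdb", "pbm"),
    "specificity": ("family", "general"),
    "radius": (15.0, 22.0, 30.0),
    "threshold": tuple(round(0.70 + 0.01 * i, 2) for i in range(31)),
}


def grid_points(grid: dict | None = None) -> list[FamilyConfig]:
    """All configurations of the parameter grid (full grid: 2 x 2 x 2 x 2
    x 3 x 31 = 1488 points), in deterministic axis order."""
    grid = {**GRID_AXES, **(grid or {})}
    keys = ("binning", "taylor", "contacts_db", "specificity", "radius",
            "threshold")
    return [FamilyConfig(family="grid",
                         binning=b, taylor=t, contacts_db=c,
                         specificity=s, radius=r, threshold=th)
            for b, t, c, s, r, th in itertools.product(
                *(grid[k] for k in keys))]


def grid_search(family_data, grid: dict | None = None, evaluate=None,
                count_tolerance: int = 1,
                score_tolerance: float = 1e-9) -> FamilyConfig:
    """Pick the per-family configuration maximizing prediction accuracy.

    ``evaluate(config, family_data) -> (n_significant, mean_similarity)``
    scores one grid point (the default runs the full PWM-prediction
    pipeline via :func:`evaluate_config`).  Selection applies, in order:
    (i) the maximum number of significant predictions, (ii) the best mean
    similarity among points whose counts are within ``count_tolerance`` of
    the maximum, (iii) the lowest threshold among score-tied points, then
    grid order for full determinism.
    """
    points = grid_points(grid)
    evaluate = evaluate or evaluate_config
    scored = [(cfg, *evaluate(cfg, family_data)) for cfg in points]
    cmax = max(s[1] for s in scored)
    cand = [s for s in scored if s[1] >= cmax - count_tolerance]
    smax = max(s[2] for s in cand)
    cand = [s for s in cand if s[2] >= smax - score_tolerance]
    cand.sort(key=lambda s: s[0].threshold)
    return cand[0][0]


def evaluate_config(config: FamilyConfig, family_data) -> tuple[int, float]:
    """Accuracy of one grid point: predict a PWM per family member under
    the configuration and count significant matches to the experimental
    motif.

    ``family_data`` is a list of dicts with keys ``table`` (ContactTable),
    ``contacts`` (interface contacts), ``experimental`` (Pwm) and
    optionally ``null_model``.
    """
    from .pwm import build_pwm, score_sequences_from_steps, step_score_matrix

    n_sig = 0
    sims = []
    for rec in family_data:
        potential = build_potential(rec["table"], config)
        contacts = [c for c in rec["contacts"]
                    if c.distance < config.radius]
        if not contacts:
            continue
        E, _ = step_score_matrix(rec.get("complex"), potential,
                                 contacts=contacts)
        scored = score_sequences_from_steps(E, mode="exhaustive")
        pwm = build_pwm(scored, threshold=config.threshold)
        match = compare_pwms(pwm, rec["experimental"],
                             rec.get("null_model"))
        sims.append(match.similarity_score)
        if is_significant(match):
            n_sig += 1
    return n_sig, float(np.mean(sims)) if sims else 0.0
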