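"""Motif-motif comparison with an empirical null (TOMTOM-equivalent
contract).

Two PWMs are aligned ungapped over every offset with at least four
overlapping columns, in both orientations (the target may be
reverse-complemented); the alignment score is the summed Pearson
correlation of the overlapping probability columns.  Significance is the
probability that a random motif of the query's width -- columns resampled
from a Dirichlet fitted to the target database -- aligns as well or better
against the target, and the similarity score is -log10 of that p-value.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .pwm import Pwm


@dataclass
class MotifMatch:
    query_id: str
    target_id: str
    offset: int
    orientation: str       # + / -
    score: float           # summed column Pearson correlation
    p_value: float
    similarity_score: float  # -log10(p_value)


def _column_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two probability 4-vectors (0 if either is
    constant, e.g. uniform)."""
    da = a - a.mean()
    db = b - b.mean()
    na = np.sqrt(da @ da)
    nb = np.sqrt(db @ db)
    if na < 1e-12 or nb < 1e-12:
        return 0.0
    return float(da @ db / (na * nb))


def alignment_optimum(query: Pwm, target: Pwm,
                      overlap_min: int = 4) -> tuple[float, int, str]:
    """Best ungapped alignment over all offsets and both orientations.

    Offset o places query column 0 under target column o.  Ties break by
    smaller |offset|, then forward orientation.  Returns
    (score, offset, orientation).
    """
    ov_min = overlap_min
    best = None
    for orientation, tgt in (("+", target), ("-", target.reverse_complement())):
        for off in range(-(query.width - ov_min),
                         tgt.width - ov_min + 1):
            lo = max(0, off)
            hi = min(tgt.width, off + query.width)
            if hi - lo < ov_min:
                continue
            score = sum(_column_correlation(query.matrix[j - off], tgt.matrix[j])
                        for j in range(lo, hi))
            key = (-score, abs(off), orientation != "+")
            if best is None or key < best[0]:
                best = (key, score, off, orientation)
    if best is None:
        raise ValueError("no alignment with the required overlap")
    return best[1], best[2], best[3]


class NullModel:
    """Resampled-motif null for alignment significance.

    Random motifs of a given width draw their columns i.i.d. from a
    Dirichlet whose parameters are fitted (method of moments) to the
    columns of a motif database; null optima are cached per
    (width, target id).
    """

    def __init__(self, database: list[Pwm] | None = None,
                 m_null: int = 200, seed: int = 0,
                 alpha: np.ndarray | None = None):
        if alpha is not None:
            self.alpha = np.asarray(alpha, float)
        elif database:
            cols = np.vstack([p.matrix for p in database])
            mean = cols.mean(axis=0)
            var = cols.var(axis=0)
            # method of moments: alpha0 from the average variance
            with np.errstate(divide="ignore", invalid="ignore"):
                s = mean * (1 - mean) / np.maximum(var, 1e-9) - 1
            alpha0 = max(float(np.mean(s[np.isfinite(s)])), 0.1)
            self.alpha = np.maximum(mean * alpha0, 1e-2)
        else:
            self.alpha = np.ones(4)
        self.m_null = int(m_null)
        self.seed = int(seed)
        self._cache: dict[tuple[int, str], np.ndarray] = {}

    def sample_motif(self, width: int, rng: np.random.Generator) -> Pwm:
        return Pwm(rng.dirichlet(self.alpha, size=width), id="null")

    def null_optima(self, width: int, target: Pwm,
                    overlap_min: int = 4) -> np.ndarray:
        key = (width, target.id)
        if key not in self._cache:
            rng = np.random.default_rng(
                (self.seed * 1000003 + width * 8191
                 + zlib.crc32(target.id.encode())) % (2 ** 31))
            vals = np.array([
                alignment_optimum(self.sample_motif(width, rng), target,
                                  overlap_min)[0]
                for _ in range(self.m_null)])
            self._cache[key] = vals
        return self._cache[key]


def compare_pwms(query: Pwm, target: Pwm,
                 null_model: NullModel | None = None,
                 overlap_min: int = 4) -> MotifMatch:
    """Optimal alignment of two PWMs plus its empirical p-value.

    p = (1 + #{null optima >= observed}) / (M_null + 1), where the null
    motifs share the query's width; similarity score = -log10(p).
    """
    null_model = null_model or NullModel()
    score, offset, orientation = alignment_optimum(query, target,
                                                   overlap_min)
    nulls = null_model.null_optima(query.width, target, overlap_min)
    p = (1.0 + float((nulls >= score - 1e-12).sum())) / (len(nulls) + 1.0)
    return MotifMatch(query.id, target.id, offset, orientation, score, p,
                      float(-np.log10(p)))


def is_significant(match: MotifMatch, alpha: float = 0.05) -> bool:
    """Strictly below alpha (p = alpha is not significant)."""
    return match.p_value < alpha


def compare_batch(queries: list[Pwm], targets: list[Pwm],
                  null_model: NullModel | None = None,
                  overlap_min: int = 4) -> list[MotifMatch]:
    null_model = null_model or NullModel(targets)
    return [compare_pwms(q, t, null_model, overlap_min)
            for q in queries for t in targets]


def matches_to_tsv(matches: list[MotifMatch]) -> str:
    lines = ["query\ttarget\toffset\tstrand\tscore\tp_value\tsimilarity"]
    for m in matches:
        lines.append(f"{m.query_id}\t{m.target_id}\t{m.offset}\t"
                     f"{m.orientation}\t{m.score:.4f}\t{m.p_value:.6g}\t"
                     f"{m.similarity_score:.4f}")
    return "\n".join(lines) + "\n"


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted q-values (utility for batch output; off by default)."""
    p = np.asarray(pvalues, float)
    n = len(p)
    order = np.argsort(p)
    q = np.empty(n)
    prev = 1.0
    for rank_rev, idx in enumerate(order[::-1]):
        rank = n - rank_rev
        prev = min(prev, p[idx] * n / rank)
        q[idx] = prev
    return q
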