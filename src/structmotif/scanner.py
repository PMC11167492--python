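"""PWM scanning with exact p-values and the binned majority-vote binding
caller used for ChIP-exo-style validation.

Scanning mirrors the FIMO contract: a log-odds score at every position of
both strands, with the p-value of a score taken from the exact discrete
distribution of PWM scores under the background (computed by dynamic
programming over columns with 1/1000 score discretization).  For the
binding-site caller, a 420-nt window centred on the true binding start is
cut into 21 bins of 20 nt; each PWM of an ensemble votes once, in the bin
its best hit covers most, and the bin(s) with the most votes are called
positive.  The central bin (11) holds the true site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pwm import Pwm

SCORE_STEP = 1e-3   # discretization of the p-value dynamic programme

N_BINS = 21
BIN_WIDTH = 20
WINDOW = N_BINS * BIN_WIDTH   # 420 nt
TRUE_BIN = 11                 # central bin, positions 201-220 (1-based)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class ScanHit:
    pwm_id: str
    sequence_id: str
    start: int      # 1-based, inclusive
    end: int
    strand: str
    score: float    # log-odds (base 2)
    p_value: float


class ScoreDistribution:
    """Exact distribution of PWM log-odds scores under the background.

    Column scores are discretized to ``SCORE_STEP`` and the integer score
    pmf is built by convolving one column at a time (each base weighted by
    its background probability).  ``pvalue(s)`` is P(score >= s) for a
    random background word.
    """

    def __init__(self, log_odds: np.ndarray, background: np.ndarray,
                 step: float = SCORE_STEP):
        self.step = step
        iscores = np.round(log_odds / step).astype(np.int64)
        offset = 0
        pmf = np.array([1.0])
        for j in range(iscores.shape[0]):
            col = iscores[j]
            lo, hi = int(col.min()), int(col.max())
            new = np.zeros(len(pmf) + (hi - lo))
            for b in range(4):
                sh = int(col[b]) - lo
                new[sh:sh + len(pmf)] += background[b] * pmf
            pmf = new
            offset += lo
        self.offset = offset          # integer score of pmf[0]
        self.pmf = pmf
        # survival function: P(score >= s)
        self.sf = np.cumsum(pmf[::-1])[::-1]

    def pvalue(self, score: float) -> float:
        i = int(np.round(score / self.step)) - self.offset
        if i < 0:
            return 1.0
        if i >= len(self.sf):
            return 0.0
        return float(self.sf[i])


def log_odds_matrix(pwm: Pwm, background: np.ndarray | None = None,
                    eps: float = 1e-4) -> np.ndarray:
    bg = pwm.background if background is None else np.asarray(background)
    return np.log2(np.maximum(pwm.matrix, eps) / bg)


def scan(pwm: Pwm, sequence: str, alpha: float = 5e-4,
         sequence_id: str = "seq",
         background: np.ndarray | None = None) -> list[ScanHit]:
    """Scan a sequence with a PWM on both strands.

    Every position gets a log-odds score; hits with exact p-value < alpha
    are returned sorted by (p, start).  ``N`` bases contribute zero
    log-odds (background-neutral).  Sequences shorter than the PWM give an
    empty list.
    """
    sequence = sequence.upper()
    w = pwm.width
    if len(sequence) < w or alpha <= 0:
        return []
    bg = pwm.background if background is None else np.asarray(background)
    lo_fwd = log_odds_matrix(pwm, bg)
    dist = ScoreDistribution(lo_fwd, bg)
    hits = []
    for strand in ("+", "-"):
        lo = lo_fwd if strand == "+" else \
            log_odds_matrix(pwm.reverse_complement(), bg)
        for start in range(len(sequence) - w + 1):
            word = sequence[start:start + w]
            s = 0.0
            for j, b in enumerate(word):
                if b in _BASE_INDEX:
                    s += lo[j, _BASE_INDEX[b]]
            p = dist.pvalue(s)
            if p < alpha:
                hits.append(ScanHit(pwm.id, sequence_id, start + 1,
                                    start + w, strand, float(s), p))
    hits.sort(key=lambda h: (h.p_value, h.start, h.strand))
    return hits


def hits_to_tsv(hits: list[ScanHit]) -> str:
    lines = ["pwm\tsequence\tstart\tend\tstrand\tscore\tp_value"]
    for h in hits:
        lines.append(f"{h.pwm_id}\t{h.sequence_id}\t{h.start}\t{h.end}\t"
                     f"{h.strand}\t{h.score:.4f}\t{h.p_value:.6g}")
    return "\n".join(lines) + "\n"


def hits_to_bed(hits: list[ScanHit]) -> str:
    lines = []
    for h in hits:
        lines.append(f"{h.sequence_id}\t{h.start - 1}\t{h.end}\t{h.pwm_id}"
                     f"\t{h.score:.2f}\t{h.strand}")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# binned majority-vote calling
# --------------------------------------------------------------------------


@dataclass
class BinProfile:
    sequence_id: str
    counts: np.ndarray           # votes per bin, index 0 = bin 1
    positive_bins: list[int]     # 1-based bins with the maximal count
    true_bin: int = TRUE_BIN

    @property
    def true_positive(self) -> bool:
        return self.true_bin in self.positive_bins

    def confusion(self) -> dict[str, int]:
        """TP/FP/FN/TN over the 21 bins: the true bin is the single real
        positive; every other called bin is a false positive."""
        tp = int(self.true_positive)
        fp = len(self.positive_bins) - tp
        fn = 1 - tp
        tn = (N_BINS - 1) - fp
        return {"TP": tp, "FP": fp, "FN": fn, "TN": tn}


def _bin_overlap(start: int, end: int, b: int) -> int:
    """Overlap (nt) of a 1-based hit interval with bin b
    ([20(b-1)+1, 20b])."""
    lo = BIN_WIDTH * (b - 1) + 1
    hi = BIN_WIDTH * b
    return max(0, min(end, hi) - max(start, lo) + 1)


def assign_bin(hit: ScanHit) -> int:
    """Bin of a hit: the bin with the largest coverage of the hit
    (ties go to the lower bin index)."""
    overlaps = [( _bin_overlap(hit.start, hit.end, b), -b)
                for b in range(1, N_BINS + 1)]
    best = max(overlaps)
    return -best[1]


def bin_profile(hits_per_pwm: dict[str, list[ScanHit]],
                sequence_id: str = "seq") -> BinProfile:
    """Vote profile of a PWM ensemble over the 21-bin window.

    Each PWM contributes a single vote: its best hit (lowest p-value,
    ties by score then leftmost) lands in the bin covering most of it.
    Positive bins are those with the maximal vote count.
    """
    counts = np.zeros(N_BINS, dtype=int)
    for pwm_id, hits in hits_per_pwm.items():
        in_window = [h for h in hits if h.start <= WINDOW and h.end >= 1]
        if not in_window:
            continue
        best = min(in_window,
                   key=lambda h: (h.p_value, -h.score, h.start, h.strand))
        counts[assign_bin(best) - 1] += 1
    if counts.max() > 0:
        positives = [b + 1 for b in range(N_BINS)
                     if counts[b] == counts.max()]
    else:
        positives = []
    return BinProfile(sequence_id, counts, positives)


def chipexo_roc(experiments: list[dict[str, list[ScanHit]]],
                alphas: np.ndarray | None = None) -> dict:
    """Averaged ROC over ChIP-exo-style experiments.

    Each experiment maps pwm_id -> all scan hits of that PWM over its
    420-nt window (unthresholded).  For every alpha in the sweep, hits
    with p < alpha are kept, the majority-vote profile is built and the
    bin confusion counted; TPR/FPR curves are averaged over experiments
    with standard error sigma / sqrt(N).  Requires >= 2 experiments.
    """
    if len(experiments) < 2:
        raise ValueError("need at least 2 experiments for a standard error")
    if alphas is None:
        alphas = np.concatenate([[0.0], np.logspace(-6, 0, 25)])
    alphas = np.asarray(alphas, float)
    tprs = np.zeros((len(experiments), len(alphas)))
    fprs = np.zeros_like(tprs)
    for e, exp in enumerate(experiments):
        for a, alpha in enumerate(alphas):
            filtered = {pid: [h for h in hits if h.p_value < alpha]
                        for pid, hits in exp.items()}
            conf = bin_profile(filtered).confusion()
            tprs[e, a] = conf["TP"] / max(conf["TP"] + conf["FN"], 1)
            fprs[e, a] = conf["FP"] / max(conf["FP"] + conf["TN"], 1)
    n = len(experiments)
    mean_tpr = tprs.mean(axis=0)
    mean_fpr = fprs.mean(axis=0)
    se_tpr = tprs.std(axis=0) / np.sqrt(n)
    se_fpr = fprs.std(axis=0) / np.sqrt(n)
    order = np.argsort(mean_fpr, kind="stable")
    fx = np.concatenate([[0.0], mean_fpr[order], [1.0]])
    fy = np.concatenate([[0.0], mean_tpr[order], [1.0]])
    auroc = float(np.trapezoid(fy, fx))
    return {"alphas": alphas, "mean_tpr": mean_tpr, "mean_fpr": mean_fpr,
            "se_tpr": se_tpr, "se_fpr": se_fpr, "auroc": auroc,
            "n_experiments": n}
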