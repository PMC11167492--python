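"""Position weight matrices and structure-based PWM prediction.

The prediction engine threads every candidate DNA sequence of the binding
site through the interface contacts of a TF-DNA complex, scores each with
the summed per-contact Z-score of the statistical potential (lower =
better), min-max normalizes so the best sequence scores 1, and builds the
PWM from the top-scoring sequences.  Because the score decomposes over
adjacent dinucleotide steps, the exact top-K can also be obtained by
dynamic programming over a 16-state chain instead of enumerating all 4^N
sequences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_IDX = [3, 2, 1, 0]  # A<->T, C<->G in ACGT order


class PwmError(ValueError):
    pass


@dataclass
class Pwm:
    """Position probability matrix: ``matrix[j, b]`` = P(base b at column j),
    bases ordered A, C, G, T.  Columns must sum to 1."""

    matrix: np.ndarray
    id: str = "motif"
    source: str = "predicted"            # predicted | experimental
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    counts: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise PwmError("PWM matrix must have shape (width, 4)")
        if self.matrix.shape[0] < 1:
            raise PwmError("PWM must have at least one column")
        if np.any(self.matrix < 0):
            raise PwmError("PWM probabilities must be >= 0")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            raise PwmError("PWM column does not sum to 1")
        self.matrix = self.matrix / sums[:, None]
        self.background = np.asarray(self.background, dtype=float)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "Pwm":
        m = self.matrix[::-1, :][:, _COMPLEMENT_IDX]
        return Pwm(m, id=self.id + "_rc", source=self.source,
                   background=self.background)

    def log_likelihood(self, seq: str, eps: float = 1e-9) -> float:
        if len(seq) != self.width:
            raise PwmError("sequence length does not match PWM width")
        idx = [_BASE_INDEX[b] for b in seq]
        return float(np.log(self.matrix[np.arange(self.width), idx]
                            + eps).sum())


def reverse_complement(seq: str) -> str:
    comp = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


# --------------------------------------------------------------------------
# MEME minimal motif format
# --------------------------------------------------------------------------


def write_meme(pwms, background: np.ndarray | None = None) -> str:
    """Serialize PWMs in MEME minimal motif format (6-decimal precision)."""
    pwms = list(pwms)
    if background is None:
        background = pwms[0].background if pwms else np.full(4, 0.25)
    out = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", "",
           "Background letter frequencies",
           " ".join(f"{b} {f:.6f}" for b, f in zip(BASES, background)), ""]
    for p in pwms:
        out.append(f"MOTIF {p.id}")
        out.append(f"letter-probability matrix: alength= 4 w= {p.width} "
                   f"nsites= 20 E= 0")
        for row in p.matrix:
            out.append(" ".join(f"{v:.6f}" for v in row))
        out.append("")
    return "\n".join(out) + "\n"


def read_meme(text: str) -> list[Pwm]:
    """Parse a MEME minimal motif file into a list of PWMs.

    Raises :class:`PwmError` with the offending line number on malformed
    headers or on probability rows that do not sum to 1.
    """
    lines = text.splitlines()
    if not any(ln.strip().startswith("MEME version") for ln in lines):
        raise PwmError("line 1: not a MEME minimal file (missing "
                       "'MEME version' header)")
    background = np.full(4, 0.25)
    pwms: list[Pwm] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            if i < len(lines):
                toks = lines[i].split()
                try:
                    freqs = {toks[k]: float(toks[k + 1])
                             for k in range(0, len(toks), 2)}
                    background = np.array([freqs.get(b, 0.25) for b in BASES])
                except (ValueError, IndexError):
                    raise PwmError(
                        f"line {i + 1}: malformed background frequencies")
        elif line.startswith("MOTIF"):
            toks = line.split()
            if len(toks) < 2:
                raise PwmError(f"line {i + 1}: MOTIF header without id")
            motif_id = toks[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                    "letter-probability matrix"):
                if lines[i].strip().startswith("MOTIF"):
                    raise PwmError(f"line {i + 1}: motif {motif_id} has no "
                                   "letter-probability matrix")
                i += 1
            if i >= len(lines):
                raise PwmError(f"motif {motif_id}: missing matrix header")
            header = lines[i].strip()
            m = re.search(r"w=\s*(\d+)", header)
            if m is None:
                raise PwmError(f"line {i + 1}: matrix header lacks width")
            width = int(m.group(1))
            rows = []
            for k in range(width):
                i += 1
                if i >= len(lines):
                    raise PwmError(f"motif {motif_id}: truncated matrix")
                vals = lines[i].split()
                if len(vals) != 4:
                    raise PwmError(f"line {i + 1}: expected 4 probabilities")
                row = [float(v) for v in vals]
                if abs(sum(row) - 1.0) > 1e-3:
                    raise PwmError(
                        f"line {i + 1}: probabilities sum to {sum(row):g}, "
                        "not 1 (normalization error)")
                rows.append(row)
            pwms.append(Pwm(np.asarray(rows), id=motif_id,
                            source="experimental", background=background))
        i += 1
    return pwms


# --------------------------------------------------------------------------
# candidate sequence scoring
# --------------------------------------------------------------------------


@dataclass
class ScoredSequence:
    sequence: str
    raw: float
    normalized: float = 0.0
    rank: int = 0


def step_score_matrix(cx, potential, contacts=None) -> tuple[np.ndarray, int]:
    """Per-step dinucleotide Z-score matrix of a complex.

    Returns ``(E, first_step)`` where ``E[k, d]`` is the summed per-contact
    Z-score at interface step ``first_step + k`` if its dinucleotide were
    ``d``; the binding site spans the contiguous range of contacted steps.
    """
    from .contacts import extract_contacts
    if contacts is None:
        contacts = extract_contacts(cx, max_radius=potential.max_radius)
    contacts = [c for c in contacts if c.distance < potential.max_radius]
    if not contacts:
        raise ValueError("no interface contacts within the potential radius")
    steps = sorted({c.step_index for c in contacts})
    first, last = steps[0], steps[-1]
    n_steps = last - first + 1
    E = np.zeros((n_steps, 16))
    for c in contacts:
        k = c.step_index - first
        E[k] += potential.zscore_vector_dinuc(c.aa, c.env, c.distance)
    return E, first


def _normalize(scored: list[ScoredSequence]) -> list[ScoredSequence]:
    """Min-max normalize so the best (lowest-energy) sequence scores 1.

    If every sequence ties, all get normalized score 1 so that threshold
    selection stays meaningful.
    """
    raws = np.array([s.raw for s in scored])
    lo, hi = raws.min(), raws.max()
    if hi - lo < 1e-12:
        norm = np.ones_like(raws)
    else:
        norm = (hi - raws) / (hi - lo)
    order = np.lexsort((np.array([s.sequence for s in scored]), raws))
    for i, s in enumerate(scored):
        s.normalized = float(norm[i])
    for r, i in enumerate(order, start=1):
        scored[i].rank = r
    scored.sort(key=lambda s: s.rank)
    return scored


def enumerate_and_score(cx, potential, mode: str = "exhaustive",
                        k: int | None = None,
                        contacts=None) -> list[ScoredSequence]:
    """Score candidate binding-site sequences with the summed per-contact
    Z-score (ZES3DC_dd).

    ``mode="exhaustive"`` scores all 4^N sequences of the N-nucleotide site
    (N <= 12); ``mode="dp_topk"`` returns the exact best ``k`` sequences by
    K-best dynamic programming over the dinucleotide-step chain.
    """
    E, _ = step_score_matrix(cx, potential, contacts)
    return score_sequences_from_steps(E, mode=mode, k=k)


def score_sequences_from_steps(E: np.ndarray, mode: str = "exhaustive",
                               k: int | None = None) -> list[ScoredSequence]:
    """Core engine over a per-step (n_steps, 16) dinucleotide score matrix."""
    n_steps = E.shape[0]
    n = n_steps + 1  # binding-site length in nucleotides
    if n < 1:
        raise ValueError("binding site must have length >= 1")
    if mode == "exhaustive":
        if n > 12:
            raise ValueError("exhaustive enumeration limited to N <= 12")
        scored = _score_exhaustive(E)
    elif mode == "dp_topk":
        if k is None:
            raise ValueError("dp_topk requires k")
        scored = _score_dp_topk(E, k)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return _normalize(scored)


def _score_exhaustive(E: np.ndarray) -> list[ScoredSequence]:
    n_steps = E.shape[0]
    n = n_steps + 1
    total = 4 ** n
    codes = np.arange(total)
    # digits[j] = base index at position j (most significant first)
    raw = np.zeros(total)
    digits = np.empty((n, total), dtype=np.int64)
    for j in range(n):
        digits[j] = (codes // (4 ** (n - 1 - j))) % 4
    for kstep in range(n_steps):
        d_idx = 4 * digits[kstep] + digits[kstep + 1]
        raw += E[kstep, d_idx]
    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)
    seq_bytes = base_arr[digits.T]
    seqs = [bytes(row).decode() for row in seq_bytes]
    return [ScoredSequence(s, float(r)) for s, r in zip(seqs, raw)]


def _score_dp_topk(E: np.ndarray, k: int) -> list[ScoredSequence]:
    """Exact top-k (lowest raw score) via K-best Viterbi on the step chain.

    State = last nucleotide; sequences are carried as base-4 integer codes
    and ties between equal-score sequences break lexicographically, so the
    ranking matches exhaustive enumeration.
    """
    n_steps = E.shape[0]
    # per last-base beam: (scores ascending, sequence codes)
    scores = [np.zeros(1) for _ in range(4)]
    codes = [np.array([b], dtype=np.int64) for b in range(4)]
    for kstep in range(n_steps):
        new_scores, new_codes = [], []
        for b_new in range(4):
            s = np.concatenate([scores[b_prev] + E[kstep, 4 * b_prev + b_new]
                                for b_prev in range(4)])
            c = np.concatenate([codes[b_prev] * 4 + b_new
                                for b_prev in range(4)])
            order = np.lexsort((c, s))[:k]
            new_scores.append(s[order])
            new_codes.append(c[order])
        scores, codes = new_scores, new_codes
    s = np.concatenate(scores)
    c = np.concatenate(codes)
    order = np.lexsort((c, s))[:k]
    s, c = s[order], c[order]
    n = n_steps + 1
    out = []
    for score, code in zip(s, c):
        seq = "".join(BASES[(code >> (2 * (n - 1 - j))) & 3]
                      for j in range(n))
        out.append(ScoredSequence(seq, float(score)))
    return out


# --------------------------------------------------------------------------
# PWM construction
# --------------------------------------------------------------------------


def build_pwm(scored: list[ScoredSequence], threshold: float = 0.95,
              pwm_id: str = "predicted",
              pseudocount: float = 0.01) -> Pwm:
    """Build a PWM from the sequences with normalized score >= threshold.

    Column j holds the base frequencies at position j among the selected
    sequences, with ``pseudocount`` added to every cell before
    normalization.  The threshold mirrors the per-family tuned cut-off and
    must lie in [0.7, 1.0].
    """
    if not scored:
        raise ValueError("no scored sequences")
    selected = [s for s in scored if s.normalized >= threshold]
    if not selected:
        raise ValueError("threshold too high: no sequence selected")
    width = len(selected[0].sequence)
    counts = np.full((width, 4), pseudocount)
    for s in selected:
        for j, b in enumerate(s.sequence):
            counts[j, _BASE_INDEX[b]] += 1.0
    matrix = counts / counts.sum(axis=1, keepdims=True)
    return Pwm(matrix, id=pwm_id, source="predicted", counts=counts)


def predict_pwm(cx, potential, threshold: float = 0.95,
                mode: str | None = None, top_k: int = 4096,
                pwm_id: str | None = None) -> Pwm:
    """End-to-end PWM prediction from an annotated complex and a potential."""
    E, _ = step_score_matrix(cx, potential)
    n = E.shape[0] + 1
    if mode is None:
        mode = "exhaustive" if n <= 10 else "dp_topk"
    scored = score_sequences_from_steps(
        E, mode=mode, k=top_k if mode == "dp_topk" else None)
    return build_pwm(scored, threshold=threshold,
                     pwm_id=pwm_id or f"{cx.source_id}_predicted")
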