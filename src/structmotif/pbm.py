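"""Extension of structural contact counts with protein-binding-microarray
(PBM) 8-mer data.

PBM experiments report, for every DNA 8-mer, a rank-based E-score in
[-0.50, 0.50].  8-mers with E > 0.45 are high-affinity ("positive"), those
with E < 0.37 unbound ("negative"); the band in between is discarded.
Positive 8-mers are placed into the template binding site via the TF's PWM
(best ungapped alignment on either strand) and the template's contacts are
re-emitted with the placed nucleotides -- and, for homologous TFs, with
amino acids substituted through a gap-free interface alignment -- growing
the contact table far beyond what crystal structures alone provide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .contacts import Contact, ContactTable
from .pwm import Pwm, reverse_complement

E_SCORE_POSITIVE = 0.45   # E > 0.45: bound
E_SCORE_NEGATIVE = 0.37   # E < 0.37: unbound


@dataclass
class PbmExperiment:
    tf_id: str
    records: dict[str, float]

    def __post_init__(self):
        for kmer, e in self.records.items():
            if len(kmer) != 8 or any(b not in "ACGT" for b in kmer):
                raise ValueError(f"invalid 8-mer {kmer!r}")
            if not -0.50 <= e <= 0.50:
                raise ValueError(f"E-score {e} outside [-0.50, 0.50]")


class KmerClasses(NamedTuple):
    positive: set[str]
    negative: set[str]
    discarded: set[str]


def classify_8mers(exp: PbmExperiment) -> KmerClasses:
    """Partition an experiment's 8-mers by E-score: positive iff E > 0.45,
    negative iff E < 0.37, the rest discarded."""
    pos, neg, disc = set(), set(), set()
    for kmer, e in exp.records.items():
        if e > E_SCORE_POSITIVE:
            pos.add(kmer)
        elif e < E_SCORE_NEGATIVE:
            neg.add(kmer)
        else:
            disc.add(kmer)
    return KmerClasses(pos, neg, disc)


def read_pbm(text: str, tf_id: str = "pbm") -> PbmExperiment:
    """Read a two-column (8-mer, E-score) table; Cis-BP-style extra columns
    and a header line are tolerated."""
    records = {}
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        toks = ln.split()
        if toks[0].lower() in ("8mer", "kmer", "sequence"):
            continue
        records[toks[0].upper()] = float(toks[1])
    return PbmExperiment(tf_id, records)


# --------------------------------------------------------------------------
# 8-mer placement in the template binding site
# --------------------------------------------------------------------------


@dataclass
class Placement:
    kmer: str
    offset: int           # start of the 8-mer in template coordinates
    strand: str           # + / -
    score: float
    placed_sequence: str  # template site with the 8-mer written in


def _kmer_pwm_score(kmer: str, pwm: Pwm, offset: int) -> float:
    """Log-likelihood of the 8-mer columns it overlaps at this offset."""
    s = 0.0
    from .pwm import _BASE_INDEX
    for i, b in enumerate(kmer):
        j = offset + i
        if 0 <= j < pwm.width:
            s += float(np.log(pwm.matrix[j, _BASE_INDEX[b]] + 1e-9))
    return s


def placement_score_floor(pwm: Pwm, n_samples: int = 10000,
                          seed: int = 20240612) -> float:
    """Median full-overlap alignment score of random 8-mers against the
    PWM; placements scoring below this floor are rejected as noise."""
    rng = np.random.default_rng(seed)
    kmers = ["".join("ACGT"[i] for i in rng.integers(0, 4, 8))
             for _ in range(n_samples)]
    scores = [max(_kmer_pwm_score(k, pwm, o)
                  for o in range(max(pwm.width - 7, 1)))
              for k in kmers]
    return float(np.median(scores))


def align_8mer_to_site(kmer: str, pwm: Pwm, template_site: str,
                       floor: float | None = None) -> Placement | None:
    """Best ungapped placement of an 8-mer in the template binding site.

    The 8-mer is slid along the PWM on both strands; the best-scoring
    offset wins (ties: forward strand, then smaller offset) and is mapped
    onto template coordinates.  Returns None when the best score falls
    below the rejection floor.
    """
    if len(template_site) != pwm.width:
        raise ValueError("template site length does not match the PWM "
                         "width from the structure")
    candidates = []
    for strand, seq in (("+", kmer), ("-", reverse_complement(kmer))):
        for off in range(max(pwm.width - 7, 1)):
            candidates.append(
                (_kmer_pwm_score(seq, pwm, off), strand, off, seq))
    candidates.sort(key=lambda t: (-t[0], t[1] != "+", t[2]))
    score, strand, off, seq = candidates[0]
    if floor is not None and score < floor:
        return None
    placed = list(template_site)
    for i, b in enumerate(seq):
        if 0 <= off + i < len(placed):
            placed[off + i] = b
    return Placement(kmer, off, strand, score, "".join(placed))


# --------------------------------------------------------------------------
# homolog mapping
# --------------------------------------------------------------------------


@dataclass
class HomologMap:
    """Residue correspondence from a template TF to a homologous target.

    ``mapping`` sends template residue index (0-based in the template
    sequence) to the aligned target amino acid; maps with a gap inside the
    interface are flagged invalid and contribute nothing to the extension.
    """

    template_tf_id: str
    target_tf_id: str
    mapping: dict[int, str]
    interface_gap: bool = False

    @classmethod
    def identity(cls, tf_id: str, sequence: str) -> "HomologMap":
        return cls(tf_id, tf_id, dict(enumerate(sequence)))


def _global_alignment(seq_a: str, seq_b: str):
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner.align(seq_a, seq_b)[0]  # first traceback = deterministic


def build_homolog_map(template_tf_id: str, template_seq: str,
                      target_tf_id: str, target_seq: str,
                      interface_positions) -> HomologMap:
    """Map template residues onto a homolog via global alignment
    (BLOSUM62, gap open 10 / extend 0.5).

    ``interface_positions`` are 0-based template residue indices at the
    protein-DNA interface; any gap aligned inside them invalidates the map.
    """
    aln = _global_alignment(template_seq, target_seq)
    mapping: dict[int, str] = {}
    aligned_template: set[int] = set()
    for (ta_start, ta_end), (tb_start, tb_end) in zip(*aln.aligned):
        for k in range(ta_end - ta_start):
            mapping[ta_start + k] = target_seq[tb_start + k]
            aligned_template.add(ta_start + k)
    gap = any(p not in aligned_template for p in interface_positions)
    return HomologMap(template_tf_id, target_tf_id, mapping,
                      interface_gap=gap)


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Percent identical residues over the global alignment length."""
    aln = _global_alignment(seq_a, seq_b)
    ident = 0
    for (ta_start, ta_end), (tb_start, tb_end) in zip(*aln.aligned):
        for k in range(ta_end - ta_start):
            if seq_a[ta_start + k] == seq_b[tb_start + k]:
                ident += 1
    return 100.0 * ident / aln.length


# --------------------------------------------------------------------------
# contact transfer
# --------------------------------------------------------------------------


def extend_contacts(template_contacts: list[Contact],
                    placements: list[Placement],
                    homolog_maps: list[HomologMap],
                    table: ContactTable,
                    residue_index: dict | None = None,
                    site_start: int = 0) -> int:
    """Transfer template contacts onto placed 8-mers and homolog residues.

    For every placement and every gap-free homolog map, each template
    contact is re-emitted with its dinucleotide read from the placed
    sequence at the contact's step and its amino acid substituted through
    the map; distances (hence bins) and environments are inherited from
    the template.  Records enter the table with provenance "pbm".  Returns
    the number of records added.
    """
    if residue_index is None:
        order = []
        for c in template_contacts:
            key = (c.residue.chain_id, c.residue.position)
            if key not in order:
                order.append(key)
        residue_index = {key: i for i, key in enumerate(order)}
    added = 0
    for pl in placements:
        if pl is None:
            continue
        for hmap in homolog_maps:
            if hmap.interface_gap:
                continue
            for c in template_contacts:
                k = c.step_index - site_start
                if not 0 <= k < len(pl.placed_sequence) - 1:
                    continue
                dinuc = pl.placed_sequence[k:k + 2]
                ridx = residue_index[(c.residue.chain_id, c.residue.position)]
                aa = hmap.mapping.get(ridx)
                if aa is None:
                    continue
                table.add_record(aa, dinuc, c.env, c.distance,
                                 provenance="pbm")
                added += 1
    return added
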