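"""Synthetic-data generators: toy TF-DNA complexes with planted contact
geometry, microarray 8-mer tables with planted positives, motif databases,
and synthetic TF families for the classification benchmark.

Everything is deterministic given its spec/seed and emitted in standard
formats (PDB, MEME, TSV), so the fixtures double as format-conformance
tests.  The geometry is idealized -- a straight B-DNA axis (rise 3.4 A,
twist 36 degrees) and schematic base-atom placements -- which satisfies
the centroid/groove contact definition without attempting physically
realistic energetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .contacts import (AA_ALPHABET, ALL_CLASSES, Contact, ContactTable,
                       extract_contacts)
from .evaluate import SyntheticTf
from .pbm import PbmExperiment
from .pwm import BASES, Pwm, write_meme
from .structure import (AA3_TO_1, MAJOR_GROOVE_ATOMS, virtual_cbeta)

AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

RISE = 3.4       # A per base pair
TWIST = 36.0     # degrees per base pair

_BASE_ATOMS = {
    "A": ["N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"],
    "G": ["N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"],
    "C": ["N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"],
    "T": ["N1", "C2", "O2", "N3", "C4", "O4", "C5", "C7", "C6"],
}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


# --------------------------------------------------------------------------
# fixture specification
# --------------------------------------------------------------------------


@dataclass
class PlantedContact:
    residue_index: int
    step_index: int
    distance: float           # A, must be < 30
    aa: str = "R"
    groove: str = "major"
    strand_side: str = "leading"


@dataclass
class FixtureSpec:
    seed: int = 0
    n_residues: int = 3
    dna_length: int = 12
    dna_sequence: str | None = None
    planted_contacts: list[PlantedContact] = field(default_factory=list)
    mismatches: list[int] = field(default_factory=list)  # positions w/ non-WC pair
    protein_mode: str = "scattered"   # scattered | helix | extended

    def __post_init__(self):
        for pc in self.planted_contacts:
            if not pc.distance < 30:
                raise ValueError("planted distances must be < 30 A")
            if pc.step_index >= self.dna_length - 1:
                raise ValueError("planted step beyond the duplex")


# --------------------------------------------------------------------------
# DNA geometry
# --------------------------------------------------------------------------


def _dna_atoms(spec: FixtureSpec, rng: np.random.Generator):
    """Idealized duplex: per pair i, leading base ring at +2 A radial,
    complementary at -2 A, C1'/P further out; major-groove atoms shifted
    +z, minor-groove -z so groove planting has distinct geometry."""
    L = spec.dna_length
    if spec.dna_sequence is not None:
        seq = spec.dna_sequence.upper()
        if len(seq) != L:
            raise ValueError("dna_sequence length != dna_length")
    else:
        seq = "".join(BASES[i] for i in rng.integers(0, 4, L))
    lead, comp = [], []
    for i, base in enumerate(seq):
        theta = math.radians(TWIST * i)
        z = RISE * i
        u = np.array([math.cos(theta), math.sin(theta), 0.0])
        t = np.array([-math.sin(theta), math.cos(theta), 0.0])
        zhat = np.array([0.0, 0.0, 1.0])
        cbase = _COMPLEMENT[base]
        if i in spec.mismatches:
            cbase = base  # plant a non-complementary pair
        for strand, b, sign in (("lead", base, 1.0), ("comp", cbase, -1.0)):
            atoms = {}
            center = sign * 2.0 * u + z * zhat
            names = _BASE_ATOMS[b]
            for k, name in enumerate(names):
                phi = 2 * math.pi * k / len(names)
                pos = center + 0.7 * (math.cos(phi) * t
                                      + math.sin(phi) * zhat)
                # well-separated groove shells so nearest-atom groove
                # detection matches the planted intent
                if name in MAJOR_GROOVE_ATOMS[b]:
                    pos = pos + 2.2 * zhat
                else:
                    pos = pos - 2.2 * zhat
                atoms[name] = pos
            atoms["C1'"] = sign * 6.0 * u + z * zhat
            atoms["O5'"] = sign * 8.0 * u + z * zhat + 0.5 * t
            atoms["P"] = sign * 9.0 * u + z * zhat
            (lead if strand == "lead" else comp).append((b, atoms))
    return seq, lead, comp


def _step_centroid(lead, comp, i) -> np.ndarray:
    coords = []
    for nuc in (lead[i], lead[i + 1], comp[i], comp[i + 1]):
        b, atoms = nuc
        coords.extend(v for n, v in atoms.items()
                      if n not in ("C1'", "O5'", "P"))
    return np.mean(np.asarray(coords), axis=0)


# --------------------------------------------------------------------------
# protein geometry
# --------------------------------------------------------------------------

def _nerf(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom D from A-B-C internal coordinates."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * math.cos(angle),
                   bond * math.sin(angle) * math.cos(torsion),
                   bond * math.sin(angle) * math.sin(torsion)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_peptide(n: int, phi: float = -57.0, psi: float = -47.0,
                  sequence: str | None = None) -> list[dict]:
    """Backbone (N, CA, C, O, CB) of an ideal peptide at the given
    dihedrals: (-57, -47) is the canonical alpha-helix, (180, 180) a fully
    extended chain.  Returns one atom dict per residue."""
    if sequence is None:
        sequence = "A" * n
    res = []
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([1.458, 0.0, 0.0])
    ang = math.radians(111.2)
    C = CA + 1.525 * np.array([math.cos(math.pi - ang),
                               math.sin(math.pi - ang), 0.0])
    for i in range(n):
        if i > 0:
            N = _nerf(res[-1]["N"], res[-1]["CA"], res[-1]["C"],
                      1.329, 116.2, psi)
            CA = _nerf(res[-1]["CA"], res[-1]["C"], N, 1.458, 121.7, 180.0)
            C = _nerf(res[-1]["C"], N, CA, 1.525, 111.2, phi)
            res[-1]["O"] = _nerf(N, res[-1]["CA"], res[-1]["C"],
                                 1.231, 120.8, 180.0)
        res.append({"N": N, "CA": CA, "C": C})
    for i, r in enumerate(res):
        if "O" not in r:
            r["O"] = _nerf(r["N"], r["CA"], r["C"], 1.231, 120.8, psi + 180.0)
        if sequence[i] != "G":
            r["CB"] = virtual_cbeta(r["N"], r["CA"], r["C"])
    return res


def _single_residue(cb_target: np.ndarray, away: np.ndarray,
                    aa: str) -> dict:
    """One residue with ideal internal geometry, its CB at ``cb_target``
    and its backbone extending along ``away`` (unit vector)."""
    away = away / np.linalg.norm(away)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(away @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    perp = np.cross(away, ref)
    perp /= np.linalg.norm(perp)
    ca = cb_target + 1.53 * away
    n = ca + 1.458 * (0.5 * away + 0.866 * perp)
    c = ca + 1.525 * (0.5 * away - 0.866 * perp)
    o = c + 1.231 * away
    atoms = {"N": n, "CA": ca, "C": c, "O": o}
    if aa != "G":
        atoms["CB"] = np.asarray(cb_target, float)
    return atoms


# --------------------------------------------------------------------------
# PDB serialization
# --------------------------------------------------------------------------


def _pdb_atom(serial, name, resname, chain, resseq, coord, element):
    name_f = f" {name:<3s}" if len(name) < 4 else name
    return (f"ATOM  {serial:5d} {name_f} {resname:>3s} {chain}{resseq:4d}"
            f"    {coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}"
            f"  1.00  0.00          {element:>2s}")


def make_complex(spec: FixtureSpec) -> str:
    """PDB text of a toy TF-DNA complex.

    The duplex is ideal B-DNA (chains B leading / C complementary); planted
    contacts place a residue's C-beta at the requested distance from the
    step centroid, aimed at a base atom of the requested groove and strand
    side; remaining residues sit > 35 A from every step.  Output is
    byte-identical for identical specs.
    """
    rng = np.random.default_rng(spec.seed)
    seq, lead, comp = _dna_atoms(spec, rng)
    L = spec.dna_length
    centroids = [_step_centroid(lead, comp, i) for i in range(L - 1)]

    residues: dict[int, tuple[str, dict]] = {}
    if spec.protein_mode in ("helix", "extended"):
        phi, psi = ((-57.0, -47.0) if spec.protein_mode == "helix"
                    else (180.0, 180.0))
        pep = build_peptide(spec.n_residues, phi, psi)
        shift = np.array([20.0, 0.0, RISE * L / 2])
        for i, atoms in enumerate(pep):
            residues[i] = ("A", {k: v + shift for k, v in atoms.items()})
    else:
        for pc in spec.planted_contacts:
            centroid = centroids[pc.step_index]
            target = _groove_atom_coord(lead, comp, pc.step_index,
                                        pc.groove, pc.strand_side)
            direction = target - centroid
            direction = direction / np.linalg.norm(direction)
            cb = centroid + pc.distance * direction
            residues[pc.residue_index] = (
                "A", _single_residue(cb, direction, pc.aa))
        far = np.array([80.0, 80.0, 0.0])
        k = 0
        for i in range(spec.n_residues):
            if i not in residues:
                atoms = _single_residue(far + np.array([0, 0, 5.0 * k]),
                                        np.array([1.0, 0.0, 0.0]), "A")
                residues[i] = ("A", atoms)
                k += 1

    aa_of = {pc.residue_index: pc.aa for pc in spec.planted_contacts}
    lines = []
    serial = 1
    for i in sorted(residues):
        chain, atoms = residues[i]
        aa = aa_of.get(i, "A")
        resname = AA1_TO_3[aa]
        for name in ("N", "CA", "C", "O", "CB"):
            if name not in atoms:
                continue
            lines.append(_pdb_atom(serial, name, resname, chain, i + 1,
                                   atoms[name], name[0]))
            serial += 1
    for chain, strand in (("B", lead), ("C", list(reversed(comp)))):
        for j, (b, atoms) in enumerate(strand):
            for name, coord in atoms.items():
                lines.append(_pdb_atom(serial, name, "D" + b, chain, j + 1,
                                       coord, name[0]))
                serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def _groove_atom_coord(lead, comp, step, groove, strand_side):
    nucs = [(lead[step], "leading"), (lead[step + 1], "leading"),
            (comp[step], "complementary"), (comp[step + 1], "complementary")]
    for (b, atoms), side in nucs:
        if side != strand_side:
            continue
        for name, coord in atoms.items():
            if name in ("C1'", "O5'", "P"):
                continue
            in_major = name in MAJOR_GROOVE_ATOMS[b]
            if (groove == "major") == in_major:
                return coord
    raise ValueError("no atom with the requested groove/strand side")


# --------------------------------------------------------------------------
# PBM experiments
# --------------------------------------------------------------------------


@dataclass
class PbmSpec:
    seed: int = 0
    n_positive: int = 10
    n_negative: int = 50
    n_discarded: int = 0
    positive_range: tuple[float, float] = (0.455, 0.50)
    negative_range: tuple[float, float] = (-0.50, 0.36)
    discarded_range: tuple[float, float] = (0.37, 0.45)


def _sample_kmer_from_pwm(pwm: Pwm, rng: np.random.Generator) -> str:
    return "".join(BASES[rng.choice(4, p=pwm.matrix[j])]
                   for j in range(pwm.width))


def make_pbm(spec: PbmSpec, planted_motif: Pwm,
             tf_id: str = "synthetic_tf") -> PbmExperiment:
    """Synthetic 8-mer table with planted positives.

    Positives are drawn from the planted motif (the consensus is seeded
    first) with E-scores above the binding threshold; negatives are random
    background 8-mers below the non-binding threshold; an optional
    discarded band sits in between.  The three E-score ranges guarantee a
    crossover-free classification.
    """
    if planted_motif.width != 8:
        raise ValueError("planted motif must have width 8 for PBM tables")
    rng = np.random.default_rng(spec.seed)
    records: dict[str, float] = {}

    def add(kmer, lo, hi):
        if kmer not in records:
            records[kmer] = float(rng.uniform(lo, hi))
            return True
        return False

    n_pos = 0
    if spec.n_positive >= 1:
        add(planted_motif.consensus, *spec.positive_range)
        n_pos = 1
    while n_pos < spec.n_positive:
        n_pos += add(_sample_kmer_from_pwm(planted_motif, rng),
                     *spec.positive_range)
    n = 0
    while n < spec.n_negative:
        n += add("".join(BASES[i] for i in rng.integers(0, 4, 8)),
                 *spec.negative_range)
    n = 0
    while n < spec.n_discarded:
        n += add("".join(BASES[i] for i in rng.integers(0, 4, 8)),
                 *spec.discarded_range)
    return PbmExperiment(tf_id, records)


# --------------------------------------------------------------------------
# motif databases
# --------------------------------------------------------------------------


def make_motif_db(n: int, widths=(8,), seed: int = 0,
                  embed: Pwm | None = None,
                  alpha: float = 0.5) -> tuple[list[Pwm], str]:
    """Random motif database (Dirichlet-sampled columns) in MEME text.

    ``embed`` places a given PWM as the first entry.  Returns
    (pwm list, MEME text)."""
    rng = np.random.default_rng(seed)
    pwms: list[Pwm] = []
    if embed is not None:
        pwms.append(Pwm(embed.matrix, id=embed.id, source="experimental"))
    widths = list(widths)
    while len(pwms) < n:
        w = int(widths[len(pwms) % len(widths)])
        m = rng.dirichlet([alpha] * 4, size=w)
        pwms.append(Pwm(m, id=f"DB{len(pwms):04d}", source="experimental"))
    pwms = pwms[:n]
    return pwms, write_meme(pwms)


# --------------------------------------------------------------------------
# planted-preference contact tables
# --------------------------------------------------------------------------


def make_planted_table(contacts: list[Contact], consensus: str,
                       enrichment: float = 5.0, baseline: float = 10.0,
                       max_radius: float = 30.0) -> ContactTable:
    """Contact table in which, at every contact's (environment, bin)
    context, all 20 x 16 (aa, dinucleotide) cells hold the baseline count
    and the contact's amino acid paired with the consensus dinucleotide of
    its step is enriched ``enrichment``-fold."""
    table = ContactTable(max_radius=max_radius)
    for c in contacts:
        d_planted = consensus[c.step_index:c.step_index + 2]
        for aa in AA_ALPHABET:
            for a in "ACGT":
                for b in "ACGT":
                    table.add_record(aa, a + b, c.env, c.distance,
                                     "pdb", baseline)
        table.add_record(c.aa, d_planted, c.env, c.distance, "pdb",
                         (enrichment - 1.0) * baseline)
    return table


def closed_loop_fixture(seed: int = 0, dna_length: int = 8,
                        enrichment: float = 5.0):
    """Full parameter-recovery fixture: a toy complex with one planted
    contact per step, and a contact table enriched 5x toward a planted
    consensus at every interface step.

    Returns (complex, contacts, table, consensus)."""
    rng = np.random.default_rng(seed)
    consensus = "".join(BASES[i] for i in rng.integers(0, 4, dna_length))
    planted = [PlantedContact(residue_index=k, step_index=k,
                              distance=6.5 + 1.0 * k,
                              aa=AA_ALPHABET[(2 * k + 1) % 20],
                              groove="major" if k % 2 == 0 else "minor")
               for k in range(dna_length - 1)]
    spec = FixtureSpec(seed=seed, n_residues=dna_length - 1,
                       dna_length=dna_length, dna_sequence=consensus,
                       planted_contacts=planted)
    from .structure import parse_complex
    cx = parse_complex(make_complex(spec), source_id=f"loop{seed}")
    contacts = extract_contacts(cx, max_radius=30.0)
    table = make_planted_table(contacts, consensus, enrichment=enrichment)
    return cx, contacts, table, consensus


# --------------------------------------------------------------------------
# synthetic TF families for the classification benchmark
# --------------------------------------------------------------------------

_SHARED_STEPS = (0, 3, 6)


def make_tf_family(family: str, n_tfs: int, consensus: str,
                   seed: int = 0, n_positive: int = 5,
                   enrichment: float = 5.0,
                   baseline: float = 10.0) -> list[SyntheticTf]:
    """Synthetic TF family sharing a planted 8-mer binding preference.

    Every member's interface covers the 7 steps of an 8-mer site.  Steps
    0/3/6 use family-shared contexts (same amino acid, environment and
    distance across members) so cross-validated potentials trained on the
    other members transfer; the remaining steps use member-specific
    contexts.  Positives are the consensus plus single-mutant 8-mers.
    """
    if len(consensus) != 8:
        raise ValueError("family consensus must be an 8-mer")
    rng = np.random.default_rng(seed)
    tfs = []
    for t in range(n_tfs):
        template = []
        for k in range(7):
            if k in _SHARED_STEPS:
                aa = AA_ALPHABET[k % 20]
                env = ALL_CLASSES[(5 * k) % 48]
                distance = 5.4 + k
            else:
                aa = AA_ALPHABET[(3 + 5 * t + k) % 20]
                env = ALL_CLASSES[(11 + 7 * t + 3 * k) % 48]
                distance = 4.3 + ((t + 2 * k) % 12)
            template.append((aa, env, distance, k))
        table = ContactTable(max_radius=30.0)
        for aa, env, distance, k in template:
            d_planted = consensus[k:k + 2]
            for aa2 in AA_ALPHABET:
                for a in "ACGT":
                    for b in "ACGT":
                        table.add_record(aa2, a + b, env, distance, "pdb",
                                         baseline)
            table.add_record(aa, d_planted, env, distance, "pdb",
                             (enrichment - 1.0) * baseline)
        positives = {consensus}
        while len(positives) < n_positive:
            pos = int(rng.integers(0, 8))
            base = BASES[int(rng.integers(0, 4))]
            mut = consensus[:pos] + base + consensus[pos + 1:]
            positives.add(mut)
        tfs.append(SyntheticTf(f"{family}_{t:02d}", family, template,
                               table, positives))
    return tfs


# --------------------------------------------------------------------------
# random potentials for oracle equivalence checks
# --------------------------------------------------------------------------


def random_step_scores(seed: int, n_steps: int,
                       n_records: int = 200) -> np.ndarray:
    """Per-step dinucleotide Z-score matrix of a randomly seeded potential.

    A random contact table (``n_records`` records over random cells) is
    turned into an interval potential; each step then draws a random
    (amino acid, environment, distance) contact context and takes its
    16-dinucleotide Z-score vector.  Deterministic given the seed.
    """
    from .potentials import FamilyConfig, build_potential
    rng = np.random.default_rng(seed)
    table = ContactTable(max_radius=30.0)
    for _ in range(n_records):
        table.add_record(AA_ALPHABET[rng.integers(20)],
                         BASES[rng.integers(4)] + BASES[rng.integers(4)],
                         ALL_CLASSES[rng.integers(48)],
                         float(rng.uniform(0.2, 29.8)), "pdb",
                         float(rng.integers(1, 6)))
    pot = build_potential(table, FamilyConfig(binning="bins", radius=30.0,
                                              contacts_db="pdb"))
    E = np.zeros((n_steps, 16))
    for k in range(n_steps):
        for _ in range(rng.integers(1, 3)):
            E[k] += pot.zscore_vector_dinuc(
                AA_ALPHABET[rng.integers(20)],
                ALL_CLASSES[rng.integers(48)],
                float(rng.uniform(0.2, 29.8)))
    return E


# --------------------------------------------------------------------------
# scan sequences
# --------------------------------------------------------------------------


def make_scan_sequence(pwm: Pwm, position: int, length: int = 420,
                       seed: int = 0) -> str:
    """Random background sequence with the PWM consensus planted at the
    given 1-based start position."""
    rng = np.random.default_rng(seed)
    seq = [BASES[i] for i in rng.integers(0, 4, length)]
    cons = pwm.consensus
    seq[position - 1:position - 1 + len(cons)] = list(cons)
    return "".join(seq[:length])
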