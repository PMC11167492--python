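"""Parsing and annotation of transcription-factor/DNA complex structures.

A TF-DNA complex is reduced to the features the contact classifier needs:
per-residue secondary structure, solvent exposure and hydrophobicity class on
the protein side; per-dinucleotide-step base centroids and a major/minor/
backbone partition of the nucleotide atoms on the DNA side.  Coordinates come
in as PDB text (parsed with Bio.PDB); everything downstream works on the
plain containers defined here.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser

# --------------------------------------------------------------------------
# residue and nucleotide vocabularies
# --------------------------------------------------------------------------

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# nonstandard residues mapped to their standard parent
NONSTANDARD_PARENT = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "SEP": "SER", "TPO": "THR",
    "PTR": "TYR", "CSO": "CYS", "HYP": "PRO", "MLY": "LYS", "M3L": "LYS",
    "KCX": "LYS", "CME": "CYS", "CSD": "CYS", "OCS": "CYS", "LLP": "LYS",
}

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# fixed two-way hydrophobicity classes
NONPOLAR_AA = set("AVLIMFWCGP")


def hydrophobicity_class(aa: str) -> str:
    return "nonpolar" if aa in NONPOLAR_AA else "polar"


DNA_RESNAMES = {
    "DA": "A", "DC": "C", "DG": "G", "DT": "T",
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T", "DU": "T",
}

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# sugar-phosphate backbone atom names (anything else on a nucleotide is base)
DNA_BACKBONE_ATOMS = {
    "P", "OP1", "OP2", "OP3", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'",
    "C2'", "O2'", "C1'",
}

# Partition of nucleotide base atoms into the DNA groove they face.  The
# assignment follows the canonical chemical description of B-DNA groove
# edges (Seeman, Rosenberg & Rich 1976; Saenger, Principles of Nucleic Acid
# Structure): the Hoogsteen edge faces the major groove, the sugar edge the
# minor groove.  Atoms not listed and not backbone default to minor.
MAJOR_GROOVE_ATOMS = {
    "A": {"N7", "C8", "C5", "C6", "N6"},
    "G": {"N7", "C8", "C5", "C6", "O6"},
    "C": {"C4", "N4", "C5", "C6"},
    "T": {"C4", "O4", "C5", "C7", "C5M", "C6"},
}

# Theoretical maximum accessible surface areas (A^2) per residue,
# Tien et al. 2013, used to turn absolute SASA into relative accessibility.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


class StructureError(ValueError):
    """Raised when a complex cannot be parsed into a protein-DNA duplex."""


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class ProteinResidue:
    chain_id: str
    position: int
    aa: str
    cb_coord: np.ndarray
    ss: str | None = None          # helix / strand / coil
    exposure: str | None = None    # buried / exposed
    atoms: dict = field(default_factory=dict, repr=False)
    sasa: float | None = None

    @property
    def hydrophobicity(self) -> str:
        return hydrophobicity_class(self.aa)


@dataclass
class Nucleotide:
    chain_id: str
    position: int
    base: str
    atoms: dict = field(repr=False, default_factory=dict)

    def base_atoms(self) -> dict:
        return {n: c for n, c in self.atoms.items()
                if n not in DNA_BACKBONE_ATOMS}


@dataclass
class BaseAtom:
    """One nucleotide atom of a step, tagged for the contact classifier."""
    name: str
    coord: np.ndarray
    groove: str        # major / minor / backbone
    strand_side: str   # leading / complementary


@dataclass
class DinucleotideStep:
    index: int
    dinucleotide: str
    base_centroid: np.ndarray
    atoms: list[BaseAtom] = field(default_factory=list, repr=False)

    def groove_atoms(self, groove: str) -> list[BaseAtom]:
        return [a for a in self.atoms if a.groove == groove]


@dataclass
class AnnotatedComplex:
    source_id: str
    protein_residues: list[ProteinResidue]
    leading_strand: list[Nucleotide]
    complementary_strand: list[Nucleotide]
    steps: list[DinucleotideStep]
    mismatches: list[int] = field(default_factory=list)
    _sasa_computed: bool = field(default=False, repr=False)

    @property
    def dna_sequence(self) -> str:
        return "".join(n.base for n in self.leading_strand)


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------


def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal-geometry C-beta from backbone N/CA/C (used for glycine)."""
    b = ca - n
    c_v = c - ca
    a = np.cross(b, c_v)
    # ideal tetrahedral placement, |CA-CB| = 1.53 A
    cb = -0.58273431 * a + 0.56802827 * b - 0.54067466 * c_v + ca
    return cb


def _groove_of(base: str, atom_name: str) -> str:
    if atom_name in DNA_BACKBONE_ATOMS:
        return "backbone"
    if atom_name in MAJOR_GROOVE_ATOMS.get(base, set()):
        return "major"
    return "minor"


# --------------------------------------------------------------------------
# parsing
# --------------------------------------------------------------------------


def _load_chains(pdb_text: str, source_id: str):
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(source_id, io.StringIO(pdb_text))
    model = next(structure.get_models())
    protein_chains: dict[str, list[ProteinResidue]] = {}
    dna_chains: dict[str, list[Nucleotide]] = {}
    for chain in model:
        for res in chain:
            resname = res.get_resname().strip()
            atoms = {a.get_name(): a.get_coord().astype(float) for a in res}
            if resname in DNA_RESNAMES:
                dna_chains.setdefault(chain.id, []).append(
                    Nucleotide(chain.id, res.get_id()[1],
                               DNA_RESNAMES[resname], atoms))
            else:
                name = NONSTANDARD_PARENT.get(resname, resname)
                if name not in AA3_TO_1:
                    if resname not in ("HOH", "WAT"):
                        warnings.warn(
                            f"dropping unmappable residue {resname} "
                            f"in chain {chain.id}")
                    continue
                aa = AA3_TO_1[name]
                if "CA" not in atoms:
                    continue
                if "CB" in atoms:
                    cb = atoms["CB"]
                elif all(k in atoms for k in ("N", "CA", "C")):
                    cb = virtual_cbeta(atoms["N"], atoms["CA"], atoms["C"])
                else:
                    cb = atoms["CA"]
                protein_chains.setdefault(chain.id, []).append(
                    ProteinResidue(chain.id, res.get_id()[1], aa, cb,
                                   atoms=atoms))
    return protein_chains, dna_chains, model


def _pair_strands(dna_chains: dict[str, list[Nucleotide]]):
    """Pair two DNA chains into an antiparallel duplex.

    Strands are paired by maximal complementary overlap over all ungapped
    offsets; the leading strand is the one whose first paired nucleotide has
    the lower author number.  Returns (leading, complementary, mismatches)
    where the complementary list is position-aligned with the leading list.
    """
    ids = sorted(dna_chains)
    if len(ids) < 2:
        raise StructureError("no DNA duplex: need two DNA strands")
    best = None
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            s1 = dna_chains[ids[i]]
            s2 = list(reversed(dna_chains[ids[j]]))  # antiparallel
            for off in range(-(len(s2) - 1), len(s1)):
                pairs = []
                score = 0
                for k in range(len(s1)):
                    m = k - off
                    if 0 <= m < len(s2):
                        pairs.append((s1[k], s2[m]))
                        if COMPLEMENT[s1[k].base] == s2[m].base:
                            score += 1
                if len(pairs) >= 2:
                    cand = (score, len(pairs), -abs(off), ids[i], ids[j],
                            pairs)
                    if best is None or cand[:3] > best[:3]:
                        best = cand
    if best is None or best[0] < 2:
        raise StructureError("no DNA duplex: no complementary strand pairing")
    _, _, _, _, _, pairs = best
    # proximity sanity check on C1' distances where available
    d = [np.linalg.norm(a.atoms["C1'"] - b.atoms["C1'"])
         for a, b in pairs if "C1'" in a.atoms and "C1'" in b.atoms]
    if d and float(np.mean(d)) > 20.0:
        raise StructureError("no DNA duplex: paired strands are not in contact")
    lead = [p[0] for p in pairs]
    comp = [p[1] for p in pairs]
    if comp[0].position < lead[0].position:
        lead, comp = comp, lead
    mismatches = [k for k, (a, b) in enumerate(zip(lead, comp))
                  if COMPLEMENT[a.base] != b.base]
    return lead, comp, mismatches


def _build_steps(lead: list[Nucleotide],
                 comp: list[Nucleotide]) -> list[DinucleotideStep]:
    steps = []
    for i in range(len(lead) - 1):
        nucs = [(lead[i], "leading"), (lead[i + 1], "leading"),
                (comp[i], "complementary"), (comp[i + 1], "complementary")]
        atoms: list[BaseAtom] = []
        centroid_coords = []
        for nuc, side in nucs:
            for name, coord in nuc.atoms.items():
                groove = _groove_of(nuc.base, name)
                atoms.append(BaseAtom(name, coord, groove, side))
                if groove != "backbone":
                    centroid_coords.append(coord)
        centroid = np.mean(np.asarray(centroid_coords), axis=0)
        steps.append(DinucleotideStep(
            index=i,
            dinucleotide=lead[i].base + lead[i + 1].base,
            base_centroid=centroid,
            atoms=atoms))
    return steps


def parse_complex(pdb_text: str, protein_chains=None, dna_chains=None,
                  source_id: str = "complex",
                  annotate: bool = True) -> AnnotatedComplex:
    """Parse PDB text into an :class:`AnnotatedComplex`.

    Parameters
    ----------
    protein_chains, dna_chains
        Optional iterables of chain identifiers restricting which chains are
        used.  By default every chain of the right molecule type is taken.
    annotate
        When true (default), secondary structure and solvent exposure are
        assigned before returning.
    """
    prot, dna, _ = _load_chains(pdb_text, source_id)
    if protein_chains is not None:
        prot = {c: r for c, r in prot.items() if c in set(protein_chains)}
    if dna_chains is not None:
        dna = {c: r for c, r in dna.items() if c in set(dna_chains)}
    prot = {c: r for c, r in prot.items() if len(r) >= 3}
    if not prot:
        raise StructureError("no protein chain with >= 3 residues")
    if len(dna) < 2:
        raise StructureError("no DNA duplex: need two DNA strands")
    lead, comp, mismatches = _pair_strands(dna)
    steps = _build_steps(lead, comp)
    residues = [r for c in sorted(prot) for r in prot[c]]
    cx = AnnotatedComplex(source_id, residues, lead, comp, steps,
                          mismatches=mismatches)
    if annotate:
        assign_secondary_structure(cx)
        assign_exposure(cx)
    return cx


# --------------------------------------------------------------------------
# secondary structure (self-contained Kabsch-Sander style assigner)
# --------------------------------------------------------------------------

_HB_ENERGY_CUTOFF = -0.5  # kcal/mol
_Q1Q2F = 0.084 * 332.0


def _backbone_hbond_energies(residues: list[ProteinResidue]) -> dict:
    """Kabsch-Sander electrostatic H-bond energies between CO(i) and NH(j).

    Returns {(i, j): energy} for donor NH of residue j accepting from CO of
    residue i.  The amide H is reconstructed from the previous peptide plane.
    """
    n = len(residues)
    hpos = [None] * n
    for j in range(1, n):
        r, p = residues[j], residues[j - 1]
        if r.chain_id != p.chain_id or r.aa == "P":
            continue
        if not all(k in r.atoms for k in ("N",)) or \
           not all(k in p.atoms for k in ("C", "O")):
            continue
        nv = r.atoms["N"]
        d1 = nv - p.atoms["C"]
        d2 = nv - p.atoms["O"]
        d1 /= np.linalg.norm(d1)
        d2 /= np.linalg.norm(d2)
        h = d1 + d2
        norm = np.linalg.norm(h)
        if norm > 1e-9:
            hpos[j] = nv + h / norm
    energies = {}
    for i in range(n):
        ri = residues[i]
        if "C" not in ri.atoms or "O" not in ri.atoms:
            continue
        c, o = ri.atoms["C"], ri.atoms["O"]
        for j in range(n):
            if abs(i - j) < 2 or hpos[j] is None:
                continue
            nv = residues[j].atoms["N"]
            h = hpos[j]
            r_on = np.linalg.norm(o - nv)
            if r_on > 7.0:
                continue
            e = _Q1Q2F * (1.0 / r_on + 1.0 / np.linalg.norm(c - h)
                          - 1.0 / np.linalg.norm(o - h)
                          - 1.0 / np.linalg.norm(c - nv))
            if e < _HB_ENERGY_CUTOFF:
                energies[(i, j)] = e
    return energies


def assign_secondary_structure(cx: AnnotatedComplex) -> AnnotatedComplex:
    """Label every residue helix/strand/coil.

    Implements a compact Kabsch-Sander-style assignment: backbone H-bond
    energies define n-turns (helix) and bridges (strand); the 8 fine states
    collapse to 3 (3/4/5-turn helices -> helix, bridges -> strand, the rest
    coil).  Residues with missing backbone atoms fall back to coil.
    """
    residues = cx.protein_residues
    n = len(residues)
    for r in residues:
        if not all(k in r.atoms for k in ("N", "CA", "C", "O")):
            warnings.warn(
                f"residue {r.chain_id}{r.position}: missing backbone atoms, "
                "labelled coil")
    hb = _backbone_hbond_energies(residues)
    has = lambda i, j: (i, j) in hb
    labels = ["coil"] * n
    same_chain = lambda i, j: residues[i].chain_id == residues[j].chain_id

    # helices from consecutive n-turns (n = 4 first, then 3, then 5)
    for turn in (4, 3, 5):
        for i in range(n - turn):
            if not same_chain(i, i + turn):
                continue
            if has(i, i + turn) and i + 1 + turn <= n - 1 and \
               has(i + 1, i + 1 + turn):
                for k in range(i + 1, i + 1 + turn):
                    if labels[k] == "coil":
                        labels[k] = "helix"

    # bridges (parallel / antiparallel) -> strand
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (has(i - 1, j) and has(j, i + 1)) or \
                   (has(j - 1, i) and has(i, j + 1))
            anti = (has(i, j) and has(j, i)) or \
                   (has(i - 1, j + 1) and has(j - 1, i + 1))
            if para or anti:
                for k in (i, j):
                    if labels[k] != "helix":
                        labels[k] = "strand"
    for r, lab in zip(residues, labels):
        r.ss = lab
    return cx


# --------------------------------------------------------------------------
# solvent exposure
# --------------------------------------------------------------------------

_ELEMENT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
                  "H": 1.20}


def _shrake_rupley_sasa(cx: AnnotatedComplex, n_points: int = 100,
                        probe: float = 1.40) -> None:
    """Rolling-probe SASA over all heavy atoms of the complex.

    Same algorithm as Bio.PDB's ShrakeRupley, applied to the detached
    coordinate containers used here (protein and DNA atoms both occlude).
    """
    coords, radii, owner = [], [], []
    for idx, r in enumerate(cx.protein_residues):
        for name, c in r.atoms.items():
            coords.append(c)
            radii.append(_ELEMENT_RADII.get(name[0], 1.8) + probe)
            owner.append(idx)
    for nuc in list(cx.leading_strand) + list(cx.complementary_strand):
        for name, c in nuc.atoms.items():
            coords.append(c)
            radii.append(_ELEMENT_RADII.get(name[0], 1.8) + probe)
            owner.append(-1)
    coords = np.asarray(coords)
    radii = np.asarray(radii)
    # Fibonacci sphere
    k = np.arange(n_points)
    golden = (1 + 5 ** 0.5) / 2
    theta = 2 * np.pi * k / golden
    z = 1 - (2 * k + 1) / n_points
    rho = np.sqrt(np.maximum(0.0, 1 - z * z))
    sphere = np.stack([rho * np.cos(theta), rho * np.sin(theta), z], axis=1)

    sasa = np.zeros(len(cx.protein_residues))
    for a in range(len(coords)):
        if owner[a] < 0:
            continue
        pts = coords[a] + radii[a] * sphere
        buried = np.zeros(n_points, dtype=bool)
        d0 = np.linalg.norm(coords - coords[a], axis=1)
        near = np.where((d0 < radii + radii[a]) &
                        (np.arange(len(coords)) != a))[0]
        for b in near:
            db = np.linalg.norm(pts - coords[b], axis=1)
            buried |= db < radii[b]
        frac = 1.0 - buried.mean()
        sasa[owner[a]] += frac * 4 * np.pi * radii[a] ** 2
    for r, s in zip(cx.protein_residues, sasa):
        r.sasa = float(s)


def assign_exposure(cx: AnnotatedComplex,
                    rel_acc_cutoff: float = 0.25) -> AnnotatedComplex:
    """Label residues buried/exposed by relative accessible surface area.

    Relative accessibility = SASA / theoretical max ASA (Tien et al. 2013);
    a residue is *exposed* iff it exceeds ``rel_acc_cutoff`` (default 0.25).
    """
    if not cx._sasa_computed:
        _shrake_rupley_sasa(cx)
        cx._sasa_computed = True
    for r in cx.protein_residues:
        rel = (r.sasa or 0.0) / MAX_ASA[r.aa]
        r.exposure = "exposed" if rel > rel_acc_cutoff else "buried"
    return cx


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------


def annotation_report(cx: AnnotatedComplex) -> str:
    """TSV report: one row per protein residue and per dinucleotide step."""
    lines = ["record\tchain\tposition\tlabel\tss\texposure\thydrophobicity"
             "\tdinucleotide\tcentroid_x\tcentroid_y\tcentroid_z"]
    for r in cx.protein_residues:
        lines.append(f"residue\t{r.chain_id}\t{r.position}\t{r.aa}\t{r.ss}"
                     f"\t{r.exposure}\t{r.hydrophobicity}\t\t\t\t")
    for s in cx.steps:
        x, y, z = s.base_centroid
        lines.append(f"step\t\t{s.index + 1}\t\t\t\t\t{s.dinucleotide}"
                     f"\t{x:.3f}\t{y:.3f}\t{z:.3f}")
    return "\n".join(lines) + "\n"
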