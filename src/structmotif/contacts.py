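"""Amino-acid <-> dinucleotide contacts and their 48-way classification.

A contact joins one amino acid with one dinucleotide step (two contiguous
nucleotides plus their complementary pair); its distance is measured from
the residue C-beta to the mean position of the step's nitrogen-base atoms.
Each contact carries a structural-environment class combining residue
hydrophobicity (2), secondary structure (3), solvent exposure (2), the DNA
groove nearest to the residue (2) and the strand side of that nearest atom
(2) -- 48 classes in total, giving a potential contact space of
16 dinucleotides x 20 amino acids x 48 classes = 15 360.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .structure import (AnnotatedComplex, DinucleotideStep, ProteinResidue,
                        STANDARD_AA)

# --------------------------------------------------------------------------
# class space
# --------------------------------------------------------------------------

HYDROPHOBICITY_LEVELS = ("polar", "nonpolar")
SS_LEVELS = ("helix", "strand", "coil")
EXPOSURE_LEVELS = ("buried", "exposed")
GROOVE_LEVELS = ("major", "minor")
STRAND_SIDE_LEVELS = ("leading", "complementary")

AA_ALPHABET = STANDARD_AA  # "ACDEFGHIKLMNPQRSTVWY"
DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")

N_AA = len(AA_ALPHABET)            # 20
N_DINUC = len(DINUCLEOTIDES)       # 16


@dataclass(frozen=True)
class ContactClass:
    hydrophobicity: str
    ss: str
    exposure: str
    groove: str
    strand_side: str

    def __post_init__(self):
        if (self.hydrophobicity not in HYDROPHOBICITY_LEVELS
                or self.ss not in SS_LEVELS
                or self.exposure not in EXPOSURE_LEVELS
                or self.groove not in GROOVE_LEVELS
                or self.strand_side not in STRAND_SIDE_LEVELS):
            raise ValueError(f"invalid environment labels: {self}")


ALL_CLASSES: tuple[ContactClass, ...] = tuple(
    ContactClass(*combo) for combo in itertools.product(
        HYDROPHOBICITY_LEVELS, SS_LEVELS, EXPOSURE_LEVELS,
        GROOVE_LEVELS, STRAND_SIDE_LEVELS))

N_ENV = len(ALL_CLASSES)                       # 48
CONTACT_SPACE_SIZE = N_DINUC * N_AA * N_ENV    # 15 360

_CLASS_INDEX = {c: i for i, c in enumerate(ALL_CLASSES)}
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
_DINUC_INDEX = {d: i for i, d in enumerate(DINUCLEOTIDES)}


def class_index(env: ContactClass) -> int:
    return _CLASS_INDEX[env]


def aa_index(aa: str) -> int:
    return _AA_INDEX[aa]


def dinuc_index(d: str) -> int:
    return _DINUC_INDEX[d]


# --------------------------------------------------------------------------
# contact extraction
# --------------------------------------------------------------------------


@dataclass
class Contact:
    residue: ProteinResidue
    step: DinucleotideStep
    distance: float
    env: ContactClass

    @property
    def aa(self) -> str:
        return self.residue.aa

    @property
    def dinucleotide(self) -> str:
        return self.step.dinucleotide

    @property
    def step_index(self) -> int:
        return self.step.index


def _classify(residue: ProteinResidue, step: DinucleotideStep) -> ContactClass:
    """Environment class of a residue/step pair.

    The groove and strand side come from the step base atom nearest to the
    residue's C-beta (backbone atoms are excluded, the groove partition is
    over base atoms only).
    """
    base_atoms = [a for a in step.atoms if a.groove != "backbone"]
    coords = np.asarray([a.coord for a in base_atoms])
    d = np.linalg.norm(coords - residue.cb_coord, axis=1)
    nearest = base_atoms[int(np.argmin(d))]
    return ContactClass(
        hydrophobicity=residue.hydrophobicity,
        ss=residue.ss,
        exposure=residue.exposure,
        groove=nearest.groove,
        strand_side=nearest.strand_side,
    )


def extract_contacts(cx: AnnotatedComplex,
                     max_radius: float = 30.0) -> list[Contact]:
    """All (residue, step) contacts with C-beta-to-centroid distance
    strictly below ``max_radius``.

    One contact at most per residue/step pair; the list is ordered by
    (residue order, step index).
    """
    contacts = []
    for residue in cx.protein_residues:
        if residue.ss is None or residue.exposure is None:
            raise ValueError("complex must be annotated before contact "
                             "extraction (ss/exposure missing)")
        for step in cx.steps:
            dist = float(np.linalg.norm(residue.cb_coord -
                                        step.base_centroid))
            if dist < max_radius:
                contacts.append(Contact(residue, step, dist,
                                        _classify(residue, step)))
    return contacts


# --------------------------------------------------------------------------
# contact tables
# --------------------------------------------------------------------------

PROVENANCES = ("pdb", "pbm")


class ContactTable:
    """Counted contacts by (amino acid, dinucleotide, environment, bin).

    Counts are stored per 1-Angstrom interval bin (bin b, 1-based, covers
    b-1 < d <= b) and per provenance ("pdb" for counts from structures,
    "pbm" for counts transferred from binding-microarray 8-mers).  The
    cumulative view at threshold x is the running sum of interval bins
    1..x.
    """

    def __init__(self, max_radius: float = 30.0, bin_width: float = 1.0):
        self.max_radius = float(max_radius)
        self.bin_width = float(bin_width)
        self.n_bins = int(math.ceil(self.max_radius / self.bin_width))
        self._counts = {p: np.zeros((N_AA, N_DINUC, N_ENV, self.n_bins))
                        for p in PROVENANCES}

    # -- indexing ----------------------------------------------------------

    def bin_of(self, distance: float) -> int:
        """0-based interval bin index: bin b covers (b*w, (b+1)*w]."""
        if distance < 0 or distance > self.max_radius:
            raise ValueError(f"distance {distance} outside table range")
        b = int(math.ceil(distance / self.bin_width)) - 1
        return max(b, 0)

    def bin_label(self, b: int) -> int:
        """1-based bin label as used in reports (bin 3 covers 2 < d <= 3)."""
        return b + 1

    # -- accumulation ------------------------------------------------------

    def add_contact(self, contact: Contact, provenance: str = "pdb",
                    count: float = 1.0) -> None:
        self.add_record(contact.aa, contact.dinucleotide, contact.env,
                        contact.distance, provenance, count)

    def add_record(self, aa: str, dinuc: str, env: ContactClass,
                   distance: float, provenance: str = "pdb",
                   count: float = 1.0) -> None:
        if count < 0:
            raise ValueError("counts must be >= 0")
        self._counts[provenance][
            _AA_INDEX[aa], _DINUC_INDEX[dinuc], _CLASS_INDEX[env],
            self.bin_of(distance)] += count

    def add_contacts(self, contacts, provenance: str = "pdb") -> None:
        for c in contacts:
            self.add_contact(c, provenance)

    # -- views -------------------------------------------------------------

    def counts(self, provenance: str | None = None,
               binning: str = "interval") -> np.ndarray:
        """Count tensor (aa, dinuc, env, bin).

        ``provenance`` None sums pdb and pbm sources; ``binning`` is
        "interval" (per-bin) or "cumulative" (threshold d <= x).
        """
        if provenance is None:
            arr = sum(self._counts.values())
        else:
            arr = self._counts[provenance].copy()
        if binning == "cumulative":
            arr = np.cumsum(arr, axis=3)
        elif binning != "interval":
            raise ValueError(f"unknown binning {binning!r}")
        return arr

    @property
    def total(self) -> float:
        return float(sum(a.sum() for a in self._counts.values()))

    def n_distinct_triples(self, provenance: str | None = None) -> int:
        """Distinct (aa, dinucleotide, environment) triples observed."""
        arr = self.counts(provenance)
        return int((arr.sum(axis=3) > 0).sum())

    def fingerprint(self, provenance: str | None = None) -> frozenset:
        """Set of occupied (aa, dinuc, env, bin) cells (redundancy filter)."""
        arr = self.counts(provenance)
        return frozenset(zip(*np.nonzero(arr)))

    def copy(self) -> "ContactTable":
        out = ContactTable(self.max_radius, self.bin_width)
        for p in PROVENANCES:
            out._counts[p] = self._counts[p].copy()
        return out

    def __iadd__(self, other: "ContactTable") -> "ContactTable":
        if (other.max_radius != self.max_radius
                or other.bin_width != self.bin_width):
            raise ValueError("incompatible table binning")
        for p in PROVENANCES:
            self._counts[p] += other._counts[p]
        return self

    # -- serialization -----------------------------------------------------

    def to_tsv(self) -> str:
        header = ("aa\tdinuc\thydrophobicity\tss\texposure\tgroove\t"
                  "strand_side\tbin\tcount\tprovenance")
        lines = [header]
        for p in PROVENANCES:
            arr = self._counts[p]
            for ia, idn, ie, ib in zip(*np.nonzero(arr)):
                env = ALL_CLASSES[ie]
                lines.append(
                    f"{AA_ALPHABET[ia]}\t{DINUCLEOTIDES[idn]}\t"
                    f"{env.hydrophobicity}\t{env.ss}\t{env.exposure}\t"
                    f"{env.groove}\t{env.strand_side}\t{ib + 1}\t"
                    f"{arr[ia, idn, ie, ib]:g}\t{p}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, max_radius: float = 30.0,
                 bin_width: float = 1.0) -> "ContactTable":
        table = cls(max_radius, bin_width)
        lines = [ln for ln in text.splitlines() if ln.strip()]
        for ln in lines[1:]:
            (aa, dinuc, hyd, ss, exp, groove, side, b, count, prov) = \
                ln.split("\t")
            env = ContactClass(hyd, ss, exp, groove, side)
            table._counts[prov][
                _AA_INDEX[aa], _DINUC_INDEX[dinuc], _CLASS_INDEX[env],
                int(b) - 1] += float(count)
        return table


def count_contacts(contacts, binning: str = "interval",
                   bin_width: float = 1.0,
                   max_radius: float = 30.0) -> ContactTable:
    """Bin extracted contacts into a :class:`ContactTable`.

    Interval mode stores one count in the bin x-1 < d <= x; the cumulative
    view (d <= x) is available from the table and satisfies
    cumulative(x) = sum(interval(1..x)).
    """
    if binning not in ("interval", "cumulative"):
        raise ValueError(f"unknown binning {binning!r}")
    table = ContactTable(max_radius, bin_width)
    table.add_contacts(contacts, "pdb")
    return table


def contact_abundance(table: ContactTable) -> float:
    """log10 of (potential contact space / distinct observed triples).

    The potential space is 16 x 20 x 48 = 15 360; full coverage scores 0 and
    the score decreases as more distinct (dinucleotide, amino acid,
    environment) triples are observed below 30 Angstrom.
    """
    n = table.n_distinct_triples()
    if n == 0:
        raise ValueError("contact abundance undefined for an empty table")
    return math.log10(CONTACT_SPACE_SIZE / n)
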