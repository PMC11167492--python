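"""Knowledge-based statistical potentials for protein-DNA interfaces.

A :class:`ContactTable` is turned into a distance-dependent log-odds score
over (amino acid, dinucleotide, environment, distance bin) cells -- the
ES3DC_dd-style potential -- with an optional polynomial completion of
unobserved bins and a per-contact Z-score transform (ZES3DC_dd) that
compares a contact's score against all 20 amino-acid substitutions in the
same (dinucleotide, environment, bin) context.  Lower energies and more
negative Z-scores are more favourable.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .contacts import (ALL_CLASSES, CONTACT_SPACE_SIZE, ContactTable,
                       N_AA, N_DINUC, N_ENV, aa_index, class_index,
                       dinuc_index)

PSEUDOCOUNT = 0.1

VALID_RADII = (15.0, 22.0, 30.0)


# --------------------------------------------------------------------------
# per-family parameterization
# --------------------------------------------------------------------------


@dataclass
class FamilyConfig:
    """Tuned parameters of one TF family's potential.

    ``contacts_db`` selects the training source (structure-only "pdb" or
    microarray-extended "pbm"); ``specificity`` chooses a family-specific or
    general potential; ``taylor`` switches polynomial completion of the
    contact space; ``binning`` is "bins" (interval) or "acc" (cumulative
    distance threshold); ``radius`` is the maximum contact distance in
    Angstrom; ``threshold`` is the normalized-score cut-off used to select
    top-ranked binding sequences for the PWM.
    """

    family: str = "general"
    contacts_db: str = "pbm"        # pdb | pbm (pdb + pbm extension)
    specificity: str = "family"     # family | general
    taylor: bool = False
    binning: str = "acc"            # bins | acc
    radius: float = 30.0
    threshold: float = 0.95

    def __post_init__(self):
        if self.contacts_db not in ("pdb", "pbm"):
            raise ValueError(f"invalid contacts_db {self.contacts_db!r}")
        if self.specificity not in ("family", "general"):
            raise ValueError(f"invalid specificity {self.specificity!r}")
        if self.binning not in ("bins", "acc"):
            raise ValueError(f"invalid binning {self.binning!r}")
        if float(self.radius) not in VALID_RADII:
            raise ValueError(f"radius must be one of {VALID_RADII}")
        if not 0.7 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0.7, 1.0]")


def load_family_configs(text: str | None = None) -> dict[str, FamilyConfig]:
    """Load per-family configurations from YAML (defaults ship with the
    package)."""
    if text is None:
        text = (importlib.resources.files("structmotif") / "data" /
                "family_config.yaml").read_text()
    raw = yaml.safe_load(text)
    out = {}
    for fam, rec in raw["families"].items():
        out[fam] = FamilyConfig(
            family=fam,
            contacts_db=rec.get("contacts_db", "pbm"),
            specificity=rec.get("specificity", "family"),
            taylor=bool(rec.get("taylor", False)),
            binning=rec.get("binning", "acc"),
            radius=float(rec.get("radius", 30)),
            threshold=float(rec.get("threshold", 0.95)),
        )
    return out


# --------------------------------------------------------------------------
# potential construction
# --------------------------------------------------------------------------


def _log_odds_scores(counts: np.ndarray,
                     pseudocount: float = PSEUDOCOUNT) -> np.ndarray:
    """Log-odds energy per (aa, dinuc, env, bin) cell.

    score = -log[ q(a,b,e;bin) / (P(a) * P(b,e)) ] with
    q = (N(a,b,e;bin) + k) / (N(bin) + k*K), K the 15 360-cell class space,
    and P the pseudocount-backed marginals of the table.  Enriched cells
    get lower (more favourable) energies; unobserved cells fall back to the
    pseudocount level and are always finite.
    """
    k = pseudocount
    K = CONTACT_SPACE_SIZE
    n_bin = counts.sum(axis=(0, 1, 2), keepdims=True)
    q = (counts + k) / (n_bin + k * K)
    n_tot = counts.sum()
    p_a = (counts.sum(axis=(1, 2, 3)) + k * K / N_AA) / (n_tot + k * K)
    p_be = ((counts.sum(axis=(0, 3)) + k * K / (N_DINUC * N_ENV))
            / (n_tot + k * K))
    ref = p_a[:, None, None, None] * p_be[None, :, :, None]
    return -np.log(q / ref)


class Potential:
    """Scoring object built from a contact table.

    ``binning="bins"`` keeps per-interval scores; ``binning="acc"``
    accumulates all contacts below the radius into a single distance
    threshold.  Scores are recomputed from the stored counts, so smoothing
    and serialization round-trips stay consistent.
    """

    def __init__(self, counts: np.ndarray, binning: str = "bins",
                 max_radius: float = 30.0, family: str = "general",
                 smoothing: bool = False, provenance: str = "pdb",
                 pseudocount: float = PSEUDOCOUNT,
                 score_fn=None):
        if counts.sum() == 0:
            raise ValueError("cannot build a potential from an empty table")
        self.family = family
        self.binning = binning
        self.max_radius = float(max_radius)
        self.smoothing = smoothing
        self.provenance = provenance
        self.pseudocount = pseudocount
        self._score_fn = score_fn or _log_odds_scores
        self.counts = counts  # interval counts restricted to the radius
        if binning == "acc":
            eff = counts.sum(axis=3, keepdims=True)
        elif binning == "bins":
            eff = counts
        else:
            raise ValueError(f"unknown binning {binning!r}")
        self.scores = self._score_fn(eff, pseudocount)
        mu = self.scores.mean(axis=0, keepdims=True)
        sd = self.scores.std(axis=0, keepdims=True)
        # treat numerically flat substitution profiles as sd = 0 -> Z = 0
        flat = sd[0] <= 1e-10 * max(float(np.abs(self.scores).max()), 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (self.scores - mu) / sd
        z[:, flat] = 0.0
        self.zscores = z

    # -- lookups -----------------------------------------------------------

    def bin_of(self, distance: float) -> int:
        if distance >= self.max_radius:
            raise ValueError(f"distance {distance} beyond potential radius")
        if self.binning == "acc":
            return 0
        return max(int(np.ceil(distance)) - 1, 0)

    def score(self, aa: str, dinuc: str, env, distance: float) -> float:
        return float(self.scores[aa_index(aa), dinuc_index(dinuc),
                                 class_index(env), self.bin_of(distance)])

    def zscore(self, aa: str, dinuc: str, env, distance: float) -> float:
        return float(self.zscores[aa_index(aa), dinuc_index(dinuc),
                                  class_index(env), self.bin_of(distance)])

    def zscore_vector_dinuc(self, aa: str, env,
                            distance: float) -> np.ndarray:
        """Z-scores over all 16 dinucleotides for a fixed contact context."""
        return self.zscores[aa_index(aa), :, class_index(env),
                            self.bin_of(distance)]

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "format": "structmotif-potential",
            "version": 1,
            "family": self.family,
            "binning": self.binning,
            "max_radius": self.max_radius,
            "smoothing": self.smoothing,
            "provenance": self.provenance,
            "pseudocount": self.pseudocount,
            "counts_shape": list(self.counts.shape),
            "counts": self.counts.ravel().tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "Potential":
        d = json.loads(text)
        if d.get("format") != "structmotif-potential":
            raise ValueError("not a serialized potential")
        counts = np.asarray(d["counts"]).reshape(d["counts_shape"])
        return cls(counts, binning=d["binning"], max_radius=d["max_radius"],
                   family=d["family"], smoothing=d["smoothing"],
                   provenance=d["provenance"],
                   pseudocount=d["pseudocount"])


def build_potential(table: ContactTable,
                    config: FamilyConfig | None = None,
                    score_fn=None) -> Potential:
    """Build a potential from a contact table under a family configuration.

    The training counts come from structures only (``contacts_db="pdb"``) or
    with the microarray extension added (``"pbm"``); bins beyond the family
    radius are dropped; Taylor completion, if enabled, imputes unobserved
    interval bins before scoring.
    """
    config = config or FamilyConfig()
    provenance = None if config.contacts_db == "pbm" else "pdb"
    counts = table.counts(provenance)
    n_bins = int(round(config.radius / table.bin_width))
    counts = counts[:, :, :, :n_bins]
    if config.taylor:
        counts = taylor_smooth_counts(counts)
    return Potential(counts, binning=config.binning,
                     max_radius=config.radius, family=config.family,
                     smoothing=config.taylor,
                     provenance="pdb" if config.contacts_db == "pdb"
                     else "pdb+pbm",
                     score_fn=score_fn)


# --------------------------------------------------------------------------
# polynomial completion ("Taylor's approach")
# --------------------------------------------------------------------------


def _bic_polyfit(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares polynomial of degree <= 2 chosen by BIC."""
    best = None
    n = len(x)
    for deg in range(0, min(2, n - 1) + 1):
        coef = np.polyfit(x, y, deg)
        resid = y - np.polyval(coef, x)
        rss = float(resid @ resid)
        bic = n * np.log(max(rss / n, 1e-300)) + (deg + 1) * np.log(n)
        if best is None or bic < best[0] - 1e-12:
            best = (bic, coef)
    return best[1]


def taylor_smooth_counts(counts: np.ndarray) -> np.ndarray:
    """Impute unobserved distance bins from a polynomial fit of log-counts.

    For each (aa, dinuc, env) profile with >= 2 observed bins, a degree <= 2
    polynomial (BIC-selected) of log-count versus bin index fills the
    zero-count bins; observed bins are never overwritten.
    """
    out = counts.copy()
    na, nd, ne, nb = counts.shape
    flat = counts.reshape(-1, nb)
    oflat = out.reshape(-1, nb)
    xs = np.arange(nb, dtype=float)
    for i in range(flat.shape[0]):
        row = flat[i]
        obs = row > 0
        n_obs = int(obs.sum())
        if n_obs == 0 or n_obs == nb:
            continue
        if n_obs == 1:
            oflat[i, ~obs] = row[obs][0]
            continue
        coef = _bic_polyfit(xs[obs], np.log(row[obs]))
        oflat[i, ~obs] = np.exp(np.polyval(coef, xs[~obs]))
    return out


def taylor_smooth(potential: Potential) -> Potential:
    """Return a copy of the potential with unobserved bins imputed."""
    return Potential(taylor_smooth_counts(potential.counts),
                     binning=potential.binning,
                     max_radius=potential.max_radius,
                     family=potential.family, smoothing=True,
                     provenance=potential.provenance,
                     pseudocount=potential.pseudocount,
                     score_fn=potential._score_fn)


# --------------------------------------------------------------------------
# redundancy filtering
# --------------------------------------------------------------------------


def contact_identity(fp_a: frozenset, fp_b: frozenset) -> float:
    """Fraction of identical (aa, dinuc, env, bin) contacts between two
    TF fingerprints (overlap over the smaller set)."""
    if not fp_a or not fp_b:
        return 0.0
    return len(fp_a & fp_b) / min(len(fp_a), len(fp_b))


def filter_redundancy(tables: dict[str, ContactTable],
                      mode: str = "family",
                      cutoff: float | None = None) -> list[str]:
    """Greedy selection of non-redundant TFs.

    TFs are visited in descending total contact count (ties by id); a TF is
    removed when its fraction of identical contacts with an already-kept TF
    exceeds the cutoff (0.70 for family-specific potentials, 0.40 for the
    general one).  Returns kept ids in visit order; idempotent.
    """
    if cutoff is None:
        cutoff = 0.70 if mode == "family" else 0.40
    order = sorted(tables, key=lambda t: (-tables[t].total, t))
    fps = {t: tables[t].fingerprint() for t in tables}
    kept: list[str] = []
    for tf in order:
        if all(contact_identity(fps[tf], fps[k]) <= cutoff for k in kept):
            kept.append(tf)
    return kept


# --------------------------------------------------------------------------
# complex scoring
# --------------------------------------------------------------------------


def zscore_contact(potential: Potential, contact) -> float:
    """Per-contact Z-score: the contact's energy against the mean and
    population SD over all 20 amino-acid substitutions in the same
    (dinucleotide, environment, bin) context; SD = 0 yields Z = 0."""
    return potential.zscore(contact.aa, contact.dinucleotide, contact.env,
                            contact.distance)


def score_complex(potential: Potential, contacts) -> dict[str, float]:
    """Interface scores of a complex: ES3DC_dd = summed energies,
    ZES3DC_dd = summed per-contact Z-scores (both additive, lower =
    better)."""
    es = 0.0
    zes = 0.0
    for c in contacts:
        if c.distance >= potential.max_radius:
            continue
        es += potential.score(c.aa, c.dinucleotide, c.env, c.distance)
        zes += zscore_contact(potential, c)
    return {"ES3DC_dd": es, "ZES3DC_dd": zes}
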