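# Methods

This note records the model, the numerical choices and the limits of the
synthetic validation, in the order the pipeline runs.

## Structure annotation

A complex is parsed from PDB text (Bio.PDB). Protein chains need at
least 3 residues; nonstandard residues are mapped to their parent
(MSE→MET etc.) or dropped with a warning. Glycine receives a virtual Cβ
from ideal tetrahedral N/CA/C geometry (bond 1.53 Å), so every residue
has the reference atom the contact definition requires.

DNA strands are paired by maximal complementary overlap over all
ungapped antiparallel offsets, with a proximity sanity check on C1'–C1'
distances; non-complementary pairs are kept but flagged as mismatches.
The *leading* strand is the one whose first paired nucleotide has the
lower author number. Step *i* covers leading nucleotides *i, i+1* and
their complements; its centroid is the unweighted mean of the
nitrogen-base (non-backbone) atoms of all four nucleotides, which makes
it invariant to which strand is called leading.

Secondary structure comes from a self-contained Kabsch–Sander-style
assigner: amide H positions are rebuilt from the previous peptide plane,
H-bonds use the electrostatic energy `0.084·332·(1/rON + 1/rCH − 1/rOH −
1/rCN)` with the conventional −0.5 kcal/mol cutoff, consecutive 3/4/5
turns give helices and bridges give strands; the 8 fine states collapse
to helix / strand / coil. Residues with missing backbone atoms fall back
to coil with a warning.

Solvent exposure uses a rolling-probe (Shrake–Rupley, 1.4 Å probe, 100
Fibonacci sphere points) surface over *all* heavy atoms — protein and
DNA, so interface residues are occluded by the duplex as they should
be — normalized by the Tien et al. (2013) theoretical maxima. The
relative-accessibility cutoff is config-exposed; the default 0.25 is the
conventional buried/exposed split. It operates on the package's own
containers rather than a parser's object tree so that synthetic
complexes assembled in memory can be annotated identically.

## Contacts and the 48-class space

One contact per (residue, step) pair, strictly below the radius (30 Å
default); the environment class is hydrophobicity (nonpolar =
{A,V,L,I,M,F,W,C,G,P}) × secondary structure × exposure × groove ×
strand side = 2·3·2·2·2 = 48 classes. Groove and strand side are decided
by the step base atom nearest to the residue Cβ; base atoms carry a
fixed major/minor table following the canonical chemical description of
the B-DNA groove edges (Hoogsteen edge → major, sugar edge → minor).
The factorization is a design choice: the feature list and the printed
sizes (48 classes, 15 360 total cells) pin down the axes but not their
order, so the class enumeration is kept in one place and is swappable.

Distance bins are 1 Å intervals `x−1 < d ≤ x`; the cumulative view at
threshold x is by construction the sum of interval bins 1..x, which the
tests assert on random tables.

## Potentials

The energy is a log-odds of the observed cell frequency against an
independence reference `P(aa)·P(dinuc, env)`, with pseudocount κ = 0.1
per cell (and κ·K mass in the denominators, K = 15 360). The functional
form sits behind a small strategy hook (`score_fn`) because variants of
this family of potentials differ in the reference state; everything
downstream only consumes ranks of Z-scores, which the chosen form fixes
sensibly: uniform tables give flat scores, enriched cells get the
minimum energy.

The Z-score of a contact standardizes its energy over the 20 amino-acid
substitutions in the same (dinucleotide, environment, bin) context
(population SD; numerically flat profiles give Z = 0). The complex score
ZES3DC_dd is the *sum* of per-contact Z-scores — additivity is what lets
the sequence score decompose over steps and makes the exact top-K
dynamic programme possible.

Polynomial completion ("Taylor" mode) imputes unobserved distance bins
per (aa, dinuc, env) profile from a BIC-selected polynomial of degree ≤2
fitted to log-counts over observed bins; observed bins are never
overwritten. Redundancy filtering is greedy in descending total contact
count (ties by id): a TF is dropped when its fraction of identical
(aa, dinuc, env, bin) cells with an already-kept TF — overlap over the
smaller fingerprint — exceeds 0.70 (family mode) or 0.40 (general).

Per-family parameters ship as YAML (`structmotif/data/family_config.yaml`)
with one record per family: contact source (structures only vs
PBM-extended), family vs general counts, Taylor on/off, interval vs
cumulative binning, radius ∈ {15, 22, 30} Å and the top-sequence
threshold ∈ [0.7, 1.0].

## PBM extension

8-mers classify as positive (E > 0.45), negative (E < 0.37) or discarded
(the band between); the three sets partition every experiment. Positive
8-mers are placed against the TF's PWM at every ungapped offset on both
strands; the best placement wins (ties: forward strand, smaller offset)
and is rejected below a floor — the median full-overlap score of 10 000
random 8-mers under a fixed seed — because unfiltered placements inject
noise. Homolog transfer uses one deterministic global alignment per pair
(BLOSUM62, gap open 10 / extend 0.5, first traceback); maps with a gap
aligned inside the interface are rejected outright. Extension re-emits
template contacts with placed nucleotides and mapped amino acids,
inheriting distances and environments, under provenance `pbm` — it never
touches `pdb` counts. Homolog contacts are transferred symbolically
(counts, not coordinates); no structures are modelled for homologs.

## PWM engine

The binding site is the contiguous nucleotide span of the contacted
steps: m contacted steps give an N = m+1 nucleotide site, scored as a
chain of N−1 dinucleotide steps whose per-step 16-vectors are the summed
contact Z-scores. Exhaustive mode (N ≤ 12) scores all 4^N sequences;
`dp_topk` runs a K-best Viterbi over the 16-state chain with
lexicographic tie-breaks and reproduces the exhaustive ranking exactly —
the tests assert identity for N ≤ 8 over 100 random potentials. Because
the score is exactly pairwise-decomposable, the DP replaces any
approximate search heuristic without loss.

Normalization maps the lowest (best) raw score to 1 and the worst to 0;
if every sequence ties, all get 1 so threshold selection stays
meaningful. PWM columns are selected-sequence base frequencies with 0.01
pseudocount per cell. MEME minimal I/O is lossless to 6 decimals and
rejects columns off by more than 1e-3 from unit sum.

## Motif comparison

Optimal ungapped alignment over all offsets with ≥4 overlapping columns
and both orientations; column similarity is the Pearson correlation of
probability 4-vectors (0 for constant columns); ties break by smaller
|offset|, then forward orientation. Significance is empirical: random
motifs of the query's width, columns i.i.d. from a Dirichlet
moment-fitted to the target database, with `p = (1 + #{null ≥ obs}) /
(M_null + 1)` and similarity = −log₁₀(p). The default M_null = 200 keeps
batch ranking fast; the null is cached per (width, target) and fully
seeded. Null p-values are near-uniform (KS < 0.1 at M_null = 1000 in the
tests). A Benjamini–Hochberg utility is provided for batch output but
off by default.

## Evaluation machinery

`normal score = 100·(M − rank + 1)/M`, nulled when the comparison with
the true motif is not significant (strict p < α, α = 0.05).
Rank-enrichment keeps each prediction's top-k (default 10 — a small k,
since large selections make the vote achievable at random) significant
matches, counts selections per database motif, and breaks count ties by
higher mean similarity then lexical id; a true motif absent from every
top-k is a no-coverage outcome, not a score. Nearest-neighbor transfer
bins neighbors by percent identity (identical residues over global
alignment length) into 10-point bins labelled 15..95; bin x covers
(x−10, x], with the top bin extended to 100 so a perfect match remains
usable.

The 8-mer classification benchmark follows the stated protocol: 10
repeats of negative sampling at ratios 1/100 or 1/500 (G+C-matched
negatives draw their G+C class from the positives' distribution first,
then a novel word within the class, so duplicate rejection cannot bias
composition), 5-fold cross-validation over TFs with the potential
trained only on other folds and never on a TF whose contact fingerprint
exceeds the redundancy cutoff against a test TF, families under 10 TFs
excluded. Areas under ROC and precision–recall curves use trapezoidal
integration.

The grid search sweeps 2 binnings × 2 Taylor × 2 contact sources × 2
specificities × 3 radii × 31 thresholds = 1 488 points and selects by
(i) most significant predictions, (ii) best mean similarity among
points within 1 of the maximal count ("similar number" has no printed
tolerance; 1 is the default), (iii) lowest threshold, then grid order
for determinism.

## Scanning and binding-site calling

Log-odds scores (base 2, probabilities floored at 1e-4) at every
position of both strands; `N` bases contribute zero. P-values come from
the exact discrete score distribution under the background, built by
column-wise convolution with 1/1000 score discretization — brute-force
word enumeration agrees within discretization error for widths ≤ 6. The
default reporting threshold is 5e-4.

The caller cuts a 420-nt window into 21 bins of 20 nt; bin b covers
1-based positions [20(b−1)+1, 20b], so the central bin 11 is 201–220.
Each PWM votes once: its best hit (lowest p, ties by score then leftmost
position) lands in the bin covering most of it (tied overlap → lower
bin). Maximal-vote bins are positive; the prediction is true iff bin 11
is positive, every other positive bin is a false positive. ROC curves
sweep the p-value threshold, average over experiments (≥2 required) and
report σ/√N standard errors.

## Synthetic data: what it does and does not show

The generator emits ideal B-DNA (3.4 Å rise, 36° twist) with schematic
base-atom placements whose major/minor shells are well separated, and
proteins either as ideal-dihedral peptides (NeRF-built helices or
extended chains) or as isolated residues aimed so a planted Cβ sits at
an exact distance from a chosen step centroid. Planted-preference
contact tables enrich one dinucleotide 5× per interface step over a
uniform baseline. Synthetic TF families share planted contexts at three
of seven interface steps so cross-validated potentials transfer, while
member-specific contexts keep fingerprints below the redundancy cutoff.

Passing the closed loops shows the machinery is self-consistent —
contacts are recovered where planted, potentials rank planted
preferences best, the predicted consensus equals the planted one, and
the benchmark separates planted positives (AUROC > 0.95) while shuffled
labels sit at chance. It does not show real-data accuracy: real
interfaces have correlated environments, non-ideal DNA geometry,
redundant homologs and experimental noise that the fixtures deliberately
omit, and the benchmark numbers on public PBM/motif databases depend on
those resources. Problem sizes in the shipped tests and acceptance
script (8-nt sites, 12-TF families, 10-motif databases, M_null = 200)
were chosen as the smallest sizes at which every property is
non-trivially exercised.

## Known limitations

- Homology modelling of TF structures, DNA conformation modelling and
  macro-complex assembly are out of scope; the engine accepts any number
  of input structures and emits one PWM each.
- The empirical comparison null is a stand-in with the same contract as
  the established motif-comparison tool's p-value; absolute p-values
  differ from that tool's, ranks and significance calls are what the
  pipeline consumes.
- The exact feature factorization behind the 48 classes and the
  appendix-level details of the Z-score and polynomial completion are
  design choices here, kept behind small interfaces so alternates can be
  swapped.
- Family labels are input metadata; the package does not re-derive
  family assignments.
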