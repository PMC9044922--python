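# Methods

This note documents the models and procedures implemented in `gfam`, the
conventions and defaults chosen where the underlying methodology leaves
room, and what the synthetic-data tests do and do not establish.

## Domain detection and family classification

Detection uses one position-specific scoring profile per domain type (AP2,
B3) rather than a full profile-HMM engine.  A profile is a matrix of
per-column log-odds scores over the 20 amino acids plus metadata (bit-score
threshold, the 1-based columns that carry the sub-family signal, and the
columns of the conserved Trp-Leu-Gly triple).  The bundled defaults are
built from consensus sequences with BLOSUM62 rows as column scores; the
profile TSV format is versioned and user-replaceable, so Pfam-derived
profiles can be substituted without code changes.

Scanning is affine-gap local alignment of the protein against the profile
(gap open 10, extend 1, in the profile's half-bit units).  Multiple hits
per protein are found by iterated best-alignment with masking; across
profiles, overlapping candidates are resolved greedily by score, then by
leftmost start — a deterministic, input-order-independent rule.  The
acceptance gate is a bit-score threshold stored in the profile (default:
half the consensus self-score).  This plays the role an E-value cut-off
plays in an HMM search: random flanking sequence scores far below it (a
random 200-residue protein scores well under half of the ~300 half-bit
self-score), while an intact planted domain scores at or near self-score,
so zero-noise recovery is exact.  Proteins shorter than half the profile
length return no hits rather than an error.

Family assignment is a total function of the hit architecture: one AP2 and
no B3 → ERF/DREB; exactly two AP2 → AP2 family; one AP2 plus one B3 → RAV;
anything else (including zero AP2) → discarded, with a warning for
unrecognized multi-domain combinations.  Counts over all labels always sum
to the number of input proteins.

Sub-family classification reads the residues aligned to profile columns 14
and 19 (1-based along the domain profile, the convention used when
counting along a Pfam domain alignment).  Each rule scores one point per
conserved residue — DREB: Val-14, Glu-19; ERF: Ala-14, Asp-19 — and the
higher score wins provided it is at least 1.  Ties fall to "other": this
covers both the no-conservation case (0–0) and the conflicting case (1–1,
e.g. Val-14 with Asp-19).  The conflict rule is a design choice, not an
observed convention; divergent domains are exactly what the "other" bucket
exists for, and the choice is deterministic over all 400 ordered residue
pairs.  A gap at both diagnostic columns also yields "other", with a
warning.  The WLG triple (columns 28–30 of the bundled profile) is
reported verbatim with gaps rendered as `-`, so variant cataloguing (WIG,
WID, GLG, …) needs no further alignment step.

## Protein biochemistry

Molecular weight is the sum of average (not monoisotopic) residue masses
plus one water (18.0153 Da), matching the kDa convention of the common
protein-analysis web services.  Non-canonical residues (including X) are
an error naming the offending position.

The theoretical pI solves net charge = 0 by bisection on pH ∈ [0, 14].
Net charge is the Henderson–Hasselbalch sum over the termini and the
ionizable side chains (D, E, C, Y acidic; H, K, R basic) with the
Bjellqvist pKa set, including its residue-specific N- and C-terminal
values.  The table is bundled as a TSV so an alternative set (e.g. the
EMBOSS values) can be swapped in.  Charge is strictly decreasing in pH,
so the root is unique; bisection stops at |charge| < 1e-4 or interval
< 1e-3.  Tests verify agreement with a dense grid scan to 1e-2 and with
an independent implementation (Biopython's ProtParam, which uses the same
pKa set but a different solver).

GRAVY is the arithmetic mean of Kyte–Doolittle indices, hence bounded by
[−4.5, 4.5] and invariant under sequence permutation.

## Duplication analysis

Pairwise scores come from global Needleman–Wunsch alignment under BLOSUM62
with affine gaps (open 10, extend 0.5 — the common BLOSUM62 convention;
the scoring scheme behind the published similarity-matrix service does not
pin gap costs, so they are configurable).  Alignment is delegated to
Biopython's `PairwiseAligner`; the first optimal traceback is taken, which
is deterministic per input.

All three percentages are normalized by the *longer* unaligned sequence
length: identity (identical aligned pairs), similarity (aligned pairs with
BLOSUM62 score > 0, identities included — the adopted reading of "similar
residues", which the matrix service does not define), and coverage (the
longer sequence's residues between the first and last column where both
sequences are aligned, i.e. excluding terminal gaps).  Identity ≤
similarity ≤ 100 and self-pairs score 100 by construction.

A pair is called segmental when coverage > 90 % AND identity > 90 %, both
strictly.  Identity, not similarity, is the gating quantity — it is the
stricter and more standard of the two — with similarity still reported
per pair for inspection.
Tandem refinement then upgrades segmental pairs that share a chromosome,
whose nearer gene ends are at most 100,000 bp apart, and that have no
other gene of the analyzed set between them ("one following the other").
Distance is measured between nearer ends, not midpoints.  Tandem calls are
therefore always a subset of segmental calls; a missing locus leaves the
pair segmental with a warning.  By default the all-vs-all comparison is
run within a family's sequence set, keeping the O(n²) alignment cost
proportional to family size.

At the default thresholds, duplicate partners simulated with 5 % point
mutations are called (expected identity ≈ 95 %) and partners with 15 %
mutations are not (≈ 85 %); for gap-free alignments the identity equals
1 − Hamming/length exactly, which the tests verify.

## Phylogeny

Distances are pairwise-deletion p-distances: sites where either sequence
of a pair carries a gap are excluded for that pair; a pair with zero
comparable sites is an error (and a skipped replicate during bootstrap).
p-distance is the default because it is the common default for
distance-based protein trees in desktop phylogenetics software; a Poisson
correction (−ln(1 − p)) is available behind a flag.  Multiple sequence
alignment is out of scope — the module consumes aligned FASTA, and the
synthetic generator emits gap-free alignments.

Neighbor joining follows Saitou–Nei with the Studier–Keppler Q-criterion.
Determinism is guaranteed by breaking Q-minimum ties at the
lexicographically smallest index pair and by clamping negative branch
lengths to zero.  The final three nodes are joined by the three-point
formulas into a trifurcating root, i.e. an unrooted binary tree with
2n − 3 edges.  For any additive input matrix the reconstructed tree's path
distances equal the input to machine precision, which is the test oracle
(random trees with U(0.5, 2) branch lengths, matrices derived by path
summation).

Bootstrap support resamples alignment columns with replacement, rebuilds
the NJ tree per replicate, and reports for each internal bipartition of
the point-estimate tree the percentage of replicates containing it.
Resampling is indexed by column with a caller-supplied seed, so supports
are reproducible and independent of taxon input order.

## Promoter cis-element scanning

Motifs are matched as exact IUPAC consensus signatures — no position
weight matrices — which mirrors signature-based cis-element reporting.
Both strands are scanned (a minus-strand hit is a match of the reverse
complement, positioned on the forward coordinate system), overlapping
matches are all reported, and promoter `N` never matches.  The bundled
catalog carries literature-standard consensi (ABRE ACGTG, G-box CACGTG,
DRE-core RCCGAC, CAAT-box CCAAT, MBS CAACTG, …) mapped to the seven
reporting groups; two entries (STRE, Unnamed-4) are flagged non-canonical
placeholders because their definitions live inside the scanning service
this module emulates and are not published as consensus strings.  The
catalog is data, not code: absolute counts depend entirely on it, which is
why only planted-truth exactness — not any published total — is a test
target.  Promoters are defined as the 2,000 bp upstream of the annotated
transcription start, extracted strand-aware.

## qPCR expression analysis

Per sample, ΔCt = Ct_target − Ct_reference.  Replicates are not paired
between conditions, so the treatment replicate's ΔΔCt subtracts the *mean*
control ΔCt of its (gene, genotype); the relative expression ratio is
2^−ΔΔCt per treatment replicate.  Technical repeats, if present as
duplicate rows, are averaged into one Ct before analysis.

Class-level aggregation deliberately mixes scales: FC is the arithmetic
mean of replicate ratios within genotype, then of genotype FCs within the
tolerance class; Log2FC is the arithmetic mean of per-replicate log₂
ratios across the class.  Under replicate variation FC ≠ 2^Log2FC
(AM ≥ GM), and published FC/Log2FC pairs produced by this design are only
mutually consistent under this reading — with log₂ applied to the mean
ratio instead, the pairs contradict each other.  Whether the class Log2FC
averages per-genotype or per-replicate log ratios cannot be fully
disambiguated from printed values; per-replicate averaging is used
throughout.

Thresholds: a gene is significantly up-regulated in a class when
Log2FC ≥ 1 and down-regulated when ≤ −1, boundaries inclusive.  The
four regulation-pattern groups are sign-based on the (tolerant,
susceptible) pair with zero counting as up — the convention needed for
genes with Log2FC of +0.04/+0.07 to group with up-regulated genes.

The trait rule scores *tolerance evidence* (significant up in tolerant,
significant down in susceptible: 0–2 points) against *susceptibility
evidence* (the mirror).  Evidence of both kinds → neutral; two points of
one kind → "highly"; one point via the class's own up/down grades into
"moderately highly" when the other class trends the opposite way without
reaching significance, else the plain label.  The rule is total over the
real plane; cells not observed in published data are filled by symmetry.
A pair with no evidence is reported as not differentially expressed.

## Phenotype

The heat damage index is defined here as the relative reduction of mean
root depth under heat, HDI = 100 × (mean_control − mean_heat)/mean_control
— the index is used in the source literature without a printed formula,
so this definition is the package's own and is unit-invariant by
construction.  Class HDI averages member genotypes.  The class comparison
is a two-sided Welch t-test (unequal variances, Satterthwaite df) on
per-replicate HDI values, with the degenerate equal-constant case defined
as p = 1.  Because no raw depth data are published, this module is
validated on synthetic data only.

## Synthetic data

Generators are pure functions of (parameters, seed).  A root seed fans out
through fixed named substreams (SeedSequence with a per-generator stream
id), so adding a generator never changes existing outputs.  Defaults
mirror the emulated study design: 2 tolerant + 2 susceptible genotypes ×
2 treatments × 3 biological replicates for Ct tables; a constant
housekeeping Ct of 20 with control ΔCt drawn once per (gene, genotype)
from U(2, 8) and Gaussian replicate noise applied to the heat arm;
2,000-bp promoters; tandem pairs separated by 2,510 bp (the few-kb
adjacency the duplication criteria target); control root depths around
100 mm.

Background sequence is scrubbed so planted signals are the only signals:
proteomes are rescanned and redrawn until the recovered domain
architecture equals the planted one, and promoter backgrounds are locally
redrawn wherever a planned motif matches outside its planted offsets.
This makes zero-noise recovery exact rather than probabilistic, which is
what the closed-loop tests assert.  A promoter plan whose motifs contain
one another (ABRE inside G-box) cannot satisfy exact recovery and is
rejected with an explanatory error.

What the synthetic data does *not* emulate: real domain divergence
(planted domains are consensus copies, so detection sensitivity at real
evolutionary distances is untested), genome-scale family sizes, base
composition bias, alignment gaps in the phylogeny inputs, amplification
efficiency differences in qPCR, and between-genotype effect heterogeneity
within a tolerance class.  Passing tests therefore establish correctness
of the rules and arithmetic, not recall on diverged real proteomes.

## Problem sizes and acceptance checks

`scripts/acceptance.py` regenerates everything from a seed and reports:
the regulation footer and trait/group agreement obtained by pushing the
18 published per-gene effects through the full 2^−ΔΔCt pipeline at zero
noise; domain/family recovery on a 220-protein proteome; exact NJ
reconstruction of 100 random 4–8-taxon additive trees; duplication calls
at 5 % vs 15 % mutation; the mean recovered Log2FC for a planted 2.62
effect over 50 noisy tables (replicate noise sd 0.2 cycles); the maximum
pI bisection-vs-grid discrepancy over 100 random peptides; promoter
planted-count exactness; and the heat-damage-index class difference for
planted 30 % vs 65 % indices.  These sizes keep the full run under a
minute on one core while leaving each estimate's sampling error far below
the decision thresholds involved.

## Known limitations

* The profile scanner is not an HMM: no per-position gap penalties, no
  E-values.  Sensitivity on strongly diverged real domains will be lower
  than HMMER's; the bundled profiles exist to make the classification
  rules executable and testable, and real analyses should substitute
  Pfam-derived profiles.
* Duplication calling ignores synteny and Ka/Ks; it implements the
  coverage/identity/distance criteria only.
* The CRE catalog is intentionally minimal; absolute element counts are
  catalog-dependent and not comparable across catalogs.
* NJ is the only tree method; no ML/parsimony, no rate heterogeneity.
* The qPCR module applies the threshold rule only — no efficiency
  correction and no inferential statistics on expression, matching the
  analysis it reproduces.
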