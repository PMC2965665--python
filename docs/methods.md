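# Methods

## Scope and shape

`nemabar` is organised as an analysis project: the computation lives in the
library under `src/nemabar/`, and the numbered scripts under `analysis/`
are thin drivers that run one stage each and write their tables under
`results/`. The library modules map one-to-one onto the pipeline stages:
sequence/taxonomy model and I/O (`core_seq`), translation and numt
screening (`mt_translation`), K2P distances (`distance_k2p`),
neighbor joining (`nj_tree`), gap analysis (`barcode_gap`), virtual PCR
(`insilico_pcr`), the QC orchestrator (`qc_pipeline`) and the simulator
(`synthetic_data`).

## Distance model

Pairwise divergence uses the Kimura 2-parameter model,
`d = −½·ln(1−2P−Q) − ¼·ln(1−2Q)`, with P and Q the transition and
transversion proportions over compared sites. K2P is not the best-fitting
model for AT-rich mitochondrial data, but it is the de-facto standard for
barcoding-gap work, which is the point of this package; gamma-corrected or
ML distances are deliberately out of scope.

Numerical choices:

- **Pairwise deletion.** Sites where either sequence carries a gap or an
  ambiguity code are skipped per pair, so fragments of unequal usable
  length remain comparable. Whether per-codon-position distances should
  instead use complete deletion is not standardised; pairwise deletion is
  used throughout.
- **Saturation.** Pairs with `1−2P−Q ≤ 0` or `1−2Q ≤ 0` have no finite K2P
  distance. They are reported as missing and listed in an exclusion
  report — never clamped to an invented maximum. Note that per-codon
  position matrices restrict to ~130 sites, where highly diverged pairs
  can produce extreme but finite third-position estimates (the estimator
  diverges as the logs approach their poles); ranges read from those
  matrices should be interpreted accordingly.
- **Codon positions.** One reading frame per alignment: the stop-minimising
  frame of the column-majority consensus, applied to all rows.

## Neighbor joining

Standard Saitou–Nei agglomeration, minimising
`Q(i,j) = (n−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)`. Exact Q ties are broken
by the lexicographically smallest taxon-id pair, where an internal node is
keyed by the smallest leaf id beneath it — this makes trees bit-reproducible
under taxon reordering (such ties genuinely occur after matrix reduction,
not only in degenerate inputs). Negative branch lengths are clamped to zero
with the deficit moved to the sibling edge, preserving path lengths. Trees
are unrooted and serialised with an arbitrary trifurcating root, branch
lengths at six decimals; labels with spaces are quoted.

Tree-based QC defines a *long branch* as a terminal branch longer than
`c_long` (default 3) times the median terminal branch, and a *taxonomic
outlier* as a long-branch leaf whose nearest leaf by path length carries a
different higher-taxon label. Both lines of evidence are required before a
leaf is removed, because a long branch alone may simply reflect sparse
taxon sampling; the trees are unrooted throughout, so no claim about
"basal" placement is made.

## Translation and numt screening

Translation uses NCBI table 5 (invertebrate mitochondrial). The
nematode-specific codon reassignment debate does not affect stop-codon
screening (the known deviation turns a stop into an amino acid, not the
reverse), so table 5 is used as-is. Codons containing ambiguity codes
translate to `X` and never count as stops — conservative with respect to
false numt calls.

A sequence is *frameshift-suspected* when its best frame (minimum internal
stops, ties to the lowest frame index) still contains internal stops, or
when an alignment gap run has length ≢ 0 (mod 3). These are exactly the two
signatures a pseudogene screen inspects. In the pipeline, the stop-codon
check translates each row in the alignment-consensus reading frame rather
than each sequence's own best frame: a pseudogene's stops cannot then be
hidden by an alternative frame choice, which is what makes the detection
of stop-carrying numts deterministic.

Length-deviant sequences (those that cannot join the modal-length
alignment) are globally aligned to the consensus with Biopython's
`PairwiseAligner` (match 2, mismatch −1, gap open −6, extend −1); their gap
runs are then classified by the same mod-3 rule into frameshifts (fatal)
vs in-frame indels (warning only, since genuine length-variable COI
fragments exist).

## QC cascade

Order: translation checks → indel calls → composition screen → K2P + NJ →
tree flags. Verdicts are assigned from a configurable fatal set; the
default marks `stop_codon`, `frameshift`, `composition_outlier` and the
*joint* `long_branch ∧ taxonomic_outlier` flag fatal, and `indel` a
warning. The composition screen flags sequences whose GC fraction deviates
from the set median by more than 0.15 (absolute): it stands in for a
database-similarity search for foreign origin, which cannot run without an
external reference database; GC displacement is the strongest
database-free signal for the same failure mode (the bacterial contaminants
this screen targets are markedly GC-richer than AT-rich nematode mtDNA),
and every QC report records this substitution. Sequences failing stages
1–3 are excluded before the tree stage, so distance saturation against
grossly foreign sequences does not block tree construction; should
saturated pairs remain, the affected sequences are dropped from the tree
stage and noted.

Chromatogram-level decisions (double peaks, usable read length) are not
computable from sequence data; sequencing success enters as a user-supplied
per-reaction boolean, tallied per primer and pooled per partition exactly
as a success-rate table.

## Virtual PCR

Primer/template matching uses IUPAC set-intersection semantics. A binding
site tolerates up to 2 mismatches over the primer but requires the three
template bases facing the primer's 3′ end to match exactly — an
approximation of annealing chemistry, where 3′-terminal mispairing blocks
extension. Amplicons are enumerated from all compatible forward/reverse
site pairs, capped at 3000 nt (extension-limit proxy), and classified
against a per-primer-pair expected-size window (I3-M11: 448 nt
primer-inclusive, Folmer: 709 nt, both derived from the primers' anchor
coordinates on the reference COI map); within ±10 % of the expected length
counts as the expected band. Outcome tallies recompute percentages from
counts at one decimal; note that 7/41 prints as 17.1 %.

## Synthetic surveys

The generator's defaults are the study conditions, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| fragment | I3M11, 393 nt | alternative: Folmer, 657 nt |
| base_freqs | A .27, C .12, G .19, T .42 | AT-rich coding mtDNA |
| kappa | 4 | transition/transversion rate ratio |
| codon_rate_multipliers | (1.0, 0.3, 8.0) | per codon position |
| intra_div | 0.005–0.03 | expected pairwise K2P within species |
| congeneric_div | 0.10–0.26 | between congeneric species |
| intergeneric_div_min | 0.12 | hard floor between genera |
| genus_branch_div | 0.08–0.16 | root-to-genus branch targets |
| design | 12 genera × 2 species × 3 specimens | 72 specimens |
| p_numt / p_contaminant | 0.10 / 0.05 | artifact injection rates |

Divergence is parameterised directly as expected K2P distance (not
time × rate), so generator targets and analysis estimates share units and
recovery is testable without conversion. Sequences evolve site-by-site
with Poisson substitution counts scaled by the codon-position multipliers;
the jump chain favours the transition partner kappa-fold and weights target
bases by the equilibrium composition, so repeated substitution does not
erode AT-richness toward a uniform composition (a purely symmetric chain
would). Substitutions creating a frame-0 stop codon are rejected
(purifying-selection proxy). The intergeneric floor is enforced, not just
expected: offending genera are re-evolved further from the ancestor until
the realised minimum between-genus distance among clean sequences meets
the floor. The 12×2×3 uniform design is a deliberate simplification of a
real survey's ragged taxon sampling (comparable scale: ~70–100 specimens,
tens of genera) chosen so that every relation class — intraspecific,
congeneric, intergeneric — is populated in every replicate.

Artifacts: a numt replaces its specimen's sequence with a copy evolved at
0.3× the mitochondrial rate (nuclear copies evolve slower, making them
dangerously similar to the real gene — the hard case) carrying either two
internal stop codons or a single-base deletion. A contaminant replaces the
sequence with a deeply diverged (target 0.35) descendant of the dataset
root pushed toward GC by transition-only changes at 30 % of sites; this
keeps its distances to genuine sequences finite (so it appears on the tree
as a long branch) while displacing GC by ~0.2, which the composition screen
detects. Independent random sequences would instead saturate K2P against
everything and could not be placed on a tree at all.

What the generator does **not** model: population-genetic structure within
species (specimens radiate from a star), indel evolution along genuine
sequences (indels are injected, not evolved), correlated taxon sampling,
sequencing noise, and heterogeneity of fragment length among genuine
sequences. Passing tests therefore demonstrate the pipeline's behaviour
under the assumed statistical structure, not robustness to every field
complication.

One empirical note: with ~60 deep synthetic sequences, the *fraction of
variable amino-acid columns* exceeds the nucleotide fraction (≈0.83 vs
≈0.67 on default data), because column-level variability saturates with
taxon count; shallower real datasets can show the opposite ordering. The
variability report therefore emits both ratios without asserting an order,
while the per-position K2P ranges do follow the rate multipliers
(position 3 ≫ position 1 > position 2).

## Problem sizes

The test suite and the acceptance script run replicate surveys at the
default 72-specimen design: 100 seeds for threshold-scan recovery, 50 for
QC sensitivity, 20 each for the acceptance script's pooled gap fractions
and sensitivities. These sizes give stable percentages (thousands of
intraspecific and tens of thousands of interspecific pairs pooled) while
keeping a full run in the low minutes on one CPU.
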