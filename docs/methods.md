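# Methods

`rfamforge` builds RNA family models (RFMs) for trans-encoded bacterial
sRNAs: starting from one experimentally defined *pivot* transcript, it
collects homologous loci from a set of genomes, assesses them with
sequence, structure, synteny and phylogeny evidence, and attaches a
search model (a covariance model, and for motif families a
thermodynamic matcher) that can find further members.  This note
documents the models, the defaults and their rationale, the numerical
choices, and what the synthetic benchmark does and does not show.

## 1. Energy model and folding

All structure computations use one compact nearest-neighbour model
(module `rnastruct`), in kcal/mol-like model units:

| term | form | default |
| --- | --- | --- |
| stack of pair q directly inside p | −(0.4 + w(p) + w(q)) | w: GC 1.5, AU 1.0, GU 0.5 |
| hairpin loop of L unpaired | +3.0 + 0.3·L | L ≥ 3 enforced |
| internal loop / bulge (l1, l2) | +1.6 + 0.4·(l1+l2) | enumerated to l1+l2 ≤ 30 |
| multiloop | +3.4 (close) + 0.4/branch + 0.1/unpaired | |
| external bases | free | |

This is deliberately *not* the Turner/Vienna parameter set.  The
pipeline's statistics (SCI, loc score, matcher energies) are defined
relative to this model, and its correctness contract is oracle-based:
the Zuker-style DP is tested against exhaustive structure enumeration
(energies evaluated through the independent loop-decomposition
function) on hundreds of random sequences up to 18 nt.  MFE ties are
broken by a fixed traceback preference (hairpin, then stack/internal by
ascending inner-pair position, then multiloop; external branches
leftmost), which makes folding deterministic; the tie-break is not
guaranteed to produce the lexicographically smallest co-optimal
dot-bracket string.

Consensus folding runs the same DP over alignment columns.  A column
pair is admissible when at least half of **all** rows (gapped rows count
against) can form a canonical/GU pair there; its score is the mean row
stack energy, plus a covariance bonus per distinct compensatory pair
type (default weight 1.0), minus a penalty per present-but-unpairable
row (default 1.0).  The all-rows majority rule matters: with an
any-row rule, a single aberrant sequence can push pairs into sparsely
occupied column regions and corrupt the consensus.  For an alignment of
identical rows every adjustment vanishes, so the consensus energy
equals the single-sequence MFE — which pins SCI = 1 for identical
sequences exactly.

## 2. Suboptimal pair bands

The Sankoff-style alignment does not consider every conceivable base
pair: each sequence contributes only pairs realisable in structures
within 20% of its MFE (`pair_band_set`).  The band is computed exactly
with an inside–outside pass (best energy of any structure *containing*
a given pair), and is itself oracle-tested against brute-force
enumeration.  20% keeps the pair lists at a few dozen entries for
sRNA-sized sequences while retaining all compensatory variants the
synthetic families generate.

## 3. loc score (simultaneous alignment and folding)

`loc_score` is this package's stand-in for a LocARNA-type score:
matched base pairs earn +8, matched characters +2, mismatches −1, gaps
cost 6 (open) + 2 per base; structure counts twice as much as sequence
per position.  Besides the pair-band restriction, the DP is banded to
diagonals within ±16 nt (widened by the length difference) — adequate
for homologs produced by short-indel evolution and exact on all
oracle-sized inputs.  The published threshold *ratios* are applied to
this score (0.33 prefilter, 0.75 auto-accept); its absolute scale is
internal, and self-score maximality (loc(S,S) ≥ loc(S,c)) is
fuzz-tested.

The SCI of a sequence set is consensus energy divided by mean
single-sequence MFE, with 0 (flagged) for structureless input; values
above 1 require the covariance bonus, i.e. compensatory variation.
Note the scale: with the default bonus (1.0 per distinct compensatory
pair type per consensus pair) a six-member family with heavily
covaried stems can reach SCI ≈ 1.5–2.5.  The *ordering* (identical = 1,
covaried > 1, structureless = 0) is the contract; the magnitude is a
property of this package's weights.

## 4. Homology search and E-values

The seeded search follows blastn conventions for short, somewhat
diverged nucleotide matches: exact 7-mer seeds, match +2 / mismatch −3,
affine gaps 2/2, Smith–Waterman extension banded ±24 diagonals around
the seed cluster.  Significance is a Karlin–Altschul expectation
K·m·n·e^(−λS) with λ, K calibrated empirically: maximal scores against
200 dinucleotide-shuffled decoys (Altschul–Erikson Euler-walk shuffle,
seeded) are Gumbel-fitted (λ = 1/scale, K = e^(loc/scale)/(m·n)).  The
semi-global scanner (global in the reference, free end gaps in the
subject; windows of 1.5× reference length, 50% overlap) has its own
calibration of the same form.  The default acceptance threshold is
E < 10⁻⁵, identical in every search round ("stringent threshold per
round"); iteration adds accepted candidates as queries and stops after
three rounds or at the first round that adds nothing.  Hits are widened
to cover the whole reference plus 10% margins, then semi-globally
trimmed; duplicates are merged at ≥ 50% reciprocal locus overlap.

Scan databases can be partitioned by taxonomy
(`filter_db_by_taxa`): the expensive semi-global pass is typically run
only against the closest taxonomic families, mirroring how such scans
are deployed in practice.

Protein-level synteny comparisons reuse the closed-form E-value with
the published gapped BLOSUM62 constants (λ = 0.267, K = 0.041, gaps
11/1) rather than a bespoke calibration; at the ~50-aa marker sizes
involved, conserved flanks sit orders of magnitude below the 10⁻⁶
threshold and the constant choice is uncritical.

## 5. The assessment funnel

Stages run in a fixed order; every decision lands in the candidate's
ledger. Thresholds (config `AssessmentConfig`):

0. hygiene: a candidate covered > 50% by one annotated protein-coding
   gene is discarded (flag `CDS_OVERLAP`) — trans-encoded sRNAs lie at
   loci distinct from protein genes, and without this rule scan hits
   inside conserved flanking ORFs pass the synteny stage trivially
   (their neighbours are the family's own markers);
1. prefilter: keep c iff loc(S,c) > 0.33·loc(S,S) (strict);
2. auto-accept: loc ratio > 0.75 AND sci(S,c) > 0.9 AND pointed-shape
   equality.  The pointed shape (level-5 abstract shape + hairpin
   centers (i+j)/2, exact halves kept) of the pairwise consensus mapped
   onto S is compared to that of S's MFE structure; centers may differ
   by ±2 nt (config, 0 = strict) because mapping through an alignment
   jitters center positions;
3. synteny: a candidate failing (2) is accepted if ≥ 1 flanking
   protein-coding gene matches the corresponding flank of an accepted
   member at E ≤ 10⁻⁶ (translated, BLOSUM62).  A side with no annotated
   gene is absent, not failing.  "Adjacent" is bounded: a gene farther
   than 300 nt (config) does not count as a flank, and the match must
   preserve relative orientation (the flank gene's strand relative to
   the sRNA must agree between candidate and member) — synteny is
   conserved order *and* orientation;
4. plausibility: accepted candidates are discarded (default; config
   keep-with-warning) on REPLICON_MISMATCH (same species as a member,
   different replicon class) or LONE_REMOTE (sole family hit in its
   family-level taxon with none in any closer group).  "Closely
   related" is bound to species level and "remote" to family level —
   both are config;
5. outlier pruning: from the multiple structural alignment (star
   alignment around the pivot), the member with the lowest consensus
   agreement is removed while that agreement is < 0.5, recomputing the
   alignment after each removal and never going below two members.

The agreement statistic deserves a note.  Naively, "fraction of
consensus pairs whose columns the member's row can pair" sounds right,
but the Sankoff aligner *optimises* pair matches: in testing, planted
random sequences scored 0.75–1.0 under that rule because their pairable
positions are dragged onto the consensus stems, so no 0.5 threshold
could ever fire.  The implemented statistic instead projects consensus
pairs onto the member through a sequence-only semi-global alignment
(±1 nt jitter tolerance) and requires the projected pair to occur in
the member's own suboptimal band.  Random 60-mers then score 0–0.25
while true members at divergence ≤ 0.4 score 0.6–1.0.

## 6. Covariance models

`build_cm` turns an alignment + consensus structure into a profile
SCFG: one pair node per SS_cons pair (16-way emission), one single node
per unpaired column, bifurcations at multiloop splits.  Emissions are
smoothed counts as log₂-odds against uniform background (0.25 / 0.0625).
Pair pseudocounts follow a structure prior — canonical/GU pairs share
90% of the pseudocount mass — so an *unseen compensatory* pair still
outscores a pair-breaking substitution, which is the point of a
covariance model.  Each node has match/delete probabilities estimated
from column gap fractions; insertions cost a flat 2 bits per base.
There are no local begins/ends and no HMM prefilter: at 50–250 columns
a vectorised CYK is fast enough.  CYK is oracle-tested against
exhaustive parse enumeration on ≤ 12-column models.

Scanning slides windows of 1.2× model length with stride
(window − model length), so no full-length occurrence can straddle all
window boundaries; within a window the best-scoring subspan is the hit
(flanks free).  Overlapping hits keep the best bits and at most the
best 50 hits are returned.  Family refinement iterates
build → scan → assess for up to three cycles, stopping when a cycle
adds nothing; the third cycle additionally requires a hit to reach 25%
of the highest member score.  A refinement hit overlapping an existing
member by more than 20% of the shorter locus is treated as a shifted
re-detection of that locus, not a new genomic copy (distinct sRNA
copies do not overlap); truly disjoint copies are admitted normally.

## 7. Thermodynamic matchers

A TDM searches for minimal-energy realisations of a structural motif:
stems constrained only by pairability and length bounds ("no weight to
the stem sequences"), hairpin loops by length and an optional IUPAC
motif they must contain, modules separated by bounded spacers.  Scans
are exhaustive within the constraint bounds (and anchored on loop-motif
occurrences when one exists), so hits provably satisfy every
constraint; the reported energy is the constrained structure's energy
under the folding model.  The default energy ceiling is −5.0 model
units; the pipeline's derived matchers instead use half of the pivot's
own constrained energy per module, which scales with module count.
Families with variable module numbers are handled exactly as the
workflow prescribes: one matcher per module count, overlap resolution
to the highest count afterwards.  An optional Rho-independent
terminator mask (GC-rich ≥ 6 bp hairpin, loop 3–8, ≥ 4 U within 5 nt)
can exclude terminator look-alikes, a known confusion source for short
GC-rich sRNA hairpins.

Matchers for the pipeline are derived automatically from the pivot's
MFE structure (`motif_from_structure`): stem bounds ±1 pair, loop
length ±2 with the observed loop sequence as motif, spacers ±50%.
This automates the "restrictive first, then relax" design loop.

## 8. Synthetic study conditions

The default dataset plants 3 families × 6 genomes (8 kb each, uniform
base composition), divergences 0.1 / 0.25 / 0.4:

* famA, famB: two-hairpin 70-nt transcripts (stems 6 bp, GC-biased);
* famC: three-hairpin 90-nt transcript with the anti-Shine-Dalgarno
  motif CCUCCUCCC frozen in every loop — the motif-family regime.

Evolution is structure-conserving: substitutions act per site at rate
d, so a pair is replaced (always by a *different* canonical/GU pair,
both partners together) with probability 1−(1−d)²; loop-motif positions
are frozen; unpaired non-motif positions substitute freely at rate d;
indels at rate d/5 fall only in unpaired non-motif regions.  Every
member is flanked by two family-specific ~150-nt marker ORFs mutated at
the same divergence (never creating stops), giving testable synteny;
decoys are Altschul–Erikson-shuffled members planted without markers.
The six genomes span two strains of one species, two further species of
the same family, and two genomes of a second family, so the
plausibility rules have structure to work with and no true member is a
lone remote hit.

These conditions realise the intended complementarity: at d = 0.1 the
seeded search alone recovers the family; at d = 0.25 iterated search
plus CM cycles are needed; at d = 0.4 the round-1 sequence search
misses members while the motif matcher (with synteny evidence) still
finds them.  What the benchmark does *not* emulate: real genomic base
composition and repeats, transcription signals, pseudogenes, paralog
copy-number variation, and real phylogenetic tree shapes — passing it
shows the machinery is correct and calibrated on its own terms, not
that the thresholds transfer quantitatively to real Rhizobiales
genomes.

## 9. Problem sizes and determinism

Defaults are desk-scale by design: 8-kb genomes, 60–90-nt transcripts,
≤ 3 search rounds, ≤ 3 CM cycles.  Every stochastic step (ancestor
design, evolution, genome assembly, decoy shuffling, EVD calibration)
takes an explicit seed; a run is reproducible byte-for-byte from its
config, and the pipeline log records config, seeds and per-stage
counts.
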