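# Methods

`httdetect` re-implements, as a tested pipeline, the inference chain used
to detect horizontal transposon transfer (HTT) in comparative snake
genomics: curate consensus sequences for repeat families, annotate
genomes with them, calibrate identity thresholds on orthologous
insertions, find recently expanding subfamilies, screen a panel of
genomes for presence/absence, and score candidate transfers against
three lines of evidence. This note records the models, the defaults and
why they are set where they are, and what the synthetic data do and do
not establish.

## The inference chain

**Curation (search–extend–align–trim).** Raw seed families (e.g.
RepeatModeler output) are first purged of redundancy: a family with
≥ 75% of its length aligning at ≥ 90% identity to a strictly longer
retained family is dropped (ties in length broken lexicographically by
id so the purge is order-independent). For each survivor the best 30
genomic copies by alignment score are collected, extended by 4000 bp of
flank, and the flanks cut back to the outermost position supported by
alignment to at least `min_support = 2` other copies. Because a repeat's
flanks are (in expectation) unique host sequence, this trims each copy
to approximately the element boundary; a pad of 25 bp of residual flank
is kept so target-site duplications (TSDs) remain visible. The trimmed
copies are aligned (MAFFT, single-threaded; `--localpair` by default,
FFT-NS-2 as the fast option for batch jobs) and a majority-rule
consensus is called: columns more than half gapped are dropped,
plurality base otherwise, ties collapsed to IUPAC codes (which
downstream identity computations treat as matching any compatible
base).

**TSD detection.** Per copy, an exact direct repeat of length
2–20 bp is sought with its two arms within ±5 bp of the element
boundaries. Short exact repeats near a fuzzy boundary are overwhelmingly
likely by chance (for k ≤ 3 the per-row chance exceeds 60% with this
wobble), so a length is only called when its row support clears both a
50% floor and the analytic chance rate plus 0.25; among eligible
lengths the largest with near-maximal support wins, which prevents the
one-base chance extension of a true TSD from inflating the call. A
consequence worth knowing: dinucleotide TSDs ("TA" of Tc1-Mariner)
are below this detection floor and must come from prior knowledge; the
classification rule table accepts them as input.

**Classification.** Ordered structural rules: (1) a hit from a
user-supplied motif table fixes the superfamily (the table is a
nucleotide stand-in for a protein-domain scan; a synthetic example
ships in `httdetect/data/example_motifs.tsv`); (2) terminal inverted
repeats (≥ 10 bp of the termini aligning to each other
reverse-complemented at ≥ 80%) plus a TSD give a DNA transposon, the
TSD length refining the superfamily via a configurable rule table;
(3) a 3' poly-A tract plus a TSD suggest a LINE; (4) otherwise Unknown.

**Annotation.** Every library family is searched against the genome;
overlapping hits are resolved greedily by score, trimming the
lower-scoring record to its largest free residue (dropped below the
80 bp minimum; overlaps of ≤ 10 bp are tolerated). Divergence
landscapes bin annotated base pairs by integer percent identity to the
consensus over [50, 100]; landscape and composition tables are exact
partitions of annotated bp, which the tests check to the base pair.

**Calibration.** From the focal genome's annotation, 5000 TEs ≥ 500 bp
are sampled (all of them, with a warning, when fewer qualify) and
extended by 1000 bp per flank. Each locus is searched against the
relative genome; a locus is accepted as orthologous when exactly one
hit covers ≥ 250 bp of the TE and ≥ 250 bp of flank. Loci with two or
more flank-containing hits are treated as potential segmental
duplications and excluded — this also conservatively drops loci whose
flanks contain fragments of other repeats. The identity-to-consensus
distribution of the accepted (ancestral) subset yields the operating
thresholds: `recent_threshold` is the 95% quantile (linear
interpolation between order statistics) rounded half-up to an integer —
half-up, not ceiling, so a quantile of 96.2 yields 96; the
`ancestral_detect_threshold` defaults to the conservative 80% floor,
with the 1st percentile of cross-genome identity available as a
derivation rule (`ancestral_detect_override=None`).

**Recent expansions and screening.** Families with ≥ 100 kb of copies
at ≥ 95% identity in any focal genome count as recently expanding. The
literal 95% gate and the calibrated `recent_threshold` are both
carried: the gate defaults to 95 and the calibrated value is reported
alongside, never silently substituted. Candidates are de-duplicated by
greedy length-sorted clustering at 95% global identity over the shorter
sequence (CD-HIT-style; order-independent by construction), optionally
filtered by the expression proxy (read coverage ≥ 1× over ≥ 95% of the
consensus for retrotransposons, of the motif-derived coding interval
for DNA transposons), and screened against every panel genome.
Presence requires both ≥ 80% identity and ≥ 100 bp aligned — the
length gate guards against spurious micro-hits and is configurable.
Classification is deliberately asymmetric: presence in *any* relative
genome makes a family ancestral; an HTT call requires absence from all
relatives plus presence in at least one distant genome; absence
everywhere outside the focal lineage leaves the family undetermined.
Calls are placed by single-gain (Dollo-like) parsimony on the branch
above the recipients' most recent common ancestor; losses are not
modelled.

**Evidence.** For each HTT call, consensuses are re-curated from every
carrier genome at 70% identity / 50% coverage (the relaxed threshold
deliberately pulls in divergent relatives usable as outgroups), split
in two when a 2-medoid partition of the per-species alignment separates
within- from between-cluster identity by ≥ 8 points, aligned, and
summarised as a neighbor-joining tree on p-distances (negative branch
lengths clamped to zero, ties broken by label order; trees are emitted
unrooted). The three evidence criteria are: patchy distribution
(present focal + distant, absent relatives), excess similarity (nearest
non-focal neighbour above the detectability floor and from a distant
group), and phylogenetic incongruence (the focal leaf's nearest
non-focal leaf by patristic distance is from a distant group). With
fewer than three consensuses a tree carries no topology and the
incongruence criterion degenerates to the nearest-neighbour comparison;
this is reported as such rather than skipped.

## Alignment machinery

Genome-scale search is delegated to `blastn` (discontiguous megablast,
the standard tool for diverged repeat search), with DUST and soft
masking disabled and, for genome-sized subjects, an indexed database
built on the fly. Identity and score of every hit are recomputed from
the returned alignment strings under the package's own convention —
identity is matches over all alignment columns, gaps included in the
denominator — so the thresholds (70/80/90/95/96%) mean the same thing
everywhere regardless of the search backend. The exact affine-gap
Smith–Waterman oracle (numba-compiled Gotoh with full traceback,
deterministic tie-breaking toward the smallest end position) provides
the ground truth that the seeded search is tested against: on random
pairs up to 25% divergence, reported hits must match the oracle within
1 identity point and 5 bp at each endpoint and never exceed its score.
The default scoring scheme is +2/−3 with gaps costing 5 + 2k, the
classic megablast-compatible choice, which keeps oracle and search
directly comparable. Multiple alignment is MAFFT; neighbor joining is
implemented in-package (the spec'd clamping and tie-break behaviour is
part of the contract) and cross-checked in tests against scikit-bio's
independent implementation on additive matrices.

## The synthetic panel

The simulator generates what the inference chain needs to be testable,
no more: i.i.d. background sequence at a set GC content evolving along
a species tree under Jukes–Cantor substitutions (branch lengths in
expected substitutions/site; the observable mismatch fraction
3/4·(1−e^(−4d/3)) is the closed form the tests assert against); TE
copies drawn independently from a family master at a per-copy
divergence, inserted with exact random TSDs on both sides and unique
flanks; and three planting modes — ancestral (inserted at an internal
node, by default the root, so copies are orthologous at identical
coordinates in all descendants), lineage-recent, and HTT (high-identity
copies in recipients and one distant donor, absent from intermediates).
Background and inherited sequence evolve by substitutions only; this is
what keeps ancestral insertion coordinates identical across genomes and
makes orthologue calibration verifiable against exact truth. The
optional 1–5 bp indel process applies only when copies are generated
from a master. One master seed drives everything; derived streams make
every output byte-reproducible.

What the simulator does not emulate — and hence what passing tests do
not establish about real data: assembly artefacts (collapsed recent
repeats, gaps, chimeric scaffolds), nested insertions, recombination
and segmental duplication (the calibration tests plant a duplication
explicitly as a fixture), GC/rate heterogeneity, lineage sorting, and
genuinely gradual divergence gradients within families. Results on real
assemblies depend on assembly quality in ways the synthetic panel
cannot show.

**The standard benchmark** (`httdetect.pipeline.benchmark_config`) is a
seven-genome panel of 2 Mb genomes: four focal species (stand-ins for
hydrophiine snakes), one close relative, and two distant aquatic
donors, with branch lengths placing the focal–relative background at
~85% identity and the distant genomes beyond alignability. Six
ancestral families arise in the focal+relative ancestor (copy
divergence 0.02 at planting, ~90% identity-to-consensus in extant
genomes) and keep expanding through recent bursts of 90 copies per
focal genome; three HTT families (90 copies each, divergence 0.02,
1200 bp masters, 8 bp TSDs) are planted into {all four focal}, {one sea
krait-like species}, and {one tiger snake-like species}, with fish- and
frog-like donors. Copy numbers are sized so every family clears the
100 kb recent-mass gate; master length and counts keep the whole run
inside a few minutes on one CPU.

## Problem sizes and numerical choices

The test suite and acceptance script use: the full 7 × 2 Mb benchmark
for end-to-end recovery; a 2-genome × 2 Mb pair with 500 sampled loci
(8 ancestral families × 80 copies, 3 recent × 60) for calibration
recovery, with a 60 kb duplicated block planted for the
segmental-duplication check; 50 seeded replicates (30 copies, 5%
divergence, 600 bp masters, 120 kb genomes) for consensus recovery;
1000 random pairs (100–500 bp, 0–25% divergence, 5% indels) for
oracle agreement; 100 random additive matrices (5–8 taxa) for NJ
exactness; and a 300 kb-per-genome rerun of the full pipeline, twice,
for byte-level determinism. Determinism throughout rests on: seeded
numpy generators with derived per-stage streams, single-threaded MAFFT
and BLAST, sorted iteration everywhere dictionaries feed output, and
explicit tie-breaking rules (purge order, hit sorting, NJ label order,
consensus IUPAC ties).

Degenerate inputs are defined rather than left to chance: empty
genomes annotate to nothing; a family with fewer than two genomic
copies yields no consensus (logged); a locus sample smaller than
requested is used whole with a warning; fewer than 50 orthologue pairs
is a calibration error instructing a larger sample; p-distances over
zero shared columns are flagged undefined (NaN) and refuse to enter a
tree.

## Known limitations

* Presence/absence is assembly-based; a family absent from an assembly
  is not necessarily absent from the genome.
* The expression proxy consumes user-supplied coverage vectors; no read
  mapping is performed.
* TE trees are unrooted NJ topologies without support values — adequate
  for the nearest-neighbour incongruence criterion, not for publication
  phylogenetics (alignments can be exported for external ML tools).
* Dollo placement ignores losses: a family lost from a relative genome
  and present in a distant one will be called HTT even if vertically
  inherited; the relative-presence rule is the (deliberately
  conservative) guard.
* Very short TSDs (≤ 3 bp) are undetectable de novo under boundary
  uncertainty, as discussed above.
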