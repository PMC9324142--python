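# Methods

This note records the models, parameter choices and numerical
conventions behind `retromob`, and what the synthetic experiments do
and do not establish about real data.

## Structural model of an intact LTR-RT

An intact copy is defined purely structurally: two long terminal
repeats (LTRs) in direct orientation, each beginning `TG` and ending
`CA`, separated so their start positions lie `min_dist`–`max_dist`
apart (defaults 3 000 / 15 000 bp), individually `min_ltr_len`–
`max_ltr_len` long (100 / 4 000 bp), at least 85% identical, and the
whole element flanked by an identical 2–20-bp target-site duplication
(TSD). "Distance" means the distance between LTR *start* positions.
`min_ltr_len` = 100 and `max_dist` = 15 000 are the conventional
defaults of detectors of this family; both are exposed as parameters.

Detection seeds on exact repeats: every k-mer of length `seed_len`
(default 80) is rolling-hashed (base-4 polynomial, uint64 wraparound;
hash hits are verified by direct comparison), and verified pairs at a
valid distance on the same diagonal are clustered into loci. Around
each locus the repeat extent is estimated by x-drop extension over the
match profile (+1 match, −3 mismatch, drop 18), candidate boundaries
are enumerated from motif positions within `tsd_vicinity` (60 bp) of
the repeat edges, and the boundary pair maximizing the ungapped match
score (matches − 2·mismatches) among those with a valid TSD is kept.
TSD search prefers the longest duplication in [2, 20]. Overlapping
candidates are resolved greedily by (identity desc, length desc,
leftmost). The LTR pair is compared ungapped; copies whose LTRs have
internal indels are found only if a seed-bearing diagonal still
satisfies the thresholds. Nested insertions are not resolved (an inner
element may shadow the outer one), and no strand is inferred
structurally — the arrangement is strand-symmetric; strand comes from
domain frames downstream.

A consequence worth stating plainly: detectability requires a
mismatch-free `seed_len`-mer shared by the two LTRs. Recently inserted
elements (near-identical LTRs) always have one; a 300-bp LTR pair at
5% divergence usually does not. The synthetic recovery experiments
therefore plant recent elements plus diverged pairs with long LTRs
(K = 0.02 over 2 500 bp), where a clean 80-mer survives with
overwhelming probability — the same detectability envelope the
seed-based detector family has on real genomes.

Solo LTRs are found by seeding query LTRs (k = 13) into the genome,
locally aligning candidate windows (match 2, mismatch −3, gap open −5,
extend −2) and keeping hits with ≥ 80% identity over aligned columns
and ≥ 90% query coverage that do not overlap an intact copy; the best
hit wins among overlapping ones.

## Classification hierarchy

*Superfamily/lineage.* Each element is translated in six frames and
reference peptides (headers `LINEAGE#DOMAIN#id`, domains GAG, PR, INT,
RT, RH) are locally aligned under BLOSUM62 (open −11, extend −1). The
best hit per domain type is kept if it reaches `score_min`, defaulting
to 60% of the self-score of the shortest reference peptide. A
subfamily's lineage is the majority best-hit label over its members'
hits; exact ties go to "unclassified" (reproducibility over coverage).
The lineage→superfamily table covers the usual plant lineages (Ale …
SIRE, TAR, Tork → Copia; Athila, CRM, Galadriel, Ogre, Reina, Retand,
Tekay → Gypsy).

*Subfamily.* One representative LTR per copy; an edge joins two copies
when local-alignment identity ≥ 0.6 and the aligned fraction of the
*longer* sequence ≥ 0.7 (the conservative overlap convention; the
shorter-sequence convention is a flag away in `ltr_pair_metrics`
callers). Subfamilies are connected components, labelled `sNNNN` by
descending size, ties by smallest member id. The partition provably
equals brute-force components of the thresholded pair graph because it
is computed exactly that way; the test suite still cross-checks
against an independently coded BFS.

*Family.* rt-domain nucleotide sequences are aligned progressively
along a star guide tree: the center minimizes total k-mer (k = 6)
distance, every sequence is globally aligned to it (match 2, mismatch
−3, open −7, extend −1) and the pairwise alignments are merged on
center coordinates ("once a gap, always a gap"). Columns with < 90%
non-gap occupancy are discarded. Pairwise K80 distances feed a
neighbor-joining tree (own implementation; negative branch estimates
clamped to 0); branch support is the percentage of column-resampled
bootstrap replicates (default 1 000; the recovery experiments use 100)
containing the same bipartition. Maximum-likelihood inference is
deliberately not used: the family rule consumes only support and
branch length, both defined for NJ, and NJ is exact on additive
matrices (asserted against scikit-bio's NJ in tests).

Families are maximal clades whose subtending branch has support > 70
and length ≥ 0.3 substitutions/site; descent stops at the first
qualifying edge, leaves under no qualifying edge form one residual
family, and terminal edges (no bootstrap uncertainty) qualify on
length alone. Families are numbered f1…fn by size, ties by smallest
member id; copies without an rt hit, and copies involved in saturated
(undefined) K80 pairs, go to the artificial family f0. When qualifying
clades nest, only the outermost is reported — the alternative (cutting
every qualifying edge) would split families further; the maximal
reading was chosen and is the only place the family definition is
genuinely open.

## Dating

At integration the two LTRs are identical; their divergence clocks the
insertion. LTR pairs are globally aligned (affine gaps); transitions P
and transversions Q are counted over ungapped columns only, since the
K80 model is defined on substitutions — gap columns carry no
substitution information. Then

    K = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q),    T = K / (2r),

with r = 1.3×10⁻⁸ per site per year, reported in Myr. Saturated pairs
(either log argument ≤ 0) are reported missing, never clamped, and are
excluded from means; mean-age intervals are t-based 95% CIs. Plain K80
is used (no gamma rate correction). Ages bin into 0.1-Myr half-open
bins. Gene context: distance 0 when overlapping a gene, otherwise the
minimum gap; genic means ≤ 1 kb; distances of 1–10 kb bin at 1 kb
(bin = ⌈d/1000⌉). Distribution comparisons use a χ² goodness-of-fit of
one sample's binned counts against the other's proportions plus a
two-sample KS test on the raw distances, both two-sided, with raw
p-values (no multiple-testing correction on these two tests).

## Read mapping

The internal mapper is seed-and-extend: exact 21-mers index the
reference; candidate diagonals are extended with the same x-drop rule
as the miner, gaplessly. This matches the synthetic error model
(substitutions only) and makes soft clips fall out naturally: whatever
fails to extend is clipped, with its sequence retained. Placements are
ranked by (matched bases desc, mismatches asc, reference id, position);
`n_best` counts co-optimal placements so callers can require unique
mapping. Terminal mismatches may be trimmed rather than counted — the
objective is the local score, which the exhaustive oracle test mirrors.
Gapped alignment, where genuinely needed (junction crossing, clip
realignment), uses edlib. SAM import/export is provided for external
alignments.

## eccDNA profiling and junctions

Read pairs with either mate mapping to an organelle reference (≥ 50%
of the read matched) are dropped. Reads are mapped to the element
library; per subfamily, RPKM = count·10⁹/(length·total mapped).
Enrichment between two samples is a 2×2 χ² without continuity
correction on [count, total − count]; when any expected cell is < 5
the p-value is Monte-Carlo simulated under fixed margins (10 000
draws; the exact enumeration over hypergeometric tables is implemented
as the test oracle). Bonferroni-adjusted p-values are attached across
tested subfamilies; raw p is always kept. Candidate-active subfamilies
need > 500 mapped reads and > 50% library-hit fraction; the 500-read
threshold is calibrated to ~0.5M-read libraries and is a parameter.

Junctions: for each element model two references are built — two-LTR:
element end joined to element start; one-LTR: internal end, one full
LTR, internal start. A read is junction evidence when it aligns across
the junction zone (the seal point for two-LTR; the entire LTR plus the
seal for one-LTR) with ≥ 15 aligned bases beyond each side. One-LTR
circles are *only* detectable this way because both of their
boundary adjacencies also occur inside the linear element; spanning
the whole single LTR is the unique signature, which requires
LTR length + 2·anchors ≤ read length. The signed junction indel (NHEJ
hallmark, |indel| ≤ 20 by default) is read off the gapped alignment
under two validity rules that testing showed to be necessary: all
indel operations must fall in one compact zone touching the seal, and
the flanks outside that zone must be near-exact (mismatch budget 3%
per base, minimum 2) — otherwise reads from the other topology can
launder their mismatching ends through scattered indels. Duplicate
fragments are collapsed before counting to damp rolling-circle
amplification bias (switchable).

## Insertion calling and validation

Reads shorter than 50 bp are discarded (quality trimming is assumed
upstream). A genome window (10 kb, non-overlapping; the window size
follows the cited windowed-detector convention) becomes a candidate
for subfamily S in a sample when ≥ 2 read pairs have one mate matching
S (≥ 40 matched bases) and the other mapped uniquely (single
co-optimal placement) into the window. Multi-mapping anchors are
dropped, so insertions whose flanks are repetitive go unreported — a
stated limitation shared with the original design.

Refinement collects soft-clipped reads around the window whose clip
(≥ 8 bp) realigns to an element terminus at ≥ 80% identity, in either
orientation. Each clip votes with its breakpoint, corrected for
microhomology: when the element terminus happens to match the flank,
the aligner extends through those bases and every read shifts by the
same offset, so the clip is realigned to the terminus and the located
offset subtracted (capped at 25 bp). Votes are clustered (gap > 200 bp
splits); the largest cluster within ~600 bp of the window (the
insert-size reach of an anchor inside it) is the refined interval,
reported only if its span is ≤ 200 bp; the left/right clip clusters of
a true insertion overlap by the TSD length, inferred when 2–20 bp.
Sites merge across samples within 200 bp; a site overlapping an
annotated reference copy is `reference`, present in ≥ 2 samples
`shared-non-reference`, else `private`.

The accuracy harness builds two references: the original, and one with
each reference insertion excised together with one TSD copy — the
empty pre-insertion allele, which regenerates informative soft clips
(N-masking is kept as an option but produces no clipped realignments
at the site). Every read set is assayed at every site against both: a
qualifying soft-clip call at an unmasked site is a false positive, a
masked site without one a false negative; rates are 100·count/(sites ×
samples), rounded half-even to one decimal, with raw counts always
reported so any rounding convention can be audited. On the printed
design of nine sites and four samples this yields 36 calls; one FN is
2.8%, two FP round to 5.6% (a count of 2/36 cannot round to 5.5% at
one decimal; raw counts disambiguate).

## Synthetic data: what it emulates and what it does not

Genomes are i.i.d. background at a configurable GC (default 0.38), so
there is no low-complexity or segmental duplication to inflate the
miner's false-positive surface — specificity results bound chance
repeats only. Planting duplicates the host bases before the insertion
point after the element, exactly as integration would. LTR pairs
diverge under the exact K80 process: for target distance d with
transition:transversion event ratio 2:1, the per-site difference
probabilities P(d), Q(d) are computed in closed form and applied as a
per-site multinomial, so the expected estimated K equals d without
simulation bias; the terminal dinucleotides are protected so structure
survives dating-scale divergence. Targets above K = 10 are rejected
(numerically unrecoverable). Reads are PE150-style: uniform fragment
starts (wrapping on circles), normal insert length (400 ± 40), FR
orientation, i.i.d. substitution errors at a constant rate, constant
quality — no indel errors, no quality model, no coverage bias. Genes
are non-overlapping random intervals; they carry no sequence signal.

Consequently, passing the recovery experiments shows the algorithms
are correct under their stated assumptions — exact breakpoints, exact
partitions, zero false calls — but says nothing about tandem repeats,
nested elements, GC-biased coverage, indel sequencing errors or
diverged element families on real assemblies, where the thresholds
(not the code paths) do the work.

## Problem sizes and determinism

The experiment drivers fix the study conditions: miner recovery on ten
1-Mb genomes with five planted elements each plus ten element-free
1-Mb controls; dating round trip on 100 LTR pairs of 600 bp at
K = 0.10; clustering oracle on 50 random sets; two-clade family
recovery on 100 replicates (4+4 taxa, 300-bp rt, 0.5 between / 0.03
within, 100 bootstraps); junction screen at 50× over both topologies ×
indels {−3, 0, +2} with ten linear controls; subline comparison on a
2×250-kb genome at 25× with 3 shared and 8/6 private insertions placed
≥ 12 kb apart (distinct windows); validation harness on a 2×100-kb
genome with nine reference insertions and four error-free 30× read
sets. All randomness flows from explicit integer seeds through
numpy Generators; the same seed reproduces byte-identical genomes and
identical results.

## Known limitations

Ungapped LTR-pair comparison in the miner; no PBS/PPT annotation; no
nested-element resolution; lineage ties unresolved by design; the
one-LTR junction criterion requires LTRs shorter than the read length
minus two anchors; insertion calling does not genotype allele
frequencies within heterogeneous samples; the mapper assumes
substitution-dominated reads (import SAM from an external aligner for
indel-rich data).
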