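# Methods

## Input model and coordinate conventions

The pipeline consumes per-individual CNV calls in the PennCNV `rawcnv`
dialect: one call per line with a region, SNP count, hidden state, integer
copy number and the source signal file. A call is by definition a
deviation from the diploid state, so `cn=2` records are rejected at parse
time. Copy numbers above 4 are accepted and retained (PennCNV rarely emits
them, but the class alphabet has an explicit >A4 bin). Sample ids default
to the basename of the signal-file token with its extension stripped; a
regex override exists because real rawcnv files embed full paths.

All coordinates are 1-based inclusive internally — the convention of
PennCNV and of the interval tables this kind of study publishes — and the
length of an interval is `end − start + 1`. BED input/output (0-based
half-open) is converted exactly once, at the file boundary. Chromosome
names sort naturally (chr2 before chr10); with the default
`autosomes_only=True` only numeric chromosomes are accepted, matching
callers configured for the 29 bovine autosomes.

## Sample QC

Samples are removed when any of the post-calling dispersion metrics
strictly exceeds its threshold: LRR standard deviation > 0.30, BAF drift
> 0.008, |waviness| > 0.08. Strict inequality (equality keeps) reproduces
the external caller's filter semantics; waviness is compared by absolute
value because it is signed in the wild. The removal report names every
failing metric. Filtering is monotone: loosening any threshold can only
keep more samples (property-tested).

## CNVR construction

CNVRs are the connected components of the ≥1-bp-overlap graph on calls,
with span equal to the union extent of the component. Abutting calls
(`end + 1 == start`) do **not** merge — adjacency joining is a distinct
operation reserved for the post-scan step, where it is applied to
*selected segments* only. A CNVR is `loss` if every member has cn < 2,
`gain` if every member has cn > 2, `both` otherwise; the three counts are
additive by construction. Singleton calls become CNVRs (no recurrence
filter). Ids are assigned in (chromosome, start) order so the output is
independent of input order.

Per-breed summaries re-run the merge on that breed's calls alone rather
than intersecting cohort CNVRs with breed carriers; re-merging is the only
construction under which every per-breed coverage is necessarily below the
cohort coverage, which is how such tables behave. Both constructions are
available (filter the calls, then merge).

Coverage fractions divide the summed CNVR lengths by the summed lengths of
the chromosomes in the provided sizes table; because CNVRs within a
chromosome are disjoint, the sum equals the bp union (checked against a
per-bp marking oracle in tests).

## Segmentation and genotypes

Each CNVR is partitioned at the breakpoint set
`{call starts} ∪ {call ends + 1}`; consecutive breakpoints delimit
candidate segments, kept only where covered by at least one call. Using
`end + 1` keeps everything 1-based inclusive without off-by-one holes.
Gaps inside a CNVR (possible when distant calls are chained through an
intermediate) yield no segment: uncovered bases are diploid for every
individual and carry no information. After partitioning, no call partially
overlaps any segment (a violated precondition raises).

The genotype of individual *s* at segment *g* is the copy-number class of
the unique call of *s* covering *g* — A0…A4 for cn 0…4, >A4 for cn ≥ 5 —
and A2 (diploid) where no call covers it, the only reading consistent with
treating cn = 2 as the normal control. Two same-sample calls over one
segment violate the no-overlap property of per-sample HMM output and raise
by default; an optional `most-extreme` policy keeps the class farthest
from diploid (ties resolved toward the loss).

Two numeric encodings feed the structure analyses. The default is one-hot
(one indicator per segment × observed class): the classes are categorical,
and A0 vs >A4 is not meaningfully "5 units" apart on a linear scale. A
copy-number encoding (0–5 per segment) is kept as an option. Under
one-hot, two individuals differing at k segments sit at Euclidean distance
√(2k).

## Population structure

Distances are Euclidean (default) or Manhattan on the encoded rows.
Tree building is agglomerative linkage — average (UPGMA-style,
size-weighted; default), complete, or single — implemented in-package with
a fixed tie-break (the pair whose smallest member ids sort first merges
first) so trees are reproducible bit for bit; tests cross-check the merge
heights against `scipy.cluster.hierarchy` and a brute-force agglomeration
oracle. Array-CNV papers usually label this step "N-J clustering" although
the generic tree-building functions they call are agglomerative; the
output here is an ultrametric tree with merge nodes at half the linkage
distance, exported as newick. Any outgroup behaviour (e.g. yaks versus
cattle) is emergent from the data, never special-cased.

PCA is a column-centred SVD. Explained fractions are σ_k² / Σσ² over *all*
singular values — fractions of the total variance, the quantity reported
as "PC1 explains x%". Component signs are fixed by making each
component's largest-magnitude loading positive. A constant matrix (zero
total variance) is rejected.

## Selection scan

Per segment, class frequencies are plain counts over each group's cells.
The statistic is the heterozygosity-based multi-allelic Fst on
group-size-weighted frequencies (equations in the README). Numerically,
Ht ≤ 1e−12 is treated as monomorphic and flagged undefined rather than
producing 0/0. The vectorised scan path is held to the scalar
`fst_segment` path to 1e−14, and `fst_segment` to an independently coded
transcription of the equations to 1e−12, in tests.

Ranking uses the defined-Fst rows; `monomorphic="zero"` optionally keeps
Ht = 0 rows at Fst 0, enlarging the top-quantile denominator (published
analyses are usually silent on this choice, and it changes the threshold,
so both are provided). With N ranked rows and quantile q (default 0.005),
m = ⌈qN⌉ and the threshold is the m-th largest Fst; *every* row at or
above the threshold is selected, so ties can push the selection past m —
the behaviour needed for "top 0.5%" lists whose lengths do not equal
⌈qN⌉ exactly.

Selected segments that overlap or abut (`end + 1 == start`) are unioned
into joined intervals (idempotent, order-invariant); genes overlap a
joined interval if they share ≥ 1 bp, and symbols are reported
deduplicated in gene-start order.

A two-group comparison re-runs segmentation on the union of the two
groups' calls only, so segment boundaries reflect exactly the individuals
compared; boundaries contributed by out-of-comparison samples would
otherwise split segments without adding information.

## Synthetic cohorts

The simulator emulates the study design the analysis assumes: groups of
individuals, a genome of autosomes, and disjoint CNV loci at which each
individual independently draws a class from its group's frequency vector.

- **Neutral loci** share one vector across groups (x = y, expected
  Fst = 0), drawn from a Dirichlet prior with default concentrations
  (0.3, 0.6, 28.0, 0.7, 0.3, 0.1) over (A0…>A4) — ~93% expected A2 mass,
  chosen to reproduce the sparsity of real call sets (order 10² calls per
  individual genome-wide, not thousands).
- **Planted loci** carry divergent per-group vectors and are the ground
  truth for recovery tests. Planted loci without explicit coordinates
  replace randomly chosen neutral loci, keeping the locus set disjoint.
- Loci are placed in equal slots per chromosome with ≥ 2 bp gaps, so each
  non-diploid draw emits exactly one call and the merge → partition →
  genotype round trip recovers every drawn class exactly (tested).
  Literally abutting equal-cn draws would coalesce into one call; the
  default geometry never produces them.
- QC metrics draw from normals well inside the thresholds, with a
  configurable contamination fraction (default 5%) pushed beyond one
  threshold to exercise the QC stage.
- The truth table stores generating vectors and the plug-in expected Fst
  computed through the *same* `fst_segment` code path, so truth and scan
  cannot drift apart.

What the simulator does **not** model: array intensities and LRR/BAF
tracks, linkage disequilibrium between loci, call-boundary uncertainty
(every carrier at a locus shares exact boundaries), and overlapping-call
geometry (interval-algebra stress tests use hand-placed calls instead).
Passing tests therefore demonstrate correctness of the pipeline's
algebra and statistics under the assumed generative model, not robustness
to HMM boundary noise in real array data.

## Test and verification scale

The planted-locus recovery check runs 20 independent seeds of a
2 × 50-individual cohort with 2,000 neutral and 10 planted loci
(plug-in Fst ≥ 0.5) and requires ≥ 9/10 planted loci in the top-0.5%
selection of every seed. The acceptance script simulates a 15-vs-11
comparison over 29 autosomes with ~2,900 loci — sized so the ranked
segment count (~2,000) matches the scale implied by top-0.5% lists of
~10 segments in published scans — and recomputes every reported quantity
from scratch at run time. Fst identities are swept over 10⁵ random
frequency pairs; equation agreement with an independent transcription is
checked on 10³ pairs at 1e−12.

## Known limitations

- The per-sample QC rule is implemented, but a study's exact removed set
  is only reproducible from its per-sample metrics, which are usually
  unpublished.
- `select_top_quantile` with very few ranked segments makes m = ⌈qN⌉
  small; at desk scale a q of 0.005 can select fewer segments than there
  are true divergent loci. This is a property of the rank cutoff, not of
  the statistic.
- Distances, linkage and PCA encodings are documented defaults, not
  canonical choices; published array-CNV analyses rarely state theirs, and
  all are configurable.
- The agglomerative tree is ultrametric; it is a clustering dendrogram,
  not a phylogeny with unequal rates.
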