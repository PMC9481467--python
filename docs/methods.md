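# Methods

`opucall` implements a species-level profiling workflow for near full-length
16S rRNA amplicons built around operational phylogenetic units (OPUs): reads
are quality-filtered, clustered into OTUs at the 98.7% species boundary,
placed in a neighbor-joining tree together with type-strain references, and
classified as cultured species, potentially new species, or potentially new
higher taxa.  A ground-truthed simulator generates every input the pipeline
consumes, so recovery of planted truth is measurable end to end.  This note
records the models, the parameters that matter, and the design choices made
where the design was genuinely open.

## Sequence identity

Every threshold in the pipeline rests on one identity measure: a global
pairwise alignment (match +1, mismatch −2, gap open −10 for the first gap
column, −1 per further column) followed by count-based identity — matches
divided by aligned columns, where columns occupied by terminal gaps are
excluded and internal gap columns count against identity.  Terminal gaps are
penalized during the search; leaving them free makes a short spurious
end-overlap optimal for divergent pairs and reports a meaningless identity
of 1.0.  Because co-optimal alignments can differ marginally in identity,
arguments are ordered canonically before aligning, making the measure
symmetric.  The dynamic program itself is scikit-bio's `pair_align`; the
scoring convention and identity semantics are defined here and are verified
in the tests against exhaustive enumeration of all alignments on short
sequences.

## Read QC

Reads carry the 27F (`AGAGTTTGATCCTGGCTCAG`) and 1492R
(`TACGACTTAACCCCAATCGC`) primers and arrive in random orientation.  Primer
search is Hamming-only (no indels) inside 30-base end windows with a
two-mismatch budget — at CCS-like error rates (~1.1 × 10⁻⁴ per base) indels
inside a 20-mer primer are vanishingly rare.  Both orientations are tried;
the insert between the primers is kept.  Trimmed inserts must fall in the
1,200–1,600 bp window (inclusive); out-of-window reads are discarded, since
no trimming target exists for them.

### Chimera model

Chimeras are detected de novo, per sample, on dereplicated uniques tested
against their strictly more abundant predecessors.  For a query of length L
and two candidate parents A and B, the two-segment model identity is
`max_b (matches to A in [0,b) + matches to B in [b,L)) / L`, computed from
per-base match profiles of the two pairwise alignments, so all breakpoints
are scored in one pass.  A read is called chimeric when three gates hold:

* the best two-segment identity reaches `chimera_score_min` (0.99) — the
  mosaic must explain essentially the whole read;
* the mosaic beats the best *single* parent by at least `chimera_min_gain`
  (0.002) — a read its best parent already explains gains nothing from a
  second parent.  An absolute cap on single-parent identity cannot work
  here: a genuine mosaic of two parents at 96% mutual identity still matches
  its majority parent at ≈ 0.98, so only the relative gain separates mosaics
  from clean reads;
* the two parents diverge by at least `chimera_min_div` (0.03), ruling out
  trivial "mosaics" of near-identical parents.

Between two diverged parents the mosaic score is constant on the plateau
between the divergent sites flanking the true junction (expected flank gap
≈ 25 nt at 4% parent divergence), so a single-base breakpoint is not
identifiable; the midpoint of the optimal plateau is reported.  With
parents ≥ 5% divergent the gain gate passes whenever the minority segment
exceeds ~4% of the read, which bounds sensitivity near 0.92 under uniform
breakpoints — chimeras with more extreme junctions are operationally
indistinguishable from their majority parent.

### Contaminants

Clusters from negative-control samples define the contaminant set; a
biological OTU is removed when its representative matches any control
representative at ≥ 98.7% — the species threshold, used because no finer
matching rule is published for this step.

## OTU clustering

Reads are pooled across biological samples, dereplicated (exact duplicates
merged, counts summed, deterministic order: count descending then id
ascending) and clustered greedily: each unique joins the *first-founded*
centroid it matches at ≥ 98.7%, otherwise it founds a centroid.  The ≥
comparison at exactly 0.987 is deliberate and used consistently here and in
classification: 16S identities are conventionally reported to one decimal
and the boundary value is treated as within-species.  The k-mer prefilter
may only skip a candidate it can prove below threshold; the only proof used
is an empty shared 8-mer set at a high threshold.  An exhaustive all-pairs
oracle with identical semantics exists solely to verify the production
path; the two are compared on hundreds of randomized fixtures.

Representatives are the most frequent member read (ties to the smallest
id).  Pooling before clustering (rather than per-sample clustering plus
merging) follows from the pipeline needing one OTU inventory across the
cohort.

## Placement and classification

Representatives are threaded onto the reference template (NAST-style): each
query is pairwise-aligned to its nearest reference and the alignment is
transferred into template coordinates, dropping query-specific insertions.
Columns with modal-residue frequency below 30% among non-gap characters are
masked before distance computation; a 50% non-gap occupancy requirement is
added because threaded queries have ragged ends that create gap-rich,
uninformative columns.  Distances are uncorrected p-distances — no
correction is assumed, and below ~25% divergence the NJ topology at this
scale is insensitive to Jukes–Cantor rescaling (the distance function is a
single switch point if correction is wanted).  The joint tree covers all
query representatives plus, per query, its 10 nearest references (union);
neighbor joining is the standard Saitou–Nei agglomeration on the
Q-criterion with two determinism rules: ties on Q resolve to the
lexicographically smallest label pair, and negative branch lengths are
clamped to zero with the deficit moved to the sister branch.  Output is
unrooted; a midpoint-rooted copy is used only for clade tests.

Classification applies three rules in priority order:

1. nearest type-strain identity ≥ 98.7% → the cultured species, regardless
   of tree position;
2. otherwise, if the smallest ancestral clade containing the query and at
   least one reference is unanimous in genus and the identity clears the
   genus floor (94.5%) → potentially new species of that genus;
3. otherwise the deepest rank (family → phylum) at which that clade is
   unanimous and whose identity floor (86.5 / 82.0 / 78.5 / 75.0) is met
   anchors a potentially new higher taxon; failing everything, the query is
   "Unclassified" within the phylum of its nearest reference.

The rank floors are the canonical 16S identity minima per rank and stand in
for the manual tree inspection the OPU approach normally requires; 16S alone
cannot reliably classify higher taxa, so the floors are configurable and
conservative.

OTUs merge into one OPU when they share category and anchor (and nearest
type strain, for cultured species) and their representative leaves — plus
the anchor's reference leaf for cultured species — span a clade containing
no outside leaf.  This strict connectivity keeps distinct lineages within
one genus separate (their parent strains sit between them) while rejoining
clustering-granularity splits of a single species.

## Profiling

Relative abundance divides OPU reads by the per-sample total after all
filters, including contaminant removal.  Presence is ≥ 1 read
(configurable).  Prevalence bins are twenty left-closed 5% intervals with
the final bin closed; the low-prevalence group is strictly below 15% of
samples.  The core-microbiota test returns all OPUs at or above a 60%
prevalence cutoff; an empty result is the "no core" conclusion.  Shannon
uses natural logarithms; Chao1 is the bias-corrected form
S_obs + F₁(F₁−1)/(2(F₂+1)).  The paired Wilcoxon signed-rank test drops zero
differences, assigns average ranks to ties, uses the exact tie-aware null
distribution (a dynamic program over doubled ranks) up to n = 25, and the
normal approximation with tie correction and continuity correction above.
Reported percentages round half-up to the printed precision of the quantity.

## Resistance-gene screening

Genes are searched against both strands of every contig with an affine-gap
Smith–Waterman (match +2, mismatch −3, gap of length k costs 5 + 2k),
implemented as a numba kernel with full traceback; scikit-bio's local
aligner is the independent oracle in the tests.  A hit requires nucleotide
identity ≥ 80% over aligned columns and aligned-gene coverage ≥ 70% of the
full gene length (numerator: aligned query span; denominator: gene length —
the ResFinder convention).  Per gene, overlapping loci (≥ 50% reciprocal of
the shorter) keep only the best score.  Thresholds are applied at the
nucleotide level; protein-space search is out of scope.

## Synthetic data

The generator is substitution-only along a rank hierarchy (phylum → family →
genus → species, one class/order per phylum), which keeps every sequence on
a common coordinate system (the template alignment is the identity) and
makes every planted identity exact: mutating k of L positions realizes
identity (L−k)/L.  Divergence budgets (10% phylum, 3.5% family, 2.5% genus,
0.9–1.85% species with disjoint mutation sets inside a genus) place realized
within-genus type-strain identities in [0.945, 0.982] and between-genus
identities below 0.945; both constraints are audited post-generation and
the database is resampled on violation.

Planted communities contain type strains (cultured truth), novel species
derived from a parent strain at 0.950–0.975 identity, and novel lineages
derived from phylum-consensus ancestors at 0.78–0.92 — both ranges keep a
margin around the 0.987 boundary so recovery tests are not threshold-flaky
(a separate boundary preset plants identities exactly at 0.987).  Occupancy
uses heavy-tailed lognormal taxon weights with a per-taxon quota enforcing
that no taxon exceeds 60% prevalence, while samples draw toward a truncated
normal richness target; within-sample abundances are lognormal.  Reads get
i.i.d. per-base errors at 1.1 × 10⁻⁴ (80% substitutions, 10% insertions,
10% deletions — a CCS-like composition), primers, random orientation,
two-parent chimeras with uniform breakpoints at rate 0.02, and contaminant
taxa shared between every sample and the negative control.

Two presets matter.  The default cohort (20 samples, 30 community taxa —
16 cultured / 9 novel species / 5 novel lineages — ~120 reads per sample) is
the unit on which end-to-end recovery is measured; it is small enough that a
full run takes minutes on one core.  The `survey_scale` preset (196 samples,
216 reference strains, 320 community taxa, richness target 49.17 ± 35.66)
reproduces the cohort-level statistics of a real ocular-surface survey at
the community level and is exercised where those moments are asserted; read
depth at the real scale (~6,000 per swab) is not simulated, and with only a
few hundred taxa the simulated low-prevalence tail is necessarily lighter
than a 1,700-OPU inventory's.  What passing recovery tests show is that the
decision rules and bookkeeping are correct under a realistic error model —
not that the pipeline reproduces any particular real community, whose
chimera mechanisms, length heterogeneity, and database incompleteness the
generator does not emulate.

## Numerical and degenerate-input conventions

Determinism everywhere: a single integer seed drives every generator
substream; clustering, NJ, and merging have explicit tie-breaks (count
descending / id ascending; lexicographic label pairs; total-count order).
Zero-total samples, all-zero count vectors, empty reference databases,
sub-three-label NJ inputs, and row pairs with no comparable columns raise
named errors rather than propagating NaNs.  All-gap alignment columns are
dropped silently by the conservation filter.  Wilcoxon with all-zero
differences warns and returns p = 1.

## Known limitations

* The chimera model is two-parent, single-breakpoint; multi-parent or
  near-breakpoint-free mosaics are out of reach by design.
* Rank anchoring above genus relies on fixed identity floors, which real
  taxa violate; the floors are parameters, not biology.
* The greedy clusterer scans centroids in founding order with an exact
  alignment per candidate; it is built for desk-scale cohorts (thousands of
  uniques), not million-read datasets.
* The simulator's substitution-only reference evolution means template
  alignment of references is trivially exact; query threading still
  exercises the indel path through read errors.
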