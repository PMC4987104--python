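# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `hcnskit`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The discovery model

A clade-specific highly conserved noncoding sequence (HCNS) is defined
operationally: a noncoding reference region for which every ingroup genome
carries a homolog at 100% identity over at least 100 bp, while no outgroup
carries a homolog conserved above the neutral-evolution threshold. The
defaults (identity 1.0, 100 bp, E ≤ 10⁻⁵ at a 3 × 10⁹ effective database
size) are deliberately stringent: with the short divergence times typical
of closely related clades, the conserved and neutral identity
distributions overlap heavily and type-I errors dominate, so the
definition trades recall of weakly conserved elements for near-certain
specificity of what it does call.

### Neutral threshold

The threshold is the mode of a genome-wide divergence distribution,
computed on a raw histogram with bins anchored at zero (default bin width
0.005 divergence units — the sources that use this procedure do not state
their binning, so it is an exposed parameter recorded in every report).
The mode is returned as the midpoint of the maximal bin, ties resolving to
the lower bin; identity-kind samples are converted to divergence
(1 − identity) so both sample kinds share one code path. The upper 1% of
values is trimmed first (synonymous-rate estimates have a heavy artifact
tail). A smoothed-density mode was considered and rejected: a kernel
bandwidth would be a second free parameter with more leverage over the
result than the bin width it replaced. The d_s sample serves only as a
consistency check: weak selection on some synonymous sites should place
its mode at or slightly below the noncoding mode, and the estimator
records whether that holds rather than altering the threshold.

### Local homology search

The search is a word-seeded (default word 11) ungapped extension with
X-drop 20 under +1/−3 match/mismatch scoring, reporting Karlin–Altschul
E-values E = K·m·n·e^(−λS) with the ungapped constants K = 0.711,
λ = 1.374; the effective search space defaults to query length × a
configured database size (3 × 10⁹), emulating a genome-scale search on
desk-scale inputs. Both strands are searched; minus-strand subject
coordinates are normalized to forward coordinates with strand `-`.
Diagonal bookkeeping skips seeds inside already-explored extents, so each
homologous segment is extended once. Because extension is ungapped, hits
terminate at indels; a pair of genomes at a few percent divergence
therefore yields hits that tile the alignable genome in indel-bounded
segments — which is exactly the hit population the downstream statistics
assume.

### Overlap resolution

Among query-overlapping hits only the longest is retained (ties: higher
identity, then smaller start), implemented greedily longest-first. One
tolerance is layered on top: consecutive ungapped segments of a single
homology chain broken at an indel routinely share a few chance-matching
bases across the junction, and discarding a several-hundred-bp segment
because it shares 5 bp with its longer neighbor destroys genuine coverage.
`resolve_overlaps` therefore takes a `slop` parameter (bp of terminal
overlap ignored when testing conflict); the operation default is 0 (the
strict rule), and the pipeline runs with slop 15 — far smaller than any
real redundant alternative alignment, far larger than junction slop.

### Perfect-conservation filter

A reference region becomes a candidate iff every ingroup species covers it
with qualifying homology. At `min_identity = 1.0` with sequences
available, each hit is first refined into its maximal exact-match runs
(runs ≥ `min_length` qualify): local alignments maximize score, so a
perfect element embedded in 98–99%-identity flanking sequence is otherwise
absorbed into a longer imperfect hit and could never satisfy a hit-level
100% rule. With `min_identity < 1` (or without sequences) the filter works
at hit level. Candidates are the cross-species intersections of qualifying
coverage, which makes accepted candidates pairwise disjoint by
construction. Rejected regions are kept, flagged `length` or `identity`,
for the audit table; all filters add flags instead of deleting candidates,
so the accepted set is independent of filter order.

### Outgroup exclusion

A candidate is vetoed iff its outgroup conservation exceeds the neutral
threshold — divergence (1 − identity) strictly below the threshold, with
boundary equality retaining the candidate and "no hit at all" retaining it
too (an unalignable ortholog is the strongest evidence of clade-specific
divergence). Two implementation choices matter:

* **Element-targeted search.** The pipeline queries each candidate's own
  sequence against the outgroup genomes rather than reusing whole-genome
  hits. A whole-genome outgroup hit that overlaps only a candidate's
  few-bp flank margin carries neutral background identity and would veto a
  genuinely clade-specific element on the strength of its flanks.
* **Element-wise conservation.** A hit's matches are spread over the full
  candidate length, so unaligned candidate positions count as divergent. A
  30 bp perfect fragment inside an otherwise saturated ortholog is 20%
  element-level conservation, not 100%.

### Chance probability

The per-comparison frequency f of hits meeting the length and identity
thresholds is measured on the resolved hit population; the probability of
a region qualifying in all n comparisons is reported as f ⁿ under
independence, together with the implied expected count. Independence
across comparisons is an upper-bound idealization — shared phylogeny
correlates the comparisons — so both the per-comparison and joint figures
are reported rather than folded into one number.

## Branch rates

Distances default to p-distance (the divergences involved are ≪ 0.75, so
the multiple-hit correction is sub-percent); Jukes–Cantor distance is a
flag, and the simulation studies use it because an unbiased estimator
makes parameter-recovery checks sharper. Gap columns are stripped before
any distance; elements retaining fewer than 50 columns are dropped and
logged (no minimum is prescribed by the procedure itself; 50 columns keeps
the per-element distance SE below ~0.03 at these divergences). The
reference terminal branch length is attributed entirely to the stem and
divided by the stem duration, because substitutions after the stem are
excluded by the 100%-identity construction of the elements. Negative
decomposition branch lengths (possible with noisy distances) clamp to zero
with a flag, never silently. The outgroup-2 side of the three-taxon star
spans 2·t_og2 − t_og1 years (terminal branch plus the internal segment).
Calibration defaults: stem 3.1 Myr, first-outgroup split 18.8 Ma, neutral
rate 1.1 × 10⁻⁹/site/year; the second-outgroup split age has no reliable
published consensus value in this context and must be supplied (the
synthetic tree uses 29 Ma, a standard catarrhini estimate).

The subtraction estimator applied to the published rounded inputs
(2.3 × 10⁻⁹ combined, 2.0 × 10⁻⁹ outgroup, 3.1/18.8 Myr) yields
4.1 × 10⁻⁹/site/year. The original analysis reports a slightly lower
value, presumably from unrounded intermediates; the package reports the
formula result and makes no attempt to match rounded output from rounded
input.

## Selection tests

* Density comparisons use per-interval variant counts and Welch's
  unequal-variance one-sided t-test (per-interval counts make an SEM
  definable; a pooled-site comparison would not).
* Insertions are anchored at the base preceding the inserted sequence;
  deletions span the deleted reference bases and count in every interval
  they touch.
* DAF bins carry σ = √(p(1−p)/N), the binomial standard error. (A version
  of this formula is sometimes printed without the radical; the quantity
  that makes dimensional sense as an error bar is the square root, which
  is what is implemented.)
* The chi-square spectrum-shift test merges bins upward until every
  expected cell reaches 1, logging each merge; merging preserves total
  counts.
* Flanking profiles: offset 0 is the mean identity of the central 100 bp;
  lateral 50 bp windows advance by 20 bp starting 30 bp inside each
  element edge; per-window means and SEMs are taken across alignments, and
  offsets are reported against the mean element half-length.
* Tajima's D uses the standard a₁…e₂ coefficient chain and is undefined at
  S = 0 (an error, not a sentinel value).

## Genomic context

The category partition is computed per base over label arrays (desk-scale
genomes make the O(genome) representation the simplest one that is
trivially a true partition). Precedence is UTR > intron > promoter >
intergenic: a UTR site is also a transcript site, and resolving upward
keeps the four fractions disjoint. Elements are assigned to every category
they overlap by ≥ 1 bp, and fractions are taken over assignments, not
elements — an element spanning a boundary legitimately counts in both
categories (published assignment counts exceed element counts, which
forces exactly this convention). Enrichment uses the hypergeometric upper
tail with Bonferroni correction over the tested terms; terms with no
background gene are dropped and logged.

## Occupancy profiles

Interval centers are start + ⌊length/2⌋; minus-strand intervals are
flipped; missing track positions are excluded per offset. The difference
test compares per-element mean scores (per-position scores are strongly
autocorrelated within an element, which would fake sample size). Overlap
depletion uses the empirical null (1 + #{null ≤ observed})/(n_reps + 1),
bounded away from zero by construction. Nucleosome-occupancy models are
not reimplemented: tracks are inputs.

## Orphan-gene filter

Set logic over presence tables (intersection over ingroup tables,
subtraction of any outgroup presence), then homology rejection with strict
inequalities at both thresholds (coverage > 0.70 AND identity > 0.50;
"exactly 70%" keeps the gene). Strictness at the identity threshold is
chosen for symmetry with the coverage threshold, whose published statement
is unambiguously strict. The pipeline is monotone: more tables or more
evidence can only shrink the final set.

## The synthetic world

The generator is the package's test bed and defines the study conditions:

* **Tree and calibrations.** Four ingroup hominids (human, chimpanzee,
  gorilla, orangutan; splits 6.9/8.8/15.7 Ma) plus gibbon (18.8 Ma) and
  macaque (29 Ma), neutral rate 1.1 × 10⁻⁹/site/year on every branch
  unless overridden, indel rate 10⁻⁴/site/Myr with geometric lengths of
  mean 3 bp — roughly a tenth of the substitution rate, enough to break
  homology into a few-hundred-bp hit mosaic as real alignments show.
* **Substitutions** follow the Jukes–Cantor closed form per site (change
  probability (3/4)(1 − e^(−4d/3))); identity-based thresholds are
  insensitive to substitution-model detail at these divergences, which is
  why the simplest model is the right one here.
* **Planted regimes.** *Conserved* elements freeze on the stem and every
  ingroup branch — anciently conserved elements whose outgroup orthologs
  remain conserved, which the outgroup filter must veto.
  *Stem-accelerated* elements run at multiplier × rate on the stem and
  freeze in the ingroup crown — the inferred history of clade-specific
  elements. *Neutral decoys* are bookkeeping entries of plain background.
  Indels are suppressed inside conserved and accelerated elements on all
  branches (an indel would otherwise silently redefine the element).
* **Discovery-world default multiplier 60** (stem divergence ≈ 0.2/site).
  The rate-estimation studies use multiplier 5 — the level actually
  estimated for such elements — but at multiplier 5 an element's outgroup
  divergence (stem 0.017 + outgroup branch 0.021) sits *below* the
  neutral full-path divergence (0.041): per-element sampling noise at
  150 bp would then make outgroup exclusion a coin flip and recall
  targets meaningless. The strong default emulates the majority of real
  clade-specific elements, whose ancestors diverged beyond outgroup
  mappability altogether (two-thirds of the real set could not be mapped
  to outgroups at all), and makes discovery guarantees deterministic
  properties of the generator rather than lottery tickets.
* **Polymorphisms.** Variant counts are Poisson with per-site density θ;
  derived-allele counts i ∈ [1, n−1] are drawn ∝ 1/i (the neutral
  frequency spectrum) or ∝ i^(−2) inside constrained intervals under the
  purifying regime, whose density is additionally scaled by a factor < 1
  (default 0.5; the density contrast study uses 2.4/2.9 ≈ 0.83, the ratio
  of human-calibrated element vs background SNP densities). Frequency-1.0
  records are never emitted, matching the upstream convention of
  discarding fixed differences.
* **What it does not emulate:** coalescent genealogies, recombination and
  linkage, GC/CpG composition effects, rate heterogeneity along the
  genome, segmental duplication, and alignment error. Passing tests
  therefore certify the *procedure* — its filters, estimators and
  statistics — under a clean neutral-plus-elements model, not robustness
  to every artifact of real genomes.

## Problem sizes

The standard study conditions are a 100 kb genome over six species with
20 planted elements for end-to-end discovery; 200 elements of 300 bp for
rate recovery; 10,000 windows of 1 kb for threshold recovery; 200 and 100
replicates at n = 500 DAFs for the Fisher test's type-I error and power;
and 1,000 null replicates for overlap depletion. These sizes put every
Monte-Carlo standard error well inside the tolerances asserted and keep a
full run in tens of seconds on one CPU.

## Known limitations

* The ungapped search fragments at every indel; there is no chaining step,
  so "one homologous region" is represented by several hits. The
  statistics are designed around that representation.
* Cross-species independence in the chance-probability estimate is an
  idealization; the reported expected count is a lower bound on what
  correlated phylogeny actually produces.
* The audit's `identity`/`length` flags describe the conservation stage
  only; candidates already rejected there skip the outgroup search, so
  their outgroup columns are empty (the accepted set is unaffected).
* External-format support is deliberately minimal (no bigWig, no
  genotype-level VCF, no GFF3); the readers convert the supported dialects
  to the internal 0-based half-open convention and nothing more.
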