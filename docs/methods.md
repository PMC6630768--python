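# Methods

## Darkness mapping

A residue is non-dark when covered by the union of criterion-A and
criterion-B intervals; there is no weighting by alignment quality and no
minimum length for a dark region (a single dark residue is a run; a
configurable minimum exists for sensitivity analyses). Classification uses
the exact thresholds: white requires D = 0 with no tolerance, dark requires
D = 1. All residue coordinates are 1-based inclusive (the UniProt FT
convention); conversion to 0-based half-open happens only inside array code.

The four-way proteome partition is computed on a **residue basis**: each
category's residue count over the total residues of the universe. This is
the reading under which the four percentages sum to 100 and total darkness
equals dark-protein % + dark-region % — an identity the test suite asserts
on every randomly generated universe.

## Annotation enrichment

The enrichment unit is the exact string triple (field, subcategory, text);
a protein contributes at most once per distinct annotation
(presence/absence, not instance counting). The dark set defaults to
strictly D = 1 proteins versus all others; a threshold-based definition is
available because the complement is a genuine modelling choice.

The two-sided Fisher exact p is computed by summing the conditional
hypergeometric weights C(r1, a′)·C(r2, c1−a′) over the support, keeping
tables whose weight does not exceed the observed one. The summation runs in
**exact integer arithmetic** (only the final ratio is a float): probability
ties between tables are then decided exactly rather than through
floating-point comparisons, and a single evaluation costs microseconds,
which is what makes the exhaustive small-table oracle comparison in the
test suite affordable. The unit suite cross-checks the values against
scipy's independent implementation on sampled tables.

The reported "ratio" is the sample odds ratio ad/bc, +inf when only the
denominator is zero and 1 when both are; direction is over-representation
iff the odds ratio exceeds 1. Benjamini–Hochberg adjustment is the standard
step-up (adjusted_(i) = min over j ≥ i of p_(j)·n/j, capped at 1),
delegated to statsmodels; DE-family and FT-family annotations are corrected
separately because they are reported as separate analyses. The default
acceptance threshold is α = 0.01 on the adjusted p. Subcategories that
identify groups of near-identical proteins rather than general properties
(SIMILARITY by default) are excluded before testing.

Treemap export writes area = −log₁₀(adjusted p). An adjusted p of exactly 0
(underflow) maps to a configured area cap, default 320 — approximately the
−log₁₀ of the smallest positive double — keeping areas finite; leaves below
a per-figure readability cutoff are dropped.

## Autonomy

m(N) counts partners with combined score **strictly greater** than N, which
makes "m(900) ≠ 0 ⇒ some score > 900 ⇒ autonomy 0" internally consistent.
On the integer grid the smallest N with m(N) = 0 equals the protein's
maximum incident score s, so the score is (1000 − s)/1000, computed in that
form so the boundary value 0.1 at s = 900 is exact. The attainable range is
therefore {0} ∪ [0.1, 1]. Intermediate values are convention-dependent
(strict vs non-strict comparison would shift them by 1/1000); the endpoints
are not. Duplicate link rows collapse to one undirected pair keeping the
maximum score; self-links are rejected. Degree distributions are reported
at the high-confidence cutoff (> 700) by default, with the low/medium tiers
(400, 700) exposed.

## Dark gene clusters

The scan list holds **all** proteins of a chromosome, labelled dark or
non-dark — a longest dark run is only meaningful against interleaved
non-dark genes. Duplicate occurrences of a protein on one chromosome keep
the earliest position; position ties break lexicographically by accession
(a deterministic rule of this implementation). The permutation p is the
plain count/n fraction of label shuffles attaining the observed run or
longer (n = 1,000 by default, so the resolution floor is 1/1000); a
(count+1)/(n+1) variant is available by flag. Each chromosome's shuffle
stream derives from the run seed and a stable hash of the chromosome name,
so results do not depend on chromosome iteration order. Because the run
statistic is integer-valued, P(p ≤ α) sits at or below α: the test is
conservative at small nominal levels, which the calibration test asserts as
an upper bound rather than a two-sided band.

Member summaries report protein length, binding partners **within the same
cluster**, and the largest single-amino-acid composition as a percentage;
missing sequences leave the bias absent rather than guessed.

## Dark tissues

Unmeasured (tissue, protein) intensities are distinguishable from literal
zeros until zero-fill, which replaces them with 0; a protein is expressed
when its value is strictly positive (an optional intensity threshold
exists, default 0 — no "highly expressed" cut is applied). The tissue ratio
is residue-level: summed dark residues of expressed proteins over their
summed lengths. Presence weighting is the default; intensity weighting
multiplies both sums by the normalized intensity and is labelled in the
output. Ranking is descending with ties broken by tissue name.

## Synthetic data

The generator emulates the five input kinds with planted parameters:

- **Lengths** log-normal (ln-scale mean 5.7, sd 0.45; median ≈ 300
  residues, Swiss-Prot-like; floor 30).
- **Classes** multinomial with default fractions (dark 0.15, grey 0.55,
  white 0.30), a eukaryote-like mix whose realized residue-level total
  darkness lands near the 40–50% range reported for higher eukaryotes;
  grey proteins draw a dark fraction uniformly from (0.1, 0.9).
- **Coverage** constructed so realized D equals the planted class exactly:
  no intervals for dark, a full-length interval for white, and a covered
  block of exactly L − d residues for grey (sometimes split across
  criteria A and B to exercise the union).
- **Annotations** planted per class by solving the 2×2 odds identity: given
  non-dark prevalence p0 and odds ratio OR, dark proteins carry the
  annotation with probability OR·odds0/(1 + OR·odds0), making OR the exact
  population parameter the enrichment stage estimates. Infeasible
  parameters fail before anything is drawn.
- **Links** per-protein Poisson degree draws (defaults: dark mean 1,
  non-dark mean 10) with partners uniform and scores uniform on
  [150, 999]. Because a drawn edge also raises its partner's degree, the
  realized class degrees sit above the planted means by a common offset;
  the planted *gap ordering* is preserved, which is what the recovery
  tests assert.
- **Genome** deals proteins into chromosomes (default 2 × 200 genes) with
  sorted random positions; planted dark runs are realized by swapping dark
  proteins into a contiguous window, erroring when the universe has too
  few dark proteins.
- **Expression** selects each tissue's expressed set greedily from
  darkness-sorted pools to approach the planted dark-residue ratio, draws
  log-scale intensities ~ N(5, 1.5) floored at 0.1, and knocks entries out
  to MISSING with the dropout probability (default 0.1).

A single master seed spawns per-component substreams (universe, sequences,
coverage, annotations, links, genome, expression), so identical spec + seed
gives byte-identical bundles and regenerating one table cannot perturb the
others. The manifest records every planted value, the seed, and per-protein
class ground truth.

What the generator does **not** emulate: real annotation text semantics and
ontology structure, correlated annotations, scale-free network topology,
gene duplication mechanisms, and realistic sequence composition (sequences
are composition-bias toys, off by default). Passing recovery tests
therefore show the estimators are correct for their statistical model, not
that real Swiss-Prot/STRING/ProteomicsDB snapshots would reproduce any
particular published number — those depend on version-locked external data.

## Problem sizes and numerical choices

The test suite runs its simulation studies at deliberate desk scale: 100
universes of 50 proteins for the partition identity, 200 replicates of 500
proteins × 60 annotations for FDR calibration, 200 chromosomes of 400 genes
× 1,000 permutations for type-I control, n = 5,000 for odds-ratio recovery
(within 25% of a planted 8), 500-gene chromosomes for cluster detection,
and 200 expressed proteins for tissue-ratio recovery (within 0.05). These
sizes put all sampling errors comfortably inside the asserted tolerances
while keeping the full suite under a minute of simulation time.

Degenerate inputs are errors, not coercions: empty masks, all-zero
contingency tables, empty universes, out-of-range intervals and scores,
unknown accessions (strict by default, drop-with-warning opt-in), and
p-values outside [0, 1] all raise with context.
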