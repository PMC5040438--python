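# Methods

## Distance model

All statistics rest on pairwise distances between aligned sequences under
**pairwise complete deletion**: for each pair, an alignment column
contributes only if both residues are unambiguous A/C/G/T. Gaps (`-`),
PAUP-style missing data (`?`), `N` and every IUPAC ambiguity code are
excluded from both the numerator and the denominator for that pair. This
keeps the identity p = P + Q exact, where *P* and *Q* are the transition
(A↔G, C↔T) and transversion proportions among comparable sites, and it
records the effective comparison length per pair (`comparable_sites`) so
short-overlap pairs are auditable. An alternative — treating compatible
ambiguity codes (e.g. R vs A) as partial matches — would make p no longer a
simple ratio of site counts; full exclusion is the conservative, common
convention for barcode libraries.

The uncorrected distance is p = d/c (differing over comparable sites,
an exact rational carried as a double). The Kimura two-parameter distance is

    K = −1/2 · ln((1 − 2P − Q) · √(1 − 2Q)).

When 1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0, or when a pair has no comparable site,
the distance is **undefined**: it is stored as NaN, excluded from every
downstream minimum/maximum/median, and counted in the table's diagnostics
(`undefined_count`). Clamping to a large value was rejected because it would
fabricate distances that could masquerade as nearest-neighbor results. When
defined, K ≥ p with equality only at p = 0.

Distances are fractions internally; every report surface multiplies by 100
and labels percent. Rounding (default 2 decimals) happens exclusively at TSV
serialization — ranking, tie detection and sorting always use the full
double-precision values, so changing the output precision can never change
which neighbor is reported.

## The pairwise kernel

Sequences are encoded once as a uint8 matrix (A,C,G,T → 0–3 with purines
even and pyrimidines odd, so a substitution is a transition iff the two
codes share parity; everything else → 4 = missing). For each record *i* the
kernel compares row *i* against all rows *j > i* with vectorized boolean
reductions, giving O(n²·w) work and n(n−1)/2 output pairs in a fixed
(i-major) order. With `threads > 1` the i-range is cut into chunks processed
by a thread pool (numpy releases the GIL in the reductions) and the chunks
are concatenated in deterministic order, so the table is bit-identical for
any thread count. A 3,339 × 653 alignment (≈5.6 million pairs) takes roughly
10 s on one CPU, so no compiled extension is needed at the scales the
package targets.

## Per-species statistics

For each species the package reports:

- **intraspecific spread** — min/max/mean/median over all conspecific pairs;
  NA for singletons (one specimen) and, degenerately, for species whose
  conspecific distances are all undefined under the chosen metric;
- **closest species** — the heterospecific species (genus ignored)
  minimizing the *smallest* cross-species pairwise distance. Min, max and
  median are then reported over *all* cross pairs between the two species,
  not only the minimizing pair of specimens. The minimum — not the mean —
  is the ranking key because the question the statistic answers is "how
  close does identification get to failing";
- **most distant congener** — the same-genus allospecific species maximizing
  the *largest* cross distance, NA when the genus has a single sampled
  species.

Ties are detected by exact equality of the full-precision ranking key and
emit one row per tied neighbor. Exact equality is deliberate: with distances
that are ratios of small integers, true ties are exact in IEEE arithmetic,
and an epsilon would create irreproducible near-ties. When one species has
closest-neighbor ties and congener ties of different multiplicity, the
output table emits max(k₁, k₂) rows and repeats the last value of the
shorter list; the two tie sets are independent, so no pairing of rows is
canonical and this keeps row counts minimal.

The median of an even number of values is the mean of the two central
values. Rows are sorted alphabetically by species (configurable in
principle; the sort is stable so tie rows keep their neighbor order).

## Dataset summaries

The gap summary treats **intraspecific** = all conspecific pairs and
**interspecific** = all heterospecific pairs regardless of genus. Besides
medians, means and ranges it reports the 95th percentile of intraspecific
and the 5th percentile of interspecific distances — the pair of numbers that
brackets a "soft" barcoding gap ignoring the 5% most extreme observations.
Percentiles use linear interpolation between order statistics (the numpy
default), fixed so outputs are reproducible across environments.

Closest-pair aggregates per group: the range is over the per-species
smallest neighbor distances; the parenthetical overall maximum and the
median pool *all* distances between each focal species and its closest
neighbor(s), since a closest pair represented by several individuals also
has larger distances. The farthest-congener median is the median of the
per-species congener maxima. Grouping is by order, family, genus or none;
a group missing a category yields NA fields plus a logged warning rather
than an error.

**Splits** are conspecific pairs at or above a threshold (default 3%),
sorted by distance descending then species then specimen ids; **lumps** are
congeneric allospecific pairs at or below a threshold (default 5%), sorted
ascending. Both thresholds are inclusive, reflecting the closed ranges these
reports conventionally cover.

**Haplotypes** are classes of byte-identical uppercase sequences over the
alignment window. Two sequences differing only at an ambiguity code (N vs A)
are distinct haplotypes — exact equality is auditable, whereas
compatibility-based merging is order-dependent. An opt-in diagnostic counts
haplotype pairs whose differences are confined to non-ACGT symbols
(O(h²·w), informative only). `distinct + nonunique = n` always holds.

**Base composition** pools unambiguous A/C/G/T counts over all sequences;
ambiguities and gaps are excluded from numerator and denominator alike.

## Primer algebra

Degenerate primers are sequences over IUPAC codes plus inosine (I). Each
symbol denotes an option set; degeneracy is the product of option-set sizes.
Inosine is modeled as pairing with any base (factor 4, never a mismatch) —
the standard universal-pairing approximation; its true pairing preferences
(I:C > I:A > I:G/T) are thermodynamic and out of scope, as are Tm/ΔG
calculations generally. Matching counts a position as a match when the
target base is in the primer symbol's option set, so mismatches(primer, t)
= 0 iff t is in the primer's expansion — a tested invariant. Cocktails
(mixtures of primers in one reaction) match with the minimum mismatch count
over members. The packaged primer table ships 12 concrete primers and 2
cocktails; the two 24-nt JJ4a variants are shipped verbatim even though
they are one base shorter than their JJ counterparts.

## The simulator and what passing its tests shows

`make_toy_dataset` plants a three-level hierarchy (genus ancestor → species
consensus → specimen) on one random root sequence, with every substitution
at a globally disjoint site drawn without replacement. Consequently the
differing-site count of any pair is exactly the number of substitutions on
the tree path between them, and each substitution's transition/transversion
identity is recorded, so P and Q are ground truth too. Defaults emulate a
dense temperate COI library: 653 columns, one private substitution per
specimen (conspecific pairs at 2/653 ≈ 0.3%, matching typical intraspecific
medians), 29 substitutions per species branch (sisters ≈ 9% apart, a typical
closest-species median) and 30 per genus branch (allogeneric pairs ≈ 18%,
matching typical interspecific means). Optional per-site noise replaces
bases with N or '-' after the planted structure; the shipped ground-truth
table is then recounted column-by-column by a naive reference routine kept
independent of the vectorized engine.

What this does *not* emulate: back-substitution and homoplasy, rate
variation among sites, codon structure, indel evolution, unbalanced
sampling, or any substitution model — planted distances are exact by
construction. Tests passing on these toys therefore demonstrate that the
*bookkeeping* (site counting, category assignment, ranking, tie handling,
thresholds, grouping) is exact, not that the K2P model fits real COI data.
Because disjointness bounds total planted sites by the alignment width,
large-n simulations use `random_dataset` (i.i.d. uniform sequences, no
ground truth), which suffices for counting and scaling checks.
`make_shared_haplotype_case` constructs the known hard case of two nominal
species sharing an identical sequence; the closest-species minimum must be
exactly 0 and the pair must appear in the lumps report at 0.00%.

## Problem sizes and reproducibility

The test suite and the acceptance script run entirely on generated data:
random toys up to n = 30 for kernel–oracle equivalence (200 toys in the
suite), 100 planted seeds for ground-truth recovery, and single matrices at
n = 198 and n = 3,339 for the pair-count identities — sizes chosen to mirror
a realistic order-level library while keeping a full run in seconds. All
randomness flows through `numpy.random.default_rng` with explicit seeds;
written artifacts echo their seed (TSV comment line, FASTA free-text field).
One CLI run writes its configuration to the log so outputs are
byte-reproducible.

## Known limitations

- Distances are computed on the alignment as given; the package never
  aligns, trims or re-windows sequences.
- No species-delimitation calls (no clustering, no "same species" verdicts):
  the tool reports distances and memberships only.
- Undefined-K2P exclusion means p- and K2P-based reports can summarize
  slightly different pair sets for very divergent or short-overlap pairs;
  the log reports how many pairs were excluded.
- The `min_comparable_sites` guard defaults to 0 (only zero-overlap pairs
  are flagged); libraries with heavily trimmed sequences may want a
  positive value.
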