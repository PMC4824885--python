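# Methods

## Identification by ranked percent identity

Remote barcode-database searches (BLAST/BOLD style) are replaced by an
exhaustive local search: every query is aligned against every
marker-compatible reference record and ranked by percent identity, the
quantity such audits actually report. Reference libraries at audit
scale are tiny (tens to hundreds of records), so exhaustive alignment
is affordable and no heuristic seeding is needed. COI full-length and
mini-barcode sequences are compared against COI references; cytochrome
*b* sequences only against cytochrome *b* references.

### Alignment and the identity statistic

Affine-gap alignment with integer scores: match +1, mismatch −1, gap
open −5, gap extend −2 (a gap of length *g* costs −5 −2(*g*−1)). Two
modes:

- `semi_global` (default): the query aligns end to end while the
  reference's terminal gaps are free, so a ~166 bp mini-barcode nests
  inside a ~655 bp reference without penalty. This is deliberately
  query-global rather than free-ends-on-both-sequences: if both ends
  of both sequences were free, a terminal substitution could be
  "dodged" by dangling the final residues of *both* sequences, which
  would overstate identity (an 8-mer differing in its last base would
  score 100% instead of 7/8).
- `global`: both sequences align end to end with penalized terminal
  gaps; the statistic is symmetric under argument swap.

Percent identity is `100 · matches / columns` where columns run from
the first to the last aligned residue pair — terminal gap columns are
excluded, internal gap columns included (the common barcode-gap
convention). `N` and IUPAC ambiguity codes never count as identical
(they score as mismatches). Because co-optimal alignments can differ
in matches and column count, the statistic is pinned down by a
lexicographic objective — maximize score, then matches, then minimize
columns — so results are reproducible bit for bit. The implementation
is a Gotoh dynamic program (numba kernel) packing the three-component
objective into one 64-bit key; opposite gap types are never adjacent
(always dominated under these scores). Alignments with no aligned pair
are excluded; for non-degenerate sequences the optimum always aligns
at least one pair. The tests check the full (score, matches, columns)
triple against two independent routes — a memoized top-down recursion
and, at tiny lengths, complete enumeration of alignment paths — and
the score component against Biopython's `PairwiseAligner` in global
mode.

### Ranking, tiers, calls

Per species, the best identity over that species' records is kept;
hits below the floor (90.0%, inclusive, so a printed "90%" match
survives) are dropped; ties order lexicographically by scientific
name. The molecular identification used for adjudication is the **top
tier**: all species within `tier_epsilon` of the best identity,
default 0 (exact ties only). Epsilon 0 is the unique simple rule
consistent with the packaged audit's verdicts — a 99.85% runner-up
behind tied 100% hits must stay out of the tier, otherwise a
"bluefin" mislabelling case would be cleared by the excluded
*T. maccoyii* hit, and a "yellowfin"→bigeye case by the 99.69%
*T. albacares* hit.

A **species-level call** (used for reporting beyond the tier, e.g.
separating Atlantic bluefin from the other tunas) requires a unique
top hit leading the runner-up by `margin_delta` (default 0.3
percentage points, chosen to separate the 100-vs-≤99.85 patterns that
justify species claims from genuine ties) plus, when requested,
tree-placement concordance.

### Trees

p-distance (1 − identity/100) matrices feed a standard Saitou–Nei
neighbor-joining implementation. Determinism: Q-matrix ties break at
the smallest (i, j) index pair; negative branch lengths are clamped to
zero with the deficit moved to the sister edge so the pair's summed
length is preserved. The placement check asks whether the query's
nearest leaf by patristic distance belongs to the candidate species
and, when the candidate has ≥2 records, whether the query falls inside
the subtree those records span (assessed after rooting at the first
non-candidate leaf, a convention that makes the unrooted "spanned
subtree" notion concrete). NJ is validated against exhaustive topology
search with least-squares branch fitting on random additive matrices,
and against scikit-bio's implementation.

## Adjudication

`mislabelled ⇔ candidate tier ∩ admissible(label) = ∅`, evaluated with
the label's species claim when one is present, else its base name.
Label normalization is designation-table-driven: a qualifier is a
species claim iff "<qualifier> <base>" or the qualifier alone is a
listed designation ("Yellowfin" → "yellowfin tuna"), otherwise it is a
preparation/habitat tag and ignored ("grilled", "spicy",
"freshwater" — the last treated as habitat because "freshwater eel" is
not a listed designation). Adjudicating against the *tier* rather than
all above-floor hits is required: umbrella terms make whole-genus
ambiguity harmless, while explicit claims are judged against exactly
the tied best evidence.

Policy defaults: names absent from the designation list but present
among the identified species' accepted common names are accepted with
a nomenclature warning (misapplied market nomenclature, e.g. "black
cod" where only "sablefish" is listed); wholly unlisted names default
to not-mislabelled-with-warning, with a strict mode available.
Unidentifiable samples (no hit ≥ floor) get an `unidentifiable`
verdict and are excluded from rate numerators and denominators. Oral
claims never alter verdicts.

Multi-species tiers are *reported* under a market-convention name (a
tied Thunnus tier containing *T. albacares* reports "Yellowfin tuna";
one containing *T. alalunga* but not *T. albacares* reports
"Albacore"); this affects report text only, never the boolean verdict.

## Reporting

Categories key on the normalized base name, so "Tuna (Albacore)" and
"Tuna (Spicy)" aggregate under `tuna`. Rates are percentages rounded
half-up to one decimal (so 12/115 prints 10.4). Category and city
marginals are asserted to sum to the overall totals on every run. The
markdown rendering shows city totals but not the city×category
crosstab, which the report object does not retain. Conservation
tallies count samples by the Red List status of the reporting species.

## Packaged audit table

The package bundles a transcription of a published 115-sample UK sushi
audit (six cities, 31 venues): per sample the menu label, marker,
ranked matches with identities, reported common name, Red List status
and verdict. It is checksummed at load. Two printed quirks are kept as
printed and documented: one row pairs a 100% *T. albacares* match with
the name "Bigeye tuna" (the computed reporting name differs for that
row only; the verdict is unaffected), and the prose count of eel
samples (21) disagrees with the tables (20 rows) — the tables are
followed. Likewise the prose's 10.2% tuna figure is not reproduced;
the report computes 5/48 = 10.4% from the counts.

## Synthetic generator

Defaults emulate the audited study's conditions: 655 bp barcodes,
115 samples, a 10% true substitution rate, a small (5%) mini-barcode
fraction (166 bp central window, fixed position), and zero query noise
(Sanger consensus reads of fresh tissue are essentially error-free;
noise is a dial for robustness experiments). The library default is
6 genera × 3 species with per-branch divergence 0.15 (between genus
ancestors and the root) and 0.04 (species to genus ancestor), typical
of confamilial genera and congeneric species at COI; interspecies
divergence can be set to 0 to mimic indistinguishable congeners.
Substitutions are independent per site, uniform over the three other
bases, on a star phylogeny within and between genera — the simplest
model that exercises the pipeline; there is no indel, codon or
rate-heterogeneity structure, no chimeras, and no primer bias, so
passing recovery tests demonstrates correctness of the audit logic,
not robustness to those real-data complications. For two sequences
derived from a common ancestor at per-branch rate *d*, expected
identity is 1 − [2d(1−d) + (2/3)d²], the closed form the calibration
test checks against.

Wrong labels are drawn uniformly from designations whose admissible
set excludes the true species (and correct labels uniformly from
compatible ones), making recovery arithmetic exact; `label_style`
restricts the pool to umbrella or species-level entries. The
parameter-recovery experiment at study scale (20 seeds × 500 samples,
zero noise, 5 genera × 3 species) checks that the mean recovered rate
sits within 3 Monte-Carlo standard errors of the truth and that
identification accuracy is exactly 1 in the divergent-species regime;
these sizes keep the full suite to a few minutes on one core while
leaving the binomial standard error (~0.3 percentage points) well
below the effects of interest.

## Known limitations

- Identity is defined through one fixed scoring scheme; other schemes
  (or other databases' column conventions) will give slightly
  different percentages near ties.
- The designation table ships only the entries the packaged audit
  needs; real audits must supply the full official list.
- IUCN statuses are a static snapshot, not a live query.
- The NJ placement check is a heuristic corroboration, not a
  likelihood-based placement.
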