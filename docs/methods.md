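# Methods

This note documents the models, numerical choices and limitations behind
the package, and what its simulation-based tests do and do not show.

## Circular pairwise alignment

Tandem monomers are circular, so two consensus sequences are compared
over every rotation of one of them and over both strands.  Each
candidate rotation is scored with a global affine-gap (Gotoh) alignment:
match +1, mismatch −1, gap open −8, gap extension −1.  The dynamic
program packs `(score, matches, diagonal steps)` into a single 64-bit
integer (radix 4096 per slot), so one vectorised pass per rotation
yields the lexicographically optimal triple; the winner's full matrix is
then recomputed once for the traceback that classifies substitution
columns into transitions (A↔G, C↔T) and transversions.  Percent
identity uses all aligned columns, gaps included.  Non-ACGT symbols
score as mismatches, are excluded from the transition/transversion
tallies, and are reported in a separate `ambiguous_columns` field so the
column bookkeeping (`matches + transitions + transversions + gaps +
ambiguous = columns`) stays exact.

Two choices here are load-bearing and were fixed by direct measurement
on simulated data:

* **Affine, not linear, gap costs.**  With any per-column gap cost, a
  pair of unequal length owes `|len(a) − len(b)|` gap columns no matter
  where they go, so the optimiser scatters them to skip mismatches —
  effectively subsequence matching.  Measured on random 149 bp vs 187 bp
  pairs this lifts identity to ~51%, which is *above* the 50%
  conservation screen used throughout satellitome work.  A stiff opening
  cost coalesces gaps into few blocks — the way monomer length
  differences actually arise — and drops the random floor to ~40–46%.
  It also reproduces the characteristic one-block geometry of published
  conserved pairs of unequal length (a 51 bp / 34 bp pair at exactly
  34/51 = 66.7% similarity).
* **Rotation/strand selection by score, not identity.**  At high
  divergence the maximum-identity rotation is a noise artefact: in
  simulations at ~1.5 substitutions/site the true rotation was never
  chosen by identity (0/15) but usually by score (12/15), because
  identity rewards whatever alignment manufactures the most matches.
  Ties are broken by more matches, then fewer columns, then forward
  strand, then the smaller rotation offset, making results fully
  deterministic.

Rotations are enumerated exhaustively for monomers up to 64 bp.  For
longer monomers an edit-distance screen (edlib, global mode, every
rotation) shortlists up to 16 rotations per strand within a margin of
the minimum before full scoring; the screen is a heuristic accelerator —
the score optimum in practice sits at or adjacent to the edit-distance
optimum — and the exhaustive path is the one verified against the
brute-force oracle.

`similarity(a, b)` is made exactly symmetric by aligning the two
sequences in a canonical order (shorter first, then lexicographic).

## Distance estimators

From the winning alignment, gap and ambiguous columns are excluded and
`P` (transitions) and `Q` (transversions) are fractions of the remaining
columns.  The Kimura 2-parameter distance is
`K = −½ ln[(1 − 2P − Q) √(1 − 2Q)]`; when either logarithm argument is
non-positive the estimator has saturated and the Jukes–Cantor
correction `d = −¾ ln(1 − 4p/3)` on the p-distance is used instead; if
that saturates too (`p ≥ 0.75`) the pair is `undefined` and excluded
from all means (reported separately).  Saturation returns NaN rather
than raising, so vectorised consumers can filter.

## Consensus turnover rate

`CTR = K / (2T)` with `T` in years, reported per year and per Myr.
Under the library hypothesis two lineages drift independently after
splitting, so the expected distance between orthologous consensus
monomers is `2 r T` for per-lineage rate `r`, and CTR estimates `r`.
Divergence times are configuration inputs (the shipped reference data
uses 40 Myr for *M. tiete* against both Colossomatinae species and
34.9 Myr within Colossomatinae).

A caveat the parameter-recovery tests quantify: at `r T ≈ 0.74`
substitutions/site/lineage the expected ortholog divergence is K ≈ 1.48
(site identity ~39%), which is *below* the 50% conservation screen.
Similarity-screened detection therefore cannot recover such pairs — in
real studies the 50% figure comes from local homology detection while
distances come from curated alignments of known orthologs.  The package
mirrors that split: `find_conserved` applies the global-similarity
screen (tested at moderate drift, where it is exact), while
parameter-recovery analyses pair families by planted ancestry
(`pairs_from_scenario`).  Even on true orthologs, alignment at this
divergence loses a little signal; measured CTR recovery across seeds is
−6% to −14%, well inside the ±25% band the tests assert.

## Synthetic data generator

The generator emulates exactly what the downstream statistics consume.

* **Substitution process**: per-site Poisson event counts with K2P rate
  structure; each event is a transition with probability
  `κ/(κ+1)` (default ts/tv ratio κ = 2, a standard vertebrate value),
  otherwise one of the two transversions.  Expected events per site is
  `rate × time`; multiple hits and back-substitutions arise naturally,
  which is why the K2P estimator (not the raw p-distance) recovers
  `rate × time` in the tests.
* **Library model**: one contiguous head-to-tail array per family,
  sized to the target genomic fraction (whole copies); each copy is an
  independently evolved monomer at the family's per-copy divergence;
  background is i.i.d. sequence at A+T = 0.56 (the mean catalog
  context; configurable).  Fragments of fixed insert (default 300 bp)
  are sampled uniformly; mates are the fragment ends (2 × 150 bp);
  base-call errors are uniform substitutions (default 0.2%); quality
  strings are constant.  Each mate is tagged with the family covering at
  least half of it, giving the ground-truth manifest.
* **Indels** default to 0: the distance arithmetic is substitution-only;
  enabling them exercises alignment robustness, nothing else.
* **Scenarios**: 2–3 species on an ultrametric tree derived from the
  pairwise divergence times (for three species the two deeper times must
  agree); shared families descend from one ancestral monomer per label,
  with the ingroup pair sharing the stem from the root to their own
  split; subset sharing (a family carried by only two of three species)
  is supported.  Private families are fresh random monomers, drawn at
  100–220 bp: the circular-similarity noise floor rises as monomers get
  shorter, and random monomers under ~80 bp can graze the 50% screen by
  chance, so privates are planted in the mid-range of reported repeat
  unit lengths.
* **Problem sizes**: the shipped defaults and test fixtures sample
  15 Mb genomes at ~0.6× coverage for discovery (≈30 000 read pairs) and
  2 Mb at 1.5× for quantification — large enough that per-k-mer
  satellite multiplicities exceed background by an order of magnitude
  and binomial sampling error sits well inside the asserted tolerances,
  small enough for a laptop-scale run.  A `full` scale profile raises
  the discovery subsample to 2 × 500 000 pairs and quantification to
  2 × 5 000 000.

What the generator does **not** emulate: position- or motif-dependent
sequencer error, quality-score structure, higher-order repeat structure,
multiple arrays per family, transposable elements, CpG effects, or
rate variation among sites.  Passing tests therefore demonstrate the
pipeline's correctness under the stated model, not performance on a
real library.

## Discovery

K-mers (default k = 21) of the reads *and* their reverse complements are
counted (integer-coded, vectorised).  The k-mer graph restricted to
k-mers with count ≥ 2 is walked greedily: walks start from k-mers with
count ≥ 8 in descending-count order, always stepping to the
heaviest admitted successor; a walk that re-enters its own path has
closed a cycle, which is spelled into a circular consensus.  Cycle
k-mers (both strands) are consumed so each family is reported once;
failed-walk k-mers are only barred from seeding new walks.  The
separation argument is coverage-based: in a sub-1× sample (mirroring
production practice, where a fixed subsample of a much larger genome is
used), background k-mer multiplicity is ~2 × coverage while a family at
abundance `a` with per-copy intact-k-mer fraction `q ≈ (1 − d)^k`
contributes `mass × a × q / (2L)` per consensus k-mer — an order of
magnitude higher at the abundances of interest.  The walk-start
threshold (not a global mass fraction) is what separates repeat from
background; a relative floor scaled to total k-mer mass would reject
every low-abundance family at any realistic scale.

Each cycle consensus is normalised to the lexicographically minimal
rotation over both strands, then refined by one round of read
realignment (edlib, tandem-extended consensus, both strands) and
per-column majority vote of up to 200 supporting reads.  Candidates need
≥ 50 supporting reads and a k-mer-mass abundance estimate ≥ 2 × 10⁻⁴
(the estimate is `a × q`, a deliberate underestimate of `a`).  A walk
can legitimately close a cycle spanning several monomer copies (a
multimer ring threading copy variants); deduplication therefore
compares candidates against a tandem extension of the shorter unit and
keeps the shorter monomer.  Very long monomers (approaching the read
length and beyond) are recoverable only as k-mer-graph cycles longer
than the read; beyond ~1 kb fragmentation is possible and such
candidates should be inspected.

The iterative loop (subsample → detect → subtract) removes a read pair
when either mate matches any accepted family at ≥ 80% identity over
≥ 50% of the read (tested on the whole read and its two halves, via
bounded edit distance against the tandem-extended consensus), and stops
when a round contributes nothing new (or at the round cap, default 8).
Termination is guaranteed: the library only shrinks.

## Quantification

Each analyzed read (both mates count toward the denominator) is aligned
to every family's tandem-extended consensus, both strands, with a
bounded edit-distance screen; a hit needs ≥ 70% identity, and reads that
miss whole are retried as halves (≥ 30 nt) to catch array-edge reads.
The hit segment located by the screen is then re-aligned with the
affine aligner to classify substitutions — the unit-cost edit path
systematically trades mismatch runs for gap pairs and was measured to
deflate a planted 12% divergence to 10.7%.  Reads hitting several
families are assigned to the best hit only (identity, then catalog
order), so the abundance sum over families is bounded by 1 by
construction, and the per-family landscape (1% bins, 0–50%) accumulates
exactly the assigned mass, making `Σ landscape = abundance` an identity
rather than an approximation.  Known bias: reads straddling an array
boundary match as halves or not at all, underestimating abundance by
roughly `read_length / array_length` — a few percent at the tested
array sizes, inside the ±15% recovery band.

## Catalog curation

Pairwise similarity over all candidates; single-linkage transitive
closure at each tier (order-independent): >95% merges same-variant
candidates (keeping the higher-abundance consensus), >80% links variants
of one family, >50% links superfamilies.  Thresholds are strict
inequalities.  Names are `<Prefix>Sat<NN>-<len>`, indices assigned in
decreasing abundance (ties: shorter monomer, then lexicographic
consensus), and renaming is idempotent.  Catalog summaries report exact
fractions (median = midpoint of central order statistics; short = <100
bp) and compute A+T from consensus sequences when available.  Screening
against a user-supplied contaminant FASTA (multigene families,
transposable elements) can be done by running `find_conserved` against
that set before tiering; no contaminant database is bundled.

## Comparative analysis

`find_conserved` performs the all-vs-all screen at ≥ 50% similarity and
resolves matches one-to-one greedily by descending similarity
(`allow_many_to_one` retains all matches; displaced candidates are
logged as conflicts).  `fill_distances` validates that every species
combination has a configured time *before* any alignment runs.
Species-pair summaries report mean ± sample sd (ddof = 1) of the
distance actually in use per pair (K2P, or JC under saturation) and of
CTR per Myr; saturated-undefined pairs are excluded and counted.  The
three-way table lists each focal-species family with its match in the
other two catalogs and the shared-with-both / shared-with-exactly-one
counts.

## ANOVA

Classic fixed-effects one-way ANOVA, computed from the sufficient
statistics (per-group n, mean, sd) — the published per-species-pair
summaries are exactly such statistics, which is how the package
re-derives the published F from printed group summaries; the raw-value
route is cross-checked against `scipy.stats.f_oneway` in the tests.
P-values come from the F distribution; no multiple-testing correction.
Note that reconstructing F from group sds printed to two decimals
carries ~2% uncertainty.

## Reference data

`satellitome.refdata` ships the published *M. tiete* satellitome table
(32 families: name, repeat unit length, A+T%, abundance, divergence),
the conserved-family triplets across the three Serrasalmidae species,
the per-species-pair K2P summary statistics, divergence times, and the
two extreme per-family distances.  These are inputs for re-deriving
published statistics, not outputs of this package.  The 30 orthologous
comparisons decompose as 10 (Mti–Cma), 11 (Mti–Pme) and 9 (Cma–Pme)
from the triplet structure.

## Known limitations

* Distances above K ≈ 1.5 are at the edge of what any alignment-based
  estimator supports; values there are lower bounds more than
  estimates, and pairs saturating both estimators are dropped from
  means.
* The discovery walk assumes a dominant consensus path; families whose
  copies are more diverged than ~15% per copy fragment the k-mer cycle
  and fall below the intact-k-mer floor at desk scale.
* The 50% conservation screen is close to the circular-alignment noise
  floor for monomers under ~80 bp; borderline matches of short monomers
  deserve manual inspection.
* The rotation screen for monomers over 64 bp is heuristic (see above);
  tie-breaks among co-optimal alignments pin down the
  transition/transversion split by a fixed traceback preference, which
  is deterministic but not unique.
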