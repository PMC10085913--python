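# Methods

This note documents the models and procedures `mircnv` implements,
the parameters that matter, what the synthetic data do and do not
emulate, and the design choices made where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and formats

All intervals are stored 0-based half-open in memory. GFF3 is read
and written 1-based inclusive, BED 0-based half-open; the conversion
is covered by round-trip tests. Overlap always means "share at least
one base pair" and is strand-agnostic throughout: short-read depth,
MLPA ligation and TE insertion are all strand-blind with respect to
the annotation, and no operation in the pipeline conditions on
strand.

## Conservation classification

A family-by-taxa table drives the classification: a family with
members outside Brassicaceae is `conserved`; one restricted to
Brassicaceae but present beyond *A. thaliana*, or forming a
multi-member named family within it, is `nonconserved_family`; a
single-member family unique to *A. thaliana* is a `singleton`. The
table is an input, not derived from sequence — re-deriving
phylogenetic breadth from cross-species catalogues is out of scope.
A family that is Brassicaceae-wide yet has a single *A. thaliana*
member is classified `nonconserved_family`; the table's two boolean
flags make that case explicit rather than leaving it to inference.

## Genomic context

Gene overlap is three-valued: `intergenic` (no gene span shares a
base), `coding` (any CDS sub-interval shares a base, of any
overlapping gene — coding takes precedence), else `noncoding`
(intronic/UTR placement). CNV overlap is recorded both as ≥1 bp
overlap and as full containment, since "contained in a variable
region" and "touching a variable region" support different readings
of locus variability. Pseudogene tracks, when provided, are treated
like a TE-style overlap flag; no pseudogene-specific rule exists.

TE-superfamily enrichment is the fraction of a superfamily among
locus-overlapping TEs divided by its fraction among all annotated
TEs. TEs overlapping several loci count once in the numerator set. A
superfamily absent genome-wide yields a missing ratio, never zero or
infinity. The ratio is invariant to duplicating the genome-wide
list, which the property suite checks.

## Uniqueness mask

Positions covered by any k-mer (default k = 40, step 1) occurring at
least twice genome-wide are masked, as are positions under windows
containing N. Counting is canonical: a window and its reverse
complement are one k-mer, and a palindromic window counts once per
position — read alignment cannot distinguish strands, so a repeat on
the opposite strand destroys uniqueness just as effectively. The
implementation marks bad-window footprints with a difference array;
tests compare it against a naive per-position oracle for
k ∈ {3, 10, 40} on random genomes, exactly.

## Genotyping regions and the copy-number estimator

Grouping uses *unextended* stem-loop coordinates: regions are the
connected components of the pairwise ≥1 bp overlap graph, computed by
a per-chromosome sweep (interval components are contiguous). The
component's union span is then extended by `flank` (default 300 bp,
clipped to chromosome ends) to stabilize short-read depth over short
hairpin loci. Extending before grouping would merge every pair of
loci within 600 bp and is deliberately not done.

The estimator is a normalized mean-depth ratio,
`CN = 2 · mean(depth over unmasked region positions) / D_a`, with
`D_a` the accession's genome-wide mean depth over unmasked positions
(a per-chromosome variant is a config flag). This is an intentional,
documented simplification: the population-scale read-depth machinery
used on real cohorts contributes precision, not a different
downstream contract, and everything after estimation consumes only
unrounded CN values. No GC-bias correction, paired-end or breakpoint
logic is included (future work).

A region with fewer than `min_callable_bp` (default 100) unmasked
positions is reported `failed` with no estimates — masking-induced
loss of callable sequence is the modeled failure mechanism, and the
default synthetic study plants one such region by duplicating its
extended span elsewhere in the genome.

Population filters, applied in order with the first failure
recorded, remove regions whose distributions cannot be trusted:
(i) reference-accession CN outside [1.0, 3.0] — the reference must
look two-copy at its own locus; (ii) population mean CN outside
[1.0, 3.0] — a paralog-absorbed or collapsed locus shifts everyone;
(iii) interquartile range above 1.0 — multimodal or noisy loci.
Quartiles use linear interpolation between order statistics (the
ubiquitous "type 7" rule; no other convention is documented for this
filter, and the choice is recorded in the config). Filtering keeps
the estimates and is idempotent. Tallies are reported at both region
and locus level, since a grouped pair makes those counts differ.

Calls threshold the unrounded estimates: loss below 0.3, gain at or
above 4.0. The asymmetry is deliberate and conservative: natural
inbred accessions are effectively homozygous, so a true full
deletion sits near 0 and a true duplication at 4 or above, while
mapping noise concentrates between 1 and 3. A locus is `variable`
iff any accession carries a non-normal call; members of a grouped
region inherit the region's classification, and loci in failed or
filtered regions are `not_genotyped`.

## MLPA

Raw probe intensities are divided by the per-sample mean of the
three control probes. By default each probe column is then divided
by its across-sample median: the 0.5 / 2.0 calling thresholds
presuppose that the two-copy state sits at ratio 1.0, which control
normalization alone does not guarantee when probes differ in
amplification efficiency; a flag restores the strictly literal
single-step normalization. Ratios below 0.5 call deletions, above
2.0 duplications. A raw signal below 2% of the sample's mean control
signal is `no_signal`: a fully deleted or diverged probe site
produces no ligation product, which is qualitatively different from
a quantitative loss (the tunable floor separates the two). Samples
whose control mean is zero are flagged invalid and excluded.
Concordance with read-depth calls maps loss↔deletion,
normal↔normal, gain↔duplication and computes the agreement rate
over sample×probe pairs with signal.

## Homology census

The census answers "how many near-copies of this precursor does an
assembly contain" at 100% query coverage and an identity floor
(default 0.97), without an external aligner. Exact seeds of length
12 locate candidates: a hit at ≥97% identity over a ~180 bp query
contains at most 5–6 errors, which by pigeonhole leaves an exact
stretch of ≥ ⌈180/7⌉ > 12 bases, so the seed stage cannot miss a
qualifying hit. Candidate windows are scored by gapped infix
alignment (edlib), identity = matching columns / alignment columns
(the blastn convention), and hits whose spans overlap by more than
half are deduplicated keeping the higher identity, mirroring
one-HSP-per-locus behaviour for tandem near-identical repeats. Both
strands are scanned and reported; no E-value statistics are
computed, since the filter is purely identity/coverage. The test
suite checks the scan against a full dynamic-programming oracle
(pure-Python on small genomes, an exhaustive vectorized edit-DP at
200 kb), and monotonicity: raising the identity floor never adds
hits.

## Dosage–expression screen

For each variable locus, Pearson r between its unrounded copy
numbers and each candidate gene's normalized expression over
pairwise-complete shared accessions (minimum 30; fewer accessions or
a zero-variance vector yields a skipped pair with a recorded
reason). Flagging is inclusive, |r| ≥ 0.3: a correlation of exactly
−0.30 passes. By default candidates are same-chromosome genes
within 1 Mb plus externally predicted target pairs, with an
`all_pairs` mode for the exhaustive scan; the windowed default
exists because proximity inside one CNV produces correlations that
are structural, not regulatory, and the per-pair `shared_cnv` and
`proximity_bp` diagnostics make that first-class output. No
significance procedure is attached to the shared-CNV diagnostic.
Mature-miRNA abundance summaries (median/quartiles of RPM,
detectable counts at a threshold, default strictly above 0) are
reported per organ × conservation class.

## Synthetic data: what is and is not emulated

The generator reproduces the *statistical structure* of the real
inputs, not their content:

- **Genome**: i.i.d. uniform A/C/G/T with planted duplicated blocks
  (and, for census runs, planted diverged query copies). Real
  genomes have compositional bias, tandem repeat families and
  centromeric structure; the mask and census are therefore tested on
  worst-case planted repeats, not realistic repeat landscapes.
- **Catalogue**: default 60 loci of 90–250 bp, 20 per conservation
  class, exactly seven overlapping precursor pairs (drawn from
  nonconserved families, as paired family members are in practice),
  others spaced ≥900 bp so extended regions never collide.
- **Population**: 200 inbred accessions in five genetic groups;
  integer CN per region drawn from class-specific distributions —
  conserved {2: 0.998, 4: 0.001, 6: 0.001}; nonconserved-family
  {0: 0.03, 2: 0.96, 4: 0.004, 6: 0.006}; singleton {0: 0.03,
  2: 0.956, 4: 0.004, 6: 0.01} — with the loss probability of young
  loci scaled per group (weights 0.2–1.7). At this scale the
  reference-proximal group carries any nonconserved loss at a rate
  near 20% and the most distant group near 80%, and roughly 96% of
  accessions carry no conserved-locus change, matching the observed
  reference-bias gradient and the rare/private character of
  conserved-locus changes. The reference accession is forced to
  CN 2 everywhere.
- **Depth**: per-base Poisson at rate λ·CN/2 (λ = 20 diploid mean),
  CN taken from the planted region state inside extended spans and 2
  elsewhere. Poisson keeps the estimator's behaviour analytically
  checkable; a negative-binomial switch exists for robustness
  testing. No read-level simulation, GC bias, mapping error or
  batch structure — recovery rates on synthetic cohorts are
  therefore an upper bound on real-data performance, and passing
  tests certify the pipeline's logic, not the estimator's field
  accuracy.
- **MLPA**: raw = scale · (CN/2) · LogNormal(0, σ), σ = 0.1, three
  control probes behaving as fixed two-copy loci, 48 samples chosen
  carrier-first.
- **Expression**: planted pairs built by the standard bivariate
  construction `base + spread·(r·z_CN + √(1−r²)·ε)`, which attains
  the target population correlation with the planted CN vector;
  independent genes i.i.d. normal. Defaults base = 100, spread = 10
  keep values ≥0 without distorting r (clipping sits 10σ away).

Every generator consumes `(seed, fixed integer tag)` through
NumPy's `SeedSequence`, and per-accession depth additionally keys on
the accession's column index, so studies are byte-identical per seed
regardless of evaluation order.

## Numerical and edge-case choices

- Planted CN = 4 sits exactly on the gain threshold: its estimate
  (mean 4.0, SD ≈ 0.03 at the default region size and coverage)
  falls on either side with near-equal probability. The defaults
  keep that state rare (≤0.4% of cells) and the recovery criterion
  accounts for it; tests of exact recovery condition on planted
  states away from thresholds.
- Zero unmasked positions or a sub-threshold callable span is a
  `failed` status, never an exception; a zero accession mean depth
  is an error (the input cannot be normalized).
- Interval adjacency is not overlap: `[a, b)` and `[b, c)` do not
  group.
- MLPA probe columns dead in every sample cannot be median-rescaled
  and are reported `no_signal` throughout.
- Census coverage below 1.0 is accepted but the aligner consumes the
  full query, so reported coverage is always 1.0; identity ties in
  deduplication resolve to the earlier genomic span.

## Problem sizes

Default scales — 500 kb genome (200 kb for the genotyping-focused
cohort preset), 60 loci, 200 accessions at λ = 20, 600-accession
expression screens, 200 kb census assemblies with 16 planted copies
— were chosen so a full study, the analysis drivers and the entire
test suite run in minutes on a single core while keeping every
statistical check (binomial CIs, Fisher-z bands, Poisson recovery)
well-powered at its stated tolerance.

## Known limitations

- The CN estimator ignores GC bias, mappability gradients and
  insert-size information; it is a mean-depth ratio, full stop.
- Conservation classification trusts the input taxa table.
- The census has no E-value model and assumes query length ≥ the
  seed length with a sensible identity floor; extreme floors below
  ~0.9 on ~180 bp queries weaken the pigeonhole guarantee.
- The expression screen reports correlation, not causation; the
  shared-CNV diagnostic flags structural confounding but does not
  test it.
- The exact variable/nonvariable split of the real catalogue is not
  reproducible without the real cohort data and is not attempted.
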