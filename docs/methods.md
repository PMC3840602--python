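# Methods

## Repeat records and scoring

An STR record mirrors the UCSC simpleRepeats schema. Two constants fix
the reporting arithmetic: a per-base match weight of 2 and a minimum
alignment score of 50, which imply a minimum reportable tract of
ceil(50/2) = 25 bp. Mismatch and indel penalties are not pinned by the
source table; we default both to 7 (Tandem Repeat Finder's published
defaults) and expose them in `ScoringParams`. Purity is computed
indel-free: the consensus motif is tiled across the tract at each of its
|motif| phases and the best phase's match fraction is reported to the
nearest integer percent. This makes purity phase-invariant (rotating the
motif never changes it) but means `perIndel ≠ 0` records can only enter
the pipeline through simpleRepeats ingestion, never from the detector.

Rounding conventions: copy number rounds half-up to one decimal
(31 bp / period 6 → 5.2), purity and base percentages are integers
(composition truncates, so the four percentages sum to 97–100), entropy
is stored at full precision and displayed to two decimals. `N` bases
count as mismatches for purity, are excluded from both numerator and
denominator of composition, and break detector seeds.

## Detection

The detector is deliberately substitution-only; it replaces a
precomputed repeats table when only FASTA is available, and an indel-free
model keeps the brute-force oracle in the tests exact. For each period
p = 1..9 it computes the autocorrelation indicator m[i] = (s[i] = s[i−p]),
opens a candidate at every exact match run of at least max(12, 2p) bases,
extends across mismatch runs no longer than p, and trims each end to the
span maximising `2·matches − 7·mismatches`. Each candidate is then scored
against its column-majority consensus; if the consensus is non-primitive
(e.g. a period-4 call of ACAC) the period collapses to the primitive
unit and the span is re-optimised against the primitive-period consensus
before anything else happens — without this step a period-2p candidate
over a pure period-p tract can retain chance flank matches that the
period-p scan correctly trims, and the two calls would disagree about
the span. Records below score 50 or purity 80 (a reporting floor
deliberately below the table's 90% filter, so filtering is observable)
are dropped; overlapping records sharing at least half of the shorter
span are resolved by higher score, then smaller period, then leftmost
start. Both strands are not scanned separately: an STR is
strand-symmetric as an interval and motifs are reported on the forward
strand.

The seed length of max(12, 2p) has one practical consequence: a planted
period-9 tract needs at least 27 bp (three copies) to seed, so the
generator enforces tract length ≥ max(25, 3p).

## Gene models, windows, compartments

Coordinates are 0-based half-open throughout. The TSS is txStart on the
+ strand and txEnd on the − strand; the regulatory window spans
`[TSS−2000, TSS+1000)` in transcript orientation, clamped at chromosome
edges rather than dropped. Models on contigs whose name contains `_`
(haplotype/random/unplaced naming) are excluded. One transcript per
locus is kept, grouping by gene symbol as the locus proxy: an explicit
canonical-id list wins when supplied, otherwise the longest genomic span
with ties broken by smallest transcript id — deterministic and
permutation-invariant. The 5′-UTR is exon-aware (exonic bases strictly
between the TSS and the CDS start in transcript orientation), not the
genomic span TSS→cdsStart. CpG-island overlap of a window is any ≥ 1 bp
half-open intersection.

Two joining rules coexist and are never mixed: table membership requires
both STR ends inside the window (full containment), while compartment
subsets — exon, intron, 5′-UTR and the TxPos windows upstream
`[−2000,−1]`, proximal `[−250,+250]`, core `[−60,+40]`, regulatory
`[−2000,+1000]` (inclusive, matching how such windows are conventionally
written) — use any-overlap.

## Profiles

Every table row adds 1 to each TxPos position it covers, so the count
track sums to the total covered length — a conservation law the tests
check for every subset (period classes, CpG split). Density divides by
the number of regulatory regions (raw counts are also retained, since
either normalisation is defensible). Composition and copy-number
profiles are unweighted means over the STRs covering a position, taken
from the record-level percentage fields rather than the underlying
genomic bases (that is what the table columns contain); uncovered
positions are missing, not zero, to avoid dragging the mean curves
toward zero over empty stretches.

Smoothing is LOWESS (locally weighted linear regression, tricube
weights) via statsmodels, with fraction 0.1 and 3 robustness iterations
by default; both are configurable and recorded in output metadata. Note
that robustness iterations are outlier-resistant by construction: on a
spiky series such as a sparse per-base count track they pull the
smoothed mean a few percent below the raw mean. On continuous noisy
series the smoother preserves the mean to well under 1%, which is what
the test suite asserts.

## Gene sets and enrichment

Four comparison sets mirror the analysis design: (1) genes with at least
one table row; (2) genes with any exonic STR, with *no* purity filter;
(3) the highest-density quartile of intronic-repeat genes, where density
is total intron width (kb) per ≥ 90%-purity intronic STR — smaller is
denser — thresholded at the linearly interpolated 25th percentile with
boundary ties included; (4) ten random samples, matched in size to set
(1), drawn uniformly without replacement from all genes with a
qualifying intronic STR. Over-representation per term uses the
hypergeometric upper tail with fold = (k/n)/(K/N); no minimum-count
filter is applied. FDR is Benjamini–Hochberg, applied per term
collection, and implemented directly (five lines) so the statsmodels
routine remains an independent cross-check in the tests. Terms are
reported from the random samples only when significant in at least 6 of
the 10 analyses. The background defaults to all canonical transcripts
surviving contig exclusion, and the term map is a user-supplied
two-column TSV; identifier translation between annotation universes is
out of scope.

## Synthetic genomes

The generator emulates the statistical structure this analysis targets
while staying deliberately simple. Background sequence is i.i.d. at GC
0.40; genes (100 by default, two 600 kb chromosomes, both strands
equally likely, 10% noncoding) are placed without overlap with 2–5 exons
and a CDS; 66% of TSS windows receive a 300 bp CpG island centred on the
TSS. Planted repeat classes, calibrated per 100 genes: 120 pure AT-rich
repeats of period 1/2/4/5/8 at TxPos −2000..−301; 80 pure GC-rich
trinucleotide-dominated repeats (periods 3/6/9) within ±300 bp of the
TSS of CpG-island genes; 30 AT-rich repeats of purity 85–87 (long
enough, 80–120 bp, to remain detectable at that purity) so the 90%
purity filter has visible effect; and 150 genome-wide repeats with a
broad period mix for spectrum comparisons. Counts scale with gene number
so plant density per window is constant.

Planting writes motif copies, then substitutes distinct positions until
the realised purity is within ±2 points of target, resampling if a
substitution would change the tract's primitive period; targets below 70
raise an error. Plants keep ≥ 50 bp from each other and from splice
sites. Each plant is then *isolated*: the period+1 flanking bases on
each side are forced to mismatch both the autocorrelation and the motif
continuation, and the detector's own span-refinement is run locally so
any residual chance near-tandem run in the background just beyond the
flank is broken. This guarantees the planted span is the score-optimal
span, making exact-span recall a meaningful test. Background chance
repeats are accepted, not suppressed; tests therefore measure precision
at truth positions rather than globally.

What the generator does not emulate: CpG dinucleotide chain structure,
isochores, realistic promoter sequence models, indel-containing repeats,
or repeat length/period correlations seen in real genomes. Passing tests
demonstrate the pipeline's arithmetic and inference are correct under
known truth, not that biological conclusions transfer to any particular
genome assembly.

An auxiliary gene-set-level simulator (`simulate_enriched_study`) draws
a study set of 200 genes from a background of 1000 with one of 40 terms
(100 genes each) up-weighted by a target fold, leaving the other terms
null. It exists to measure detection power of the enrichment statistics
over many replicates cheaply; the test suite requires a fold-3 term to
reach FDR < 0.05 in at least 95 of 100 replicates, and a full-genome run
with a planted term bias is exercised separately.

## Problem sizes and determinism

Default test fixtures use a 1.2 Mb two-chromosome genome with 100 genes
and 380 plants (simulation ≈ 1 s, detection ≈ 0.3 s); the profile
recovery check uses 150 genes on 2 Mb and the spectrum check 500
genome-wide plants — sizes chosen so the full suite completes in well
under a minute while keeping binomial sampling error small relative to
the tested effects. All randomness flows from explicit
`numpy.random.default_rng` seeds; identical configurations produce
byte-identical FASTA, tables and summaries, and every output file
carries a metadata header with package version, a hash of the analysis
parameters (output location excluded) and the seed.

## Known limitations

* The detector's substitution-only model under-reports indel-containing
  repeats; such records are supported only via simpleRepeats ingestion.
* Locus grouping by gene symbol is a proxy; annotation sets whose
  symbols are not locus-unique will over-merge.
* Purity is best-phase tiling, which can score a heavily substituted
  tract slightly above its alignment-based purity; banded-alignment
  purity is out of scope.
* Enrichment fold and p are reported even for very small k; interpret
  single-digit overlaps with care.
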