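# Methods

## Scope and coordinate conventions

`svbench` evaluates structural-variant (SV) callsets restricted to three
event classes — deletions (DEL), tandem duplications (DUP), and inversions
(INV) — each represented as a single reference interval. Insertions,
translocations, and breakends are rejected at parse time with a logged skip:
they have no unambiguous single-interval representation, and every scoring
rule here is interval-based.

All internal coordinates are 0-based half-open `[start, end)`, so
`length = end − start` with no off-by-one cases; conversion to and from the
1-based conventions of VCF and GFF3 happens only at I/O boundaries. For a
symbolic VCF record the event interval is `[POS − 1, END)` with END read as
1-based inclusive: a `<DEL>` at POS=101, END=200 is `[100, 200)`, size
100 bp. When END is absent the interval is reconstructed from |SVLEN|.
Records written by `svbench` carry SVTYPE, END, and SVLEN; SVLEN is declared
as a String-typed INFO field because recent htslib re-derives the record
length (and hence the printed END) from an Integer SVLEN under the VCF 4.4
padding-base convention, which conflicts with the first-affected-base
convention above. The printed value is still a plain signed integer, and the
reader accepts both conventions (SVLEN-derived ends are detected and
corrected when reading third-party files).

## Simulation design

The simulator plants truth sets under a size/type-binned design:

- **Bins.** Sizes span `min_size` (default 100 bp, also the hard floor) to
  `max_size` (default 280 kbp) on log-spaced edges; lower bins are half-open
  and the last bin is closed so every size belongs to exactly one bin. Sizes
  within a bin are drawn log-uniformly, with each bin's lower edge included
  once per type so boundary sizes are always exercised. Exact bin edges are
  a free design choice here: any strictly increasing edge list is accepted,
  and the emergent number of mock genomes is a consequence of the edges,
  counts and budget rather than a target.
- **Counts.** Every (type, bin) cell receives exactly `per_bin_count`
  variants (default 30) summed across the whole set of mock genomes; an
  audit test asserts the counts are exact.
- **Budget.** The base pairs planted in one mock genome may not exceed
  `max_fraction` (default 1%) of the total reference length. Packing is
  first-fit decreasing by size with a seeded shuffle breaking size ties —
  deterministic given the seed and near-minimal in genome count. A single
  variant larger than the budget is an immediate infeasibility error naming
  the offending bin.
- **Placement.** Coordinates are drawn by seeded rejection sampling,
  chromosome chosen proportional to length, uniform start within the
  feasible range; a position is rejected if the variant would leave the
  chromosome, come within `min_gap` (default 500 bp) of an already-placed
  variant, or intersect a run of ≥ 10 Ns. The gap keeps planted events
  scorable as distinct variants; setting `min_gap=0` permits adjacent
  events such as the back-to-back DUP/DEL/INV cluster of the BC4586 strain.
  Larger variants are placed first to reduce rejection; a retry cap (1000)
  turns pathological densities into a clear error rather than a hang.
- **Mutation.** DEL removes `[start, end)`; tandem DUP inserts one extra
  copy immediately after `end` (copy number 2, the simplest event consistent
  with "tandem"); INV substitutes the reverse complement. Variants are
  applied right-to-left per chromosome so stored coordinates remain
  reference coordinates.

## Synthetic caller

`perturb_truth` emulates the four failure modes real callers exhibit, each
with its own parameter: missed events (`fn_rate`, per-variant Bernoulli
drop), novel false events (`fp_rate`, the expected FP fraction of the
output; FP count is `round(survivors · fp_rate / (1 − fp_rate))`), breakpoint
error (`jitter_sd`, independent rounded Gaussian shifts per breakpoint,
clamped to keep size ≥ 1 and stay on the chromosome), and fragmentation
(`split_prob`, a surviving call emitted as two abutting halves partitioning
its span — the case that makes the reciprocal-overlap rule's split-call
penalty observable). False-positive types and sizes are resampled from the
truth set's empirical distribution rather than a parametric law so that
size-stratified metrics remain interpretable, and FP events are placed away
from all truth intervals so the expected precision is exactly
`1 − fp_rate`. Everything is deterministic given the seed.

The generator makes no attempt to imitate any specific caller's error
profile, read-depth dependence, or sequence-context biases; passing recovery
tests therefore demonstrates that the scoring stack measures what it claims
on calls with known error structure, not that any particular caller would
achieve those scores on real reads.

## Scoring rules and numerical choices

- Matching is same-type only and many-to-one: a call is TP iff at least one
  same-type truth variant reaches reciprocal overlap ≥ `min_recip`
  (default 0.5, ties count as TP). No one-to-one assignment is attempted;
  inflation from duplicate calls is instead removed upstream by
  deduplication, which collapses each connected component (transitive
  closure of pairwise ≥ 1 bp overlap) of same-type calls to one survivor by
  the ordered policy QUAL → read support → size → seeded random draw. Each
  criterion only breaks ties left by the previous one; absent evidence
  (missing QUAL/support) sorts last.
- Degenerate metric denominators are defined as 0: precision with
  TP+FP = 0, recall with TP+FN = 0, F1 with precision+recall = 0, and the
  Jaccard of two empty coverage sets — stable aggregation over empty strata
  beats propagating NaNs.
- Jaccard treats each side's intervals as a base-pair *set* (overlapping
  intervals within one callset count once) and is computed per SV type;
  pooled Jaccard across types is not reported because type-specific coverage
  sets are the unit every comparison here uses.
- Size-stratified reports assign both truth variants and calls to strata by
  their own size (half-open ranges, last edge included). A call whose
  jittered size crosses a stratum edge is scored in its own stratum; the
  overall (unstratified) row is always reported alongside and is the
  authoritative total. Report tables round half-up to 2 decimals; internal
  values are unrounded.
- Chromosome-namespace mismatches (calls and truth sharing no sequence
  names at all, e.g. `chrI` vs `I`) raise an error rather than silently
  scoring everything FP.

## Gene-span agreement

Protein-coding genes are read from GFF3 `gene` features by `biotype`
(`gene_biotype`/`gene_type` accepted as synonyms). A prediction's gene set
contains every gene whose span is covered ≥ 50% by that single SV (coverage
is per call, not per merged callset coverage, and strand is ignored); calls
longer than 50 kbp are excluded, and calls with empty gene sets are dropped
from the analysis. Two same-type predictions agree iff their gene sets are
exactly equal — strict set equality, not subset or overlap.

Concordance summaries: UpSet-style *exclusive* intersection counts (each
gene contributes to exactly the combination of callers containing it, so
counts partition the union), per-caller unique-gene percentages
(100 × |genes in no other caller| / |caller's genes|, undefined for empty
sets), and per-strain medians of variant counts and distinct-gene counts.
Medians over an even number of strains use the mean of the two middle values
and are reported unrounded, hence half-integers. Multi-strain agreement
pools strains per caller by default; a per-strain mode is available by
passing single-strain callset maps.

## Reproducibility

Every stochastic stage receives a sub-seed derived from the single run seed
by CRC-32 of `"{seed}:{stage}"` (stable across platforms and below 2³¹).
Identical configurations produce byte-identical truth VCFs and reports; the
pipeline manifest records the tool version, all parameters, derived seeds,
and SHA-256 checksums of the written files.

## Problem sizes used in the test and audit suites

Unit and property tests run on toy references of 10 kbp–2 Mbp, where
per-base boolean-mask oracles can recompute every overlap, Jaccard, and
classification decision by brute force. The design audit uses a 5 × 1 Mbp
synthetic reference with the size range scaled by the same
reference-length ratio as the full-scale design (280 kbp on ~100 Mbp →
14 kbp on 5 Mbp), which exercises the span budget at the same relative
scale. Parameter-recovery checks use 500 truth variants per seed over
10 seeds and compare pooled precision/recall against the generating rates
at three binomial standard errors.

## Known limitations

- No read-level simulation, alignment, or caller execution: the unit of
  input is a callset, not a BAM. Error rates of real callers must be
  emulated, not reproduced.
- No genotypes, multi-sample VCFs, insertions, or translocations.
- Homozygous, single-haplotype mutation only; no zygosity model.
- The reciprocal-overlap rule shares the known failure mode it is meant to
  expose: a truth event split into fragments each below the threshold is
  unrecoverable by any per-call rule (quantified by the split-penalty test).
- UpSet intersection counts are computed and written as TSV; no UpSet figure
  is rendered.
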