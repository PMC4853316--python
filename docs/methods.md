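# Methods

This note records the statistical definitions, the conventions chosen
where the underlying procedures are genuinely ambiguous, what the
synthetic-data generator does and does not emulate, and the package's
known limitations.

## Assembly statistics

**N50.** Lengths are sorted descending; the N50 is the length at which the
running sum first reaches half of the total. It is always one of the
observed lengths. No relation to the median is assumed (N50 can fall below
the median for some length multisets).

**GC%.** Pooled over all sequences and computed over unambiguous bases
only: `100·(G+C)/(A+C+G+T)`. Ambiguity codes and N are excluded from both
numerator and denominator, so the statistic reads "GC among known bases".

**Median.** For an even-sized length set, the midpoint of the two central
values.

**ExN50.** "x% of the data" is interpreted as x% of total **TPM mass** —
the standard construction: transcripts are ranked by TPM descending (ties
broken by length descending, then id ascending, so curves are
bit-reproducible), and the Ex subset is the shortest prefix whose
cumulative TPM reaches `x/100 · ΣTPM`. The ExN50 at x is the N50 of that
subset's lengths; subset size and the subset's minimum TPM are reported
alongside. Consequences worth knowing:

* subset size is nondecreasing and minimum TPM nonincreasing in x;
* at x = 100 the subset is every transcript with positive TPM, so ExN50
  equals the plain N50 whenever no transcript has TPM 0 — zero-TPM
  transcripts never enter any Ex subset;
* a zero total TPM leaves the curve undefined and is an error.

Transcripts missing from the expression table are treated as TPM 0 with a
warning rather than an error, since de novo assemblies routinely contain
contigs the quantifier dropped.

**TPM filtering.** `count_above_tpm` keeps TPM ≥ threshold (inclusive):
eliminating transcripts "below" a floor keeps those exactly at it.

## Full-length assessment

Per query, hits with e-value above the cutoff (default 1e-20, comparison
inclusive) are discarded and the maximal-bitscore survivor kept (ties:
minimal e-value, then first occurrence — the order aligners emit is
meaningful). Coverage is the **subject-coordinate span** divided by the
subject length, not the alignment-length column: that column counts gap
columns and can exceed the subject span, whereas the span measures how
much of the homolog the transcript actually reaches. Coordinates are
1-based inclusive and orientation-insensitive; coverage is clamped to 1.
Multiple HSPs per query–subject pair are *not* merged or tiled — the
single best HSP defines coverage, the simplest defensible convention; HSP
chaining is out of scope. Binning uses half-open `(lower, upper]` percent
bins (exact zeros to the lowest bin) with cumulative counts as the suffix
sum from the 100% bin downward.

Because this needs the subject's full length, the hit reader requires a
13th column (subject length) appended to the 12 standard tabular-alignment
columns (`outfmt '6 std slen'`); 12-column files are rejected with a
message saying how to regenerate them.

## Codon usage

CDS sequences shorter than 300 nt (100 codons) are excluded — implemented
as keep length ≥ 300, the inclusive reading of a "longer than 100 amino
acids (300 bp)" filter whose parenthetical equates the two; the threshold
is a flag. Counting walks each sequence in-frame from position 1 in
non-overlapping triplets, drops a trailing 1–2 nt remainder, and skips
(but tallies) triplets containing non-ACGT characters rather than failing
on ambiguity codes. The genetic code is fixed to the standard nuclear
table; alternative codes are out of scope because every host this pipeline
compares uses the standard code for nuclear CDS.

RSCU follows the classical formula (see README). Conventions:

* stop codons are excluded by default (`include_stop` computes the
  three-codon stop family as well) — codon-usage comparisons are over the
  20 amino acids;
* an amino acid with zero total count yields *missing* RSCU for all its
  codons (the formula is 0/0 there), never 0 or 1, and is excluded from
  range/SD summaries;
* the per-family sum identity (Σ RSCU = n_i for every observed family) is
  a mathematical consequence of the formula and is asserted
  property-style in the test suite;
* the bias SD is the **population** form (divide by n_i), chosen because
  a synonymous family is the entire population of interest, not a sample
  from a larger one; single-codon amino acids have range 0 and SD 0;
* tied extremes resolve to the lexicographically smallest codon.

Cross-sample comparison aligns per-sample RSCU tables into codon × sample
and amino-acid × sample (range, SD) matrices; missing stays missing.
Exact reproduction of published per-species values depends on which CDS
annotation release is used and whether isoforms were deduplicated, so
cross-species numbers should be read as annotation-version-dependent.

## Glycogene profiling

Published glycogene catalogues typically rest on manual curation of blast
hits; this package substitutes explicit, configurable thresholds so the
procedure is reproducible: a reference gene is present iff some hit passes
e-value ≤ 1e-20, identity ≥ 30%, and subject coverage ≥ 0.5 (all
defaults; the max-bitscore passing hit is recorded as support). Loosening
any threshold can only add present genes (a property test asserts this
monotonicity). A gene's expression is the TPM of its **single best**
supporting transcript, not a sum over all matching transcripts — one mark
per gene. Counts produced under these thresholds will not exactly match
manually curated catalogues, and are not meant to.

## Signal-peptide ranking

The predictor's cleavage position is the first mature-protein residue, so
the signal peptide is residues 1..pos−1. Only positive calls are ranked,
by transcript TPM descending (ties: D-score descending, then protein id),
with contiguous ranks from 1. Proteins that do not begin with methionine
get a truncation flag — such predictions usually come from 5'-truncated
transcripts or an upstream in-frame start — and are flagged for review,
never silently removed. When one transcript yields several predicted
proteins with signals, each is ranked independently; identical signal
sequences are not deduplicated. A missing expression record ranks the
protein at TPM 0 with a warning; an unresolvable protein→transcript id
drops the prediction with a warning.

The SignalP reader is fixed to the v4 short format (columns name, Cmax,
pos, Ymax, pos, Smax, pos, Smean, D, Y/N, Dcutoff, networks; the Ymax
position is the cleavage site). Other versions' headers are rejected
outright rather than half-parsed. Negative-call rows retain their scores
but store no cleavage position, since it is meaningless without a call.

## Synthetic data

The generator emulates, with known parameters:

* **CDS**: log-normal lengths (defaults μ=6.8, σ=0.55 on the log scale,
  ≈1 kb mean, floored at 150 nt and rounded to whole codons, matching
  typical de novo assembly length profiles); an ATG start, a body of
  i.i.d. uniform amino acids whose codons are drawn from per-family
  probability vectors sampled once from a symmetric Dirichlet (α = 0.8,
  moderate bias), and a single terminal stop — so the true RSCU of codon
  j is exactly `n_i · p_ij` and no internal stops exist by construction;
* **expression**: log-normal TPMs (μ=1, σ=2 — strongly heavy-tailed, as
  in real RNA-seq) normalized to sum to 1e6, written in the RSEM
  isoforms.results dialect;
* **hits**: per-query subject coverage from Beta(2, 1.2) (skewed toward
  full length), realized as integer 1-based coordinates with
  `span = max(1, round(cov·L))` — exact to ±1/L; ~5% of hits get
  deliberately weak e-values to exercise the cutoff, and ~30% of queries
  a weaker secondary hit to exercise best-hit selection;
* **SignalP tables**: Bernoulli(0.15) positive calls with cleavage
  positions uniform over 16..31;
* **glycogene reference and hits**: 40 genes over ten categories with a
  realistic mechanism/fold composition (inverting majority, ~30% GT-A,
  ~20% GT-B), each present with probability 0.8 per sample via a
  threshold-passing hit; some absent genes get sub-threshold decoy hits.

One master seed is fanned out to per-component child streams via
`numpy.random.SeedSequence`, so the corpus is byte-identical across runs
and regenerating one piece never perturbs another.

What it does **not** emulate: read-level noise, assembly fragmentation or
chimerism, isoform structure, correlated codon usage along a gene,
realistic species codon tables, or homology structure among sequences.
Passing tests therefore demonstrate the *statistics* are computed
correctly and recover known generative parameters — not that any
biological conclusion transfers to a particular real dataset.

## Problem sizes and numerical choices

The default corpus is 400 CDS (~1.4e5 codons) — large enough for every
distributional check yet fast enough that the full suite runs in seconds.
The RSCU parameter-recovery check uses a 1,500-CDS draw (~5e5 codons),
chosen a priori so that binomial sampling error of RSCU for the 6-codon
families (≈0.014 SD) sits well below the 0.05 recovery tolerance.
Distributional generator checks (Beta coverage moment, Bernoulli signal
rate) use 3-standard-error bands at n = 10,000, plus a ±1/L allowance
where continuous values are realized on integer coordinates.

Floating-point care: the ExN50 prefix search clamps its index so that
accumulated rounding at x = 100 cannot step past the last transcript; the
RSCU family-sum identity holds to ~1e-15 in practice and is asserted at
1e-9.

## Known limitations

* No HSP merging: a homolog hit by several partial HSPs is credited only
  with its best single HSP's coverage, which can understate completeness.
* Glycogene presence is threshold-based; it trades the sensitivity of
  manual curation for reproducibility.
* The expression reader treats duplicate transcript ids as an error
  rather than summing them; gene-level aggregation of isoforms is out of
  scope.
* FASTA gzip transparency, SAM/BAM and XML alignment formats are not
  supported.
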