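# Methods

This note documents the models, rules and numerical choices behind
`mirisoform`, and what its synthetic-data validation does and does not
demonstrate.

## Read model and preprocessing

A small-RNA library read is modelled as `insert + 3′ adapter (+ filler)`,
truncated to the instrument read length: the insert is a mature-miRNA
isoform (15–27 nt) or an uncharacterized small RNA, so the sequencer almost
always reads through it into the adapter.

**Adapter trimming.** The read is truncated at the *leftmost* alignment of
an adapter prefix (length ≥ `min_adapter_overlap`, default 3) against the
read whose mismatch fraction is ≤ `max_adapter_error_rate` (default 0.1,
allowed mismatches = ⌊rate × overlap⌋); partial matches are implicitly
3′-anchored because the comparison window is capped by the read end.
Qualities are truncated in lockstep. A read with no qualifying occurrence
is kept unchanged — the length window then removes untrimmed full-length
reads, which is safer than discarding short inserts whose adapter fell
outside the cycle window. Trimming is idempotent except in the genuinely
ambiguous case where the retained insert itself ends in an adapter-prefix
homolog; single-pass (conventional) semantics were chosen over iterating to
a fixpoint, which would systematically over-trim such inserts. The default
adapter is the Illumina TruSeq Small RNA 3′ adapter; it is always
configurable.

**Filtering.** A trimmed read is accepted iff 15 ≤ length ≤ 27 nt (the
window that brackets mature miRNAs) and the median Phred score of the
*retained* bases is ≥ 30. The median of an even-length list is the
arithmetic mean of the two middle order statistics; this convention decides
accept/reject exactly at the Phred-30 boundary and is therefore fixed, not
configurable. Whether the quality filter should see pre- or post-trim
bases is not externally prescribed; filtering the retained bases was chosen
because they are what counting sees.

## Counting, prevalence filtering and normalization

Pipeline B tallies exact strings: no collapsing of 1-mismatch neighbours,
because the isoform-level resolution is the point. Reads containing N are
tallied verbatim as distinct strings (never silently merged); N never
matches any reference base during annotation. The cohort matrix unions all
observed sequences with lexicographic row order so outputs diff cleanly.

**Median-prevalence filter.** A row is kept iff its count is ≥ 1 in at
least `ceil(n/2)` of the `n` samples — "at least half" read inclusively,
so a sequence present in exactly half an even cohort passes. "Detected"
means raw count ≥ 1, not an RPM threshold, because filtering precedes
normalization. The filter is idempotent.

**RPM.** `count / denominator × 10⁶` cell-wise. The denominator `R_all`
is the number of *accepted* reads for pipelines B/C (total reads in the
sample after preprocessing) and the number of *mapped* reads for the
pipeline-A surrogate — two deliberately different definitions, selected per
pipeline. When denominators are per-sample column totals, RPM columns sum
to 10⁶ exactly (up to float rounding).

**Size factors.** For the RPM-vs-count-model normalization comparison the
median-of-ratios estimator is implemented directly: per sample, the median
over features with nonzero counts in *every* sample of
count / geometric-mean-across-samples, then rescaled so the factors'
geometric mean is 1 (this scale convention makes invariance under global
rescaling exactly testable). Dispersion estimation and negative-binomial
testing are intentionally absent — only the normalization is compared.
The comparison itself is a pooled Pearson correlation of
log2(value + offset) over all (feature, sample) cells; the offset (default
1 RPM) admits zeros and is recorded with the output.

## Seed analysis

Pipeline C sums isoform rows sharing the same first `k` bases (default 8)
of the 5′ end. This is the 5′ 8-mer — *not* the canonical seed at
positions 2–8 — because 5′ processing of mature miRNAs is precise, the
8-mer covers the functionally decisive region, and most qPCR consensus
targets include it. Collapsing operates on raw counts with denominators
unchanged, so RPM-then-group-sum equals collapse-then-RPM exactly; column
totals are conserved. Isoforms from different hairpins that coincidentally
share an 8-mer prefix are merged (the grouping rule is purely sequence
based) and can be recognized via the per-group member lists in the report.
Default order is filter-then-collapse, with collapse-first available.

## Annotation and the closest-family counter

A sequence is an **entry isoform** when it and a mature entry contain one
another as exact substrings — read bidirectionally, since trimmed isomiRs
are routinely 1–3 nt shorter than the entry and one-directional containment
would push them into the hairpin class. Failing that, it is a **hairpin
isoform** if it occurs inside a hairpin with ≤ 1 substitution (no indels;
tolerance configurable), else **uncharacterized**. Because no genome
alignment is performed, "uncharacterized" here means "matches no provided
mature/hairpin reference" — a strict superset of what a genome-aligned
workflow would call uncharacterized small RNA.

The pipeline-A surrogate matches each accepted read against every mature
reference (substring either way, ≤ 1 substitution, substitutions only) and
increments **every** matching reference — whole-count multi-target credit,
not fractional. Matching is a brute-force all-offsets scan with early
exit; at the ~20 nt scale of this problem that is exact, fast enough, and
trivially checkable against an independent scanner, which the test suite
does on random pairs and on the miR-30-style fixture.

## Fold-change calls

Per feature, the fold change is the ratio of arithmetic-mean RPM across
case samples to the mean across controls (means of RPM, not medians and
not log-space means, matching how marker tables are conventionally
presented; alternatives are config-exposed). Calls use inclusive
thresholds: FC ≥ 1.25 → up, FC ≤ 0.8 → down, else unchanged; features
absent from the filtered matrix are reported `not_detected`, which is
distinct from detected-but-flat. The default pseudocount is 0 and a 0/0
ratio is a hard error — silently imputing would fabricate fold changes; a
feature present in the matrix whose contrasted conditions are both
all-zero (possible only in unfiltered, multi-condition matrices) is
likewise reported `not_detected` rather than given an undefined ratio. No
p-values are attached; the marker evaluation is fold-change-based by
design.

## Synthetic cohorts and ground truth

The generator emulates the structures the pipelines quantify:

* **References**: random hairpins (default 20, 72 nt) with embedded 5p and
  3p mature arms (22 nt, 12 nt flanks), or a user-supplied reference set.
* **IsomiRs**: per-read 5′/3′ offsets drawn from small symmetric
  distributions (defaults: 5′ {−2…+2} peaked at 0 with 60%, 3′ slightly
  wider with 40% at 0, reflecting the looser 3′ processing of real
  isomiRs), sliced from the hairpin so extensions are template-matched;
  plus per-base substitutions at rate 0.01.
* **Abundance**: Zipf-like (1/rank) mixture over mature entries, rank
  order decoupled from name order; condition fold changes multiply entry
  weights for case samples and the mixture renormalizes. The recorded
  `expected_fold_changes` are therefore *compositional* ratios — the
  quantity an RPM fold change actually estimates — which differ from the
  programmed ratios by the case-mixture renormalization constant.
* **Background**: 20% of reads (matching a realistic uncharacterized share
  of roughly a fifth of accepted reads) from a pool of 50 random 15–27 nt
  species, rejection-sampled so none is contained in, or contains, any
  reference sequence.
* **Depth**: 10 samples per condition, 10⁵ reads per sample, with
  mean-preserving log-normal per-sample depth variation (σ = 0.3,
  i.e. ~30% coefficient of variation) so the two normalizations are not
  trivially identical. These cohort sizes keep every end-to-end check
  comfortably desk-scale while leaving per-marker counts large enough
  (tens to hundreds of reads per sample) for ±20% fold-change recovery.
* **Qualities**: per-base Phred ~ N(38, 3), clipped to [2, 41].
  Substitutions touch only the insert, never the adapter, so
  adapter-trimming behaviour is independent of the error model.

One seeded NumPy generator stream drives everything; the seed is recorded
in the sample-sheet header and a fixed seed reproduces FASTQ output
byte-for-byte (gzip mtime is pinned to zero for this reason).

The miR-30-style fixture uses the real entry sequences of hsa-miR-30e/-30a
/-30d-5p (Hamming distances 1 and 2 from the 30e anchor) plus a *synthetic*
4-substitution variant standing in for the more distant family member, so
the family realizes distances {1, 2, 4} at equal length; reads are drawn at
a programmed 30e:30d:30a = 1:2:7 ratio. It reproduces the canonical
ambiguity: at 1-mismatch tolerance the 30e entry is credited to both 30e
and 30a, while the distance-4 member stays unambiguous.

**What passing tests do not show**: the generator has no
position-dependent error profile, no PCR duplicates, no ligation bias, and
its background is uniform-random rather than degradation-derived; real
libraries also carry large fractions of reads outside the 15–27 nt window
(rRNA/tRNA fragments, longer RNAs) that the generator does not emit, so
the near-100% acceptance rate of synthetic cohorts says nothing about
real-data acceptance rates. Conclusions supported by the tests concern
the correctness of counting, grouping, annotation, normalization and
fold-change arithmetic under the stated read structure.

## Numerical and degenerate-input choices

* Phred encoding is fixed to +33; +64 input is rejected by downstream
  implausibility rather than auto-detected (silent mis-decoding is worse
  than a loud failure).
* U→T and uppercase canonicalization happen at every ingest point (FASTQ
  and FASTA), so all comparison is in one DNA alphabet.
* Ties in adapter matching and in best-occurrence scans go to the leftmost
  offset; mismatch scans early-exit once the current best is unbeatable.
* Empty trimmed reads are rejected as `too_short`; an empty FASTQ yields
  an empty stream, and an all-zero column is impossible as a denominator
  (denominators must be positive).
* Seed extraction on a sequence shorter than `k` is a hard error; it
  cannot arise after the 15 nt length filter at the default k = 8.
* Matrix row order is lexicographic everywhere for reproducible diffs.

## Problem sizes used in validation

Unit and property tests run on matrices up to a few hundred rows and
cohorts of 10³–10⁴ reads; the end-to-end fold-change-recovery check and
the acceptance script use the generator defaults above (20 samples ×
10⁵ reads). These sizes were chosen so the complete suite exercises every
pipeline at full default configuration while remaining a coffee-break run
on one CPU.
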