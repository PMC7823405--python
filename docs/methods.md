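# Methods

This note documents the models, algorithms and defaults behind `mirap`, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not demonstrate.

## Adapter inference

**Model.** In a read-through sRNA-seq library every read is
`insert + 3′ adapter (+ downstream sequence)`, truncated at the instrument
read length. Any k-mer of the retained adapter portion therefore appears in
nearly every read, while insert k-mers are diluted across the transcriptome.
Inference counts, over the first `sample_size` reads (default 50,000 — the
head of the file, so no seed is needed), the number of reads containing each
k-mer at least once (k-mers containing N are excluded).

**Default mode** (k = 12): the most frequent 12-mer is the candidate iff its
read-presence ratio is ≥ `ratio_threshold` (default 0.40). The 0.40 default
deliberately sits far above what a single abundant transcript can reach in a
mixed small-RNA library (an individual miRNA rarely exceeds ~15% of total
reads) yet far below the ~100% presence of a true adapter; libraries below it
are declared adapter-free. This absence rule is what lets an adapter-free
library pass preprocessing unharmed.

**Exhaustive mode**: for k ∈ {9, 10, 11, 12} the top 5 k-mers passing any
admission threshold in {0.2, 0.3, 0.4, 0.5} are trial-trimmed against a
5,000-read subsample, scoring each candidate by the fraction of reads whose
trimmed length lands in the miRNA-sized window [18, 26] nt. The best score
wins (ties: longer k, then lexicographic). This scoring is what anchors the
call to the adapter's 5′ end: an interior adapter k-mer trims to
`insert + offset`, pushing lengths out of the window. A sub-12-mer winner is
extended to the most frequent 12-mer containing it. The library is declared
adapter-free when the best score is < 0.20 *and* the best presence ratio is
< 0.05. All thresholds are exposed as function parameters; they are this
package's definitions, chosen once from the read-through model above.

**Known-library matching** slides the candidate ungapped along each library
entry with full containment; similarity = 100 × matches / candidate length,
ties to the earlier entry. ≥ 90% replaces the candidate with the full known
adapter. No indels: adapters differ by substitutions and truncation, and the
ungapped scan is deterministic and oracle-testable. The bundled library
holds nine real platform adapters and nine synthetic entries (named
`synthetic_*`) illustrating user enrichment; entries were screened so that
no 12-mer of one adapter matches another at ≥ 11/12, which keeps
cross-matching unambiguous.

Inference is 3′-only; a user-supplied adapter (3′ or 5′) always takes
precedence and disables inference.

## Preprocessing

Order per read: quality trim → full-adapter removal → k-mer cleansing →
classification. Defaults: quality threshold Q20, length bounds [18, 50] nt,
cleansing k-mer length 10, error rate 0.10, minimum terminal overlap 3 nt.

*Quality trimming* uses the standard running-sum rule: walking from the 3′
end, accumulate (threshold − Q); cut where the partial sum is maximal and
positive (ties resolve to the smaller number of removed bases).

*Adapter matching* is semi-global and ungapped: candidates are every full
adapter occurrence plus every adapter prefix of length ≥ 3 ending at the
read's 3′ end (mirrored for 5′ adapters), valid when mismatches ≤
⌊error_rate × matched length⌋; fewest mismatches win, then the leftmost cut.
The 3 nt minimum overlap exists because shorter terminal matches carry
almost no signal (a random 3-mer matches 1 in 64 reads); it is exposed in
`PreprocessConfig`.

*K-mer cleansing* applies every contiguous 10-mer of the adapter, in 5′→3′
order of start offset, as a 3′ trim pattern to reads the full pass left
untouched; the first matching k-mer trims the read, marks it
`mappable_cleansed`, and removes it from the loop. The loop inherits the
0.10 error rate, so a 10-mer tolerates one mismatch; consequently a k-mer
adjacent to the true fragment can match one base early and cleansed reads
may end within ±1 nt of the exact insert boundary — harmless downstream
because mature assignment tolerates small end offsets (below).

*Classification*: trimmed reads shorter than 18 nt → `too_short`; within
bounds → `mappable` / `mappable_cleansed`; untrimmed reads →
`without_adapter`, discarded as likely artifacts. When the adapter call is
`none` the discard rule is disabled — an adapter-free library loses nothing.
Reads longer than 50 nt after trimming are dropped and tallied separately
(`too_long`); the four-way class fractions fold them into
`without_adapter` so the report keeps its four categories. `too_short` is
assessed before the maximum-length filter.

## Alignment and quantification

The aligner is a deliberate desk-scale design: an exact-match index of all
12-mers of the targets (both strands) is probed with each read's first 12
bases, and candidate placements are verified over the full read allowing at
most 1 substitution (N counts as a mismatch). All best-stratum hits are
reported. The 12 nt seed is this package's choice for the unspecified "seed
region" of short-read aligners; reads with an error inside the seed are
lost, which is the main recovery cost quantified below.

Mature attribution follows the quantifier convention of allowing templated
isomiR ends: a plus-strand hit on a hairpin counts toward a mature miRNA
when it lies within [mature start − 2, mature end + 5]. Multi-mapping reads
increment every matching mature (no fractional splitting); a separate
distinct-read tally avoids double counting in "% of reads quantified". RPM
uses the sample's summed mature counts as denominator, making the count
table self-contained; raw counts are provided for any analysis (like the DE
stage) that needs them.

## Differential expression

Size factors are classical median-of-ratios over rows with no zero count
(an error, with advice to filter, if none exists — cross-checked in the
test suite against an independent DESeq2 implementation). Fold changes are
log2((mean_B + 1)/(mean_A + 1)) on normalized counts; rankings are by signed
fold change. Instead of re-implementing negative-binomial Wald testing, the
significance statistic is a two-sided label-permutation p-value on the fold
change (default 1,000 shuffles, seeded, add-one corrected) — fully
specified and assumption-free, at the cost of granularity at small sample
sizes (with 3 vs 3 there are only 20 label splits). PCA is computed on
log2(normalized + 1) with feature centering.

## The simulator

The simulator regenerates the study conditions used throughout validation:
778,072 single-end reads, adapter-free, split miRNA 39.7% / rRNA 29.3% /
tRNA 12.6% / snoRNA 10.1% / other 8.3% ("other" = random-sequence reads
standing in for unlisted species, since the named classes sum to 91.7%).
Class counts use largest-remainder allocation so the composition is exact
and deterministic; per-miRNA counts are multinomial under a log-normal
(σ = 1) expression profile over 50 synthetic hairpins (60–90 nt, one or two
embedded 20–23 nt matures). miRNA reads are mature sequences with 20% / 10%
probability of a −1 / +1 nt templated 3′ variant; rRNA reads are
pre-fragmented 18–40 nt molecules; tRNA (70–90 nt) and snoRNA (60–300 nt)
reads are random 18–40 nt fragments. 2% of reads receive one uniform random
substitution; qualities are Q30–Q40 with an optional low-quality tail
(default off). All randomness flows from one seeded generator: a seed fixes
the FASTQ byte-for-byte.

The 2%/1-substitution error model is the one unstated quantity of the
original artificial dataset; it was fixed once from the recovery arithmetic
of the ≤1-mismatch aligner (an error lands in the 12 nt seed of a ~22 nt
read about 55% of the time, predicting ≈ 98.9% miRNA recovery) and is
exposed in `SimulationConfig` rather than tuned per experiment.

With an adapter, reads become `insert + adapter + random padding` truncated
to the 50 nt read length — the read-through model — which is what makes
every adapter k-mer near-universal and the inference problem well-posed.

**What passing these simulations does not show.** The generator has no
ligation bias, no indels, no quality-dependent error profile, no
multi-mapping between distinct hairpin families beyond chance, and its
"other" class is random sequence rather than real degradome; real libraries
are harsher on all counts. The validation demonstrates the pipeline's
internal correctness and its behavior under the stated composition, not
performance on arbitrary real data.

## Numerical and scale choices

Evaluation problem sizes — the full 778,072-read dataset, 50,000-read
adapter-recovery libraries, 50 hairpins — are the package's standard
validation configuration and run in about a minute total on one CPU.
Deterministic tie-breaks throughout: candidate k-mers by (count, longer k,
lexicographic), library matches by order, adapter matches by (errors,
leftmost), hairpin pairing by (name-prefix preference, lexicographic).
Degenerate inputs are defined, not special-cased: empty libraries give
empty statistics with zero fractions, all-zero samples keep RPM 0 with a
warning, and a single-sample PCA is an error.

## Known limitations

Single-end Phred+33 FASTQ only; no 5′ adapter inference (removal of a
user-supplied 5′ adapter is supported); no indel-tolerant alignment, isomiR
cataloguing or novel-miRNA discovery; genome alignment is an optional
verification gate, not a placement method; the DE stage is two-condition
only, without dispersion shrinkage or batch correction.
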