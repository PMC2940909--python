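# Methods

This note documents the models, parameter choices and numerical
conventions behind `exontile`. It is the package's own account of its
procedures; every empirical statement here is recomputed by the test
suite or by `scripts/acceptance.py`.

## Coordinates and formats

Internal coordinates are 0-based half-open throughout; everything
written to GFF3 or block TSV is 1-based inclusive. Sequences are
restricted to {A, C, G, T, N}; U is mapped to T and lowercase uppercased
on read. Alignment evidence is consumed as 12-column BLAST-style
tabular rows, with an optional 13th column carrying the query frame for
protein hits (negative frame ⇒ the hit lies on the query's reverse
strand). Query coverage is computed as (|qend − qstart| + 1) / query
length, i.e. coverage *of the query*.

## Redundancy collapse

A hit qualifies for elimination iff identity > 98 %, query coverage
> 0.75 and E < 10⁻⁵ — all three strict, matching the printed
inequalities. The rule is asymmetric by construction: coverage is of
the query, so the shorter/partial sequence is the one eliminated.

Collapse is greedy in a fixed priority order (source class:
gene_prediction > scaffold_model > at_model > velvet_contig > unigene;
then longer sequence; then lexicographic id). A record is eliminated
iff an already-retained record is the subject of a qualifying hit with
it as query. Consequences:

- retention preference for gene predictions over redundant unigenes
  falls out of the class ranking;
- in a similarity chain a ~ b ~ c without an a ~ c hit, the middle
  element is eliminated and both ends kept (greedy, not clique
  clustering) — deterministic and order-independent given the key;
- controls are exempt: never eliminated, and never used as subjects to
  eliminate others (controls are conceptually added after filtering).

The built-in `align_pair` aligner (exact-seed, ungapped extension
+1/−2 with X-drop 10) exists for desk-scale fixtures; its E-value is an
explicit surrogate, 2^(−score/2), monotone in score. Production use
consumes externally computed tabular alignments.

## Orientation cascade

Stage order is fixed: protein hit → genomic hit → array signal →
longest ORF → poly-A tail. The first stage producing a confident call
decides and its evidence class is recorded; a reverse call stores the
reverse complement. Records with no confident evidence remain
unorientated and proceed to tiling with the uniform fallback.

Defaults for the sequence-intrinsic stages (chosen conservatively —
these ranked last in reliability): `orf_min_codons = 100`,
`orf_margin_ratio = 1.5` (the winning strand's longest complete
ATG..stop ORF must reach 100 codons and exceed the other strand's by
50 %; ties abstain), `polya_min_run = 10` consecutive A within the last
`polya_window = 25` bases (forward) or T within the first 25 (reverse);
conflicting poly-A and poly-T evidence abstains. Signal evidence maps
sense-detected → forward and antisense-detected → reverse; the
antisense branch is an extension and simply never fires if the signal
table contains only sense entries.

## Exon boundaries

Blocks from alignments failing E < 10⁻¹⁵ are discarded; among surviving
alignments only the minimum-E one is used (no multi-alignment
reconciliation — determinism). Consecutive blocks merge into one exon
when the transcript-side gap is < 3 bases (small indels) and the
genomic gap is < `min_intron_gap = 50` bases; larger genomic gaps are
treated as introns and place a boundary. Overlapping transcript blocks
in one chain are a hard error (malformed input). Without usable
evidence a transcript is one exon spanning its full length
(`uniform_fallback`), so probes are spread evenly.

## Probe tiling

Per gene: `probes_per_gene = 15` probes of `probe_length = 25` bases,
against an array capacity of 2.44 million probes. Usable length of an
exon is its candidate offset count, max(0, length − 24). Probes are
apportioned among exons proportionally to usable length by
largest-remainder rounding (remainder ties to the earlier exon; counts
capped at usable length). Within an exon, target offsets are
round((i + 0.5)·usable/count); each target snaps outward to the nearest
acceptable offset, lower offset on ties.

A window is acceptable when it contains no N, passes the complexity
screen (mononucleotide entropy ≥ 1.2 bits, homopolymer run ≤ 12, no
period-2 repeat covering ≥ 20 of 25 bases) and is not
cross-hybridising. Cross-hybridisation uses two strand-canonical k-mer
indexes over the whole record set: the exact rule fires when the
25-mer occurs in any other gene; the seed rule fires when any
contiguous 18-mer occurs in ≥ 2 other genes (a cheap stand-in for
near-exact matches). These filters are a transparent replacement for a
vendor-internal probe quality score, which is not public.

Exclusion reasons are assigned with a fixed precedence: `too_small`
when candidate offsets < 15; `low_complexity` when complexity-passing
candidates < 15; otherwise, if unique probes are insufficient, the
shortfall is notionally filled with cross-hybridising windows and the
gene excluded — `indistinguishable` when one single competitor gene
carries all selected probes (e.g. a verbatim copy: no probe set could
tell the two apart), `cross_hybridisation` otherwise. This generalises
the natural "every candidate fails" definitions to mixed-failure genes
while reproducing them exactly in the pure cases.

Probe sequence defaults to the reverse complement of the sense
transcript window (sense-target chemistry); `probe_strand = "sense"`
flips this. Identical input yields byte-identical design files.

## Expression statistics

All signals are log2; fold changes and splicing indices are reported on
the linear scale. Gene-level signal is the unweighted mean of a gene's
probe-set log2 values (the commercial gene-summarisation algorithm is
proprietary; the unweighted mean is the transparent choice).

- **Median standardisation** subtracts each probe set's median log2
  value across samples.
- **Pre-filter**: a gene is removed when its fold change between
  condition means lies in the *inclusive* band [0.77, 1.3] ("between"
  read inclusively); with > 2 conditions, only when every pairwise fold
  change is inside the band.
- **Differential expression**: one-way fixed-effects ANOVA across
  conditions on gene-level values (scipy), BH step-up correction
  (implemented in-package, cross-checked against an independent
  reference in tests), significant at corrected p < 0.01 and linear
  fold change > 2 in either direction. Zero within-group variance with
  distinct means is perfect separation (p = 0); fully constant data
  give F = 0, p = 1.
- **Splicing index**: on a gene-normalised matrix (each probe set minus
  its gene's mean per sample), SI = 2^(mean contrast) between two
  conditions; flagged at SI ≥ 5 *on the linear ratio scale*. A log2
  reading of the same threshold (32-fold) was judged implausibly strict
  for an exon-level effect; `si_scale = "log2"` is available for the
  alternative interpretation.
- **3′/5′ bias**: linear 3′/5′ ratios per control pair; Welch
  (unequal-variance) two-sample t-test, one-tailed, default alternative
  "platform B more biased". Welch is the safe choice where only a
  "one-tailed t-test" is specified.

### Numerical conventions

Band and threshold comparisons are performed in log2 space with bounds
computed by the same `math.log2` call the generators use, so a planted
fold change of exactly 1.3 meets the bound bit-for-bit (a monotone
transform; the decision is mathematically identical). On top of that,
threshold comparisons carry a relative 10⁻⁹ equality guard: values
equal to the threshold up to last-ulp rounding (as produced by mean /
normalisation chains) count as equal. This is a float-tie guard, not a
band change — a ratio of 4.99 still does not flag.

## Synthetic fixtures

The generators define the study conditions for all tests; they are pure
functions of their parameters and seed (byte-identical reruns).

- **Unigene sets**: base genes are uniform-random sequences screened to
  share no 18-mer (both strands), so the cross-hybridisation filter
  fires only on planted collisions. Each base gene gets exactly one
  unambiguous orientation evidence source, round-robin over the five
  classes; ORF evidence is planted as a cassette of ≥ 120 stop-free
  sense codons (verified unambiguous under the default ORF parameters,
  regenerated otherwise), poly-A as a 12-base tail. Half the records
  (by default) are stored reverse-complemented with the evidence
  flipped to match. Duplicates copy a contiguous `dup_coverage`
  fraction of a parent, pad with fresh sequence, and are mutated by
  substitutions only — so the realised identity and query coverage of
  every planted duplicate are known exactly from the edit script.
- **Expression matrices**: two conditions ("leaf"/"root") × `n_reps`
  replicates; gene baselines ~ Normal(8, 2) log2 shared by the gene's
  probe sets; i.i.d. Normal(0, `noise_sd`) per cell. DE effects add
  ± `de_log2fc` to every probe set of a gene in one condition. Splice
  effects are planted *on the gene-normalised scale*: the target probe
  set is raised by log2(ratio) and its siblings lowered by
  log2(ratio)/(k−1) in that condition, so the gene mean is unchanged
  (no DE leakage) and the gene-normalised contrast equals the planted
  ratio exactly. A naive one-sided shift would be diluted by (k−1)/k
  through gene normalisation and would distort the gene's fold change.
- **Control pairs**: probe5 ~ Normal(8, 1), probe3 = probe5 +
  log2(bias_factor) + noise, so the expected linear ratio is the bias
  factor. Default n = 17 pairs per platform mirrors a typical control
  ladder.

What the fixtures do **not** emulate: real base composition and
paralogue divergence spectra, EST sequencing error, alignment noise in
block evidence, probe-level (as opposed to probe-set-level) intensity
models, and array normalisation artefacts. Passing tests therefore
demonstrate the correctness of the decision rules and statistics under
controlled conditions, not field performance on real cDNA collections.

## Problem sizes

The default test and acceptance runs use 8–50 genes of 0.5–1.2 kb,
matrices of ≤ 40 genes × 6 samples, and 20-seed recovery sweeps —
sizes chosen so the full suite runs in seconds while every code path
(multi-exon allocation, each exclusion class, each evidence class,
boundary values of every threshold) is exercised.

## Known limitations

- The redundancy collapse resolves mutual/transitive redundancy among
  equal-class sequences by the documented greedy order; other orders
  would be equally defensible.
- The internal aligner's E-value is a surrogate; it must not be
  compared against thresholds calibrated for library-size-aware
  statistics.
- The cross-hybridisation screen is k-mer exact/seeded; it does not
  model thermodynamics (Tm/ΔG) or mismatch tolerance beyond shared
  18-mers.
- `de_test` assumes a balanced design with ≥ 2 replicates per
  condition and fixed effects; no empirical-Bayes variance shrinkage.
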