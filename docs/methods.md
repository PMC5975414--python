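# Methods

## Scope and data model

`splicevis` operates on level-3-style quantification matrices (features ×
samples, non-negative reals, RSEM-like normalized counts) rather than reads:
there is no alignment, no PSI from read counts, no splicing-event
classification and no differential-splicing statistic. The analysis unit is
one queried gene; all annotation and normalization is performed per gene.

Coordinates are 0-based half-open internally. GTF files and locus-encoded
feature IDs (`chrom:start-end:strand` for exons,
`chrom:pos:strand,chrom:pos:strand` for junction donor/acceptor anchors) are
1-based inclusive at the boundary, converted exactly once at I/O.

## Annotation by overlap

An exon feature is assigned to every transcript whose genomic *span*
(first-exon start to last-exon end) it overlaps by at least one base; a
junction is assigned to every transcript whose span contains both anchors.
The span rule — rather than exon-level intersection — is deliberate: it
matches a display whose rows are quantified features aligned against whole
isoform ranges, and it is monotone (enlarging a feature never loses
matches). Junctions use both-anchor containment rather than
either-anchor overlap; with span-based matching, either-anchor would admit
junctions that merely brush a transcript's end. Features with unknown
strand match transcripts on either strand; a known-vs-known mismatch
excludes the match. A feature overlapping no transcript of the queried gene
is returned unassigned, never an error, since per-gene querying is the
tool's model. Implementation uses an interval tree over transcript spans;
the test suite checks equivalence against a brute-force all-pairs oracle on
randomized inputs.

## The usage transform

Given the gene's feature matrix `x` (n features × m samples):

1. `e_j = mean_i x_ij` — the gene expression estimate is the plain average
   of the features being normalized (exon and junction matrices are
   normalized independently, each with its own n).
2. `r_ij = x_ij / e_j` — the splicing-index step; where `e_j = 0` the ratio
   is defined as 0 and the sample is flagged in the result
   (`zero_expression_samples`) rather than emitting NaN, matching the
   visual semantics of an empty column.
3. `Q95_i` = 95th percentile of `r_i·` across samples, linear interpolation
   between order statistics (numpy's default "linear"/type-7 method). The
   quantile is taken of the *ratios*, not the raw values: the transform
   divides `r` by it, and the 0.05 floor it is compared against is a
   gene-relative threshold.
4. `y_ij = min(r_ij / max(Q95_i, 0.05), 1)`.

Consequences worth knowing: values at or above the feature's 95th
percentile clamp to exactly 1, so with m ≥ 20 every feature attains 1;
multiplying one sample's column by any c > 0 leaves that sample's usage
unchanged (library-size invariance); and group means of `y` are compressed
relative to the underlying inclusion fractions, because `Q95` sits in the
upper tail of the noisy ratio distribution (see "What the generator shows"
below). Equivalence with an independent scalar transcription of the formula
is enforced to 1e-12 in the tests.

## Clinical harmonization

Rules are data, not code: a JSON list (packaged default in
`src/splicevis/rules/default_rules.json`) names each output variable, its
kind and its raw source field, so per-cohort variable sets can be swapped
without code changes. Generic kinds (`passthrough`, `numeric-binned`,
`merge-map`, `survival`) cover simple transformations; the dedicated kinds
(`pack-years`, `stage`, `lihc-risk`, `alcohol`, `pregnancies`) encode
semantics that plain bins or maps cannot (substage stripping, the 0-vs->0
split, the 1–5/>5 classes).

Decisions taken where the conventions were open:

- Pack-years bins are half-open — [0,10), [10,100), [100,∞) — the only
  reading consistent with the labels "less than 10" / "less than 100" /
  "greater than 100"; exact boundary values go to the upper bin.
- Survival: event = 1 only for a defined, *non-zero* `day_to_death`
  (a recorded 0 is treated as not-a-death); time = max of the present day
  counts; both absent → missing pair. Event is never emitted without a
  time. Negative day counts are errors.
- Stage collapsing is case-insensitive, strips a `Stage ` prefix and one
  trailing substage letter A/B/C only (so `IS` does not become `I`),
  yielding exactly {I, II, III, IV, X}; anything else, including the
  literal `Indeterminate`, maps to `UNDEFINED`.
- Pregnancies 0 is outside the declared class vocabulary {1..5, >5} and
  maps to `UNDEFINED`, as do non-integers.
- All rules are total over arbitrary string/number input: unknowns land in
  the literal `UNDEFINED`, never an exception (the explicit error contracts
  — negative pack-years, negative day counts — are the exception for
  plainly corrupt input). `Indeterminate` matching is case-insensitive.
- A rule whose source field is absent from the table produces `UNDEFINED`
  for every record plus a warning, not an error.

`harmonize` emits a report (per-variable category counts, `UNDEFINED`
tallies, event counts) used for reconciliation against ground truth.

## Survival analysis

Groups are formed by an isoform-expression cutoff; the default is the
midpoint of the observed range, `(min + max) / 2`, and expression exactly
at the cutoff goes to the high group. Start-time filtering keeps samples
with `time >= start` and re-zeroes their clocks — a plain filter, not
left-truncation with delayed entry; the conditional-KM alternative was
considered and rejected as a different estimand than the "filter the
entered individuals" behavior being reproduced. The product-limit
estimation itself is delegated to `lifelines.KaplanMeierFitter`; the module
extracts event times, per-step survival and at-risk counts into a plain
`KMCurve`, and the tests verify it against an independently coded
product-limit loop and against closed forms (no censoring → one minus the
empirical CDF). A log-rank test is available as a clearly-marked extra; the
rendered figures carry no test statistic. Cox models, hazard ratios and
confidence bands are out of scope.

## Rendering

SVG output is deterministic by construction: no timestamps, element order
is insertion order, geometry floats fixed at 3 decimals. Identical inputs
give byte-identical documents, which is what the determinism tests assert.
Numeric fidelity and layout are testable without pixel comparison because
every usage mark carries `data-sample-id`/`data-feature-id`/`data-y`
attributes (12 significant digits, round-tripping well under 1e-9), KM
groups carry their step values, and box rects carry their quartiles.

In the main plot, samples are columns ordered within each clinical group by
ascending gene expression with ties broken by sample id; each feature row
draws one vertical mark per sample with height proportional to `y_ij`
(a vertical-mark encoding of the original's shadowed-line rows — the exact
area-vs-bar convention of the source figures is not specified, so the
simplest faithfully-proportional encoding was chosen). The left panel draws
each transcript as exon boxes joined by an intron line on a linear
genomic-to-pixel scale over the gene span. Box plots use Tukey convention:
quartile box, whiskers to the most extreme point within 1.5 IQR, points
beyond drawn individually. Colors come from a fixed palette assigned to
category labels in sorted order. Interactivity (hover, knobs, browser
links) is replaced by CLI flags (`--cutoff`, `--start-time`); an optional
PNG rasterization was considered and dropped — SVG is the testable,
diffable artifact.

## The synthetic cohort generator

`fixtures.simulate` emulates the input side of a tumor-study cohort:

- **Gene models**: non-overlapping genes on one chromosome, integer-grid
  coordinates (120 bp exons, 380 bp introns). Within a gene, transcripts
  share flanking exons and differ by one skipped internal exon — the
  cassette pattern; by default 2 transcripts, 6 exons, cassette at index 3
  (the fourth exon).
- **Quantifications**: per-sample gene abundance is log-normal
  (median 1000, σ = 0.5 on the log scale — a realistic inter-sample spread
  for normalized counts). The inclusion isoform receives fraction *p* of
  the gene's output (default 0.9 in the 150-sample tumor-like group, 0.1 in
  the 50-sample normal-like group, n = 200 total); remaining isoforms split
  the rest equally. Exon values are sums over isoforms containing the exon,
  junction values sums over isoforms in which the flanking exons are
  adjacent (so the skip junction is carried by the skip isoform), each
  times multiplicative log-normal noise (σ = 0.2, "moderate": ±20%-ish
  scatter). With σ = 0 the construction identities are exact.
- **Clinical**: category truths (stage, pack-years, risk factor, alcohol,
  pregnancies, with realistic missingness) are sampled *first* and then
  rendered into raw TCGA-style strings (substaged `Stage IIIA`, numeric
  pack-years, `Indeterminate`/empty for missing), so the manifest's
  expected counts are ground truth independent of the harmonizer being
  tested. Survival is exponential with log-hazard
  `log h = log h0 + β·z`, z the standardized log inclusion-isoform
  expression (h0 = 1/1500 per day, β = 1), censored by uniform follow-up on
  [0, 2000] days — the minimal model that makes cutoff-grouped KM curves
  separate in the configured direction.

What passing on this generator does and does not show: it validates the
formula implementations, the plumbing between modules, determinism, and
that a strong configured splicing switch and survival effect are recovered
end to end. It does not emulate batch effects, isoform-estimation
uncertainty, length biases, correlated noise across features, TCGA barcode
semantics or realistic censoring patterns, so it says nothing about
statistical power on real cohorts.

One quantitative note: with inclusion 0.9 vs 0.1 the *usage* group
difference recovered end to end is ≈ 0.67–0.68, not 0.8. This is the
quantile rescaling at work — `Q95` of the cassette ratios sits in the noisy
upper tail of the tumor group (≈ 1.2× the tumor-mean ratio), deflating the
tumor mean usage to ≈ 0.78 while the normal group sits near 0.10. The
recovery check's ±0.15 band around the configured difference accommodates
exactly this known compression.

## Numerical and degenerate-input choices

- Quantile method everywhere (Q95, box-plot quartiles): linear
  interpolation between closest order statistics, the mainstream default.
- `e_j = 0`: usage 0 plus a flag, never NaN. All-zero matrices render as
  empty columns.
- Missing values at load: impute-0 with a warning count by default;
  `missing="drop"` removes rows instead. Both are tallied in the load
  report.
- Book-ended or duplicate exons in a GTF transcript are merged; truly
  overlapping exons, duplicate transcript IDs across genes, malformed
  lines (with line number) are errors. Exon-less transcripts are skipped
  with a warning.
- Gene resolution precedence: exact symbol (case-insensitive) > exact ID >
  unique alias; ambiguity is an error listing candidates.
- Sample joins are inner joins with a mandatory reconciliation report
  (counts of expression-only, clinical-only and survival-less samples) —
  silent drops being the classic join bug in this data.
- Empty groups: cutoff splits warn and proceed with the nonempty group;
  the main plot refuses a spec whose groups contain no samples.

## Known limitations

Whether the original tool computed `Q95` on ratios or raw values, and
whether its start-time knob meant filtering or true left truncation, is not
documented; the choices here (ratios; filtering) are explicit and tested
but are this package's own. The per-cohort 30-variable catalogue is not
reproduced — the shipped rule set covers the six documented transformation
families and is extensible through the rules JSON. The usage statistic
inherits the limits of span-based annotation: features shared between
overlapping genes are attributed to whichever gene is queried.
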