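# Methods

## Measurement model

`storyload` treats a narrative stimulus as a bag of countable surface
events. Four features are extracted per text, chosen to be complementary
proxies for structural demand and to be computable with deterministic
string rules so that two runs — or two labs — always agree:

* **Sentence count.** The automatic splitter cuts after any run of `.`
  `!` `?` followed by whitespace, discarding empty fragments. This rule is
  deliberately naive: it over-splits abbreviations ("Mr. Smith") and knows
  nothing about functional clause boundaries. The sanctioned correction is
  the `sentence_count_override` manifest column: when present, the
  effective count (denominator of the ratio features) follows the
  override while the automatic split is retained for per-sentence keyword
  flags. We prefer an explicit, auditable override to a cleverer splitter
  whose behavior would be harder to reproduce.
* **Average sentence length** = word count / effective sentence count,
  kept at full precision. Words are maximal whitespace-delimited tokens;
  hyphenated words and contractions are single tokens and punctuation
  stays attached.
* **Complex sentence ratio** = fraction of sentences containing ≥ 1
  subordinating conjunction (default set: *because, although, when, if,
  since, though, unless, while*; configurable). A sentence with several
  subordinators counts once; sentence-initial subordinators count.
  If an override sets the effective count below the number of
  subordinator-bearing auto sentences the numerator is clamped to the
  denominator with a warning — the ratio is defined on [0, 1].
* **Estimated Information Units** = commas + "and" occurrences + "but"
  occurrences. Only U+002C counts; semicolons and dashes are excluded
  because the definition names commas. This is a proxy for the
  informational density of the *written* stimulus and is not comparable
  to produced IUs scored from spoken retellings.

Keyword matching has two modes. The default, `word_boundary`, requires
whole-word, case-insensitive matches ("band" ≠ "and"). The `substring`
mode reproduces naive `str.count`/`re.search` behavior for parity with
simpler pipelines; it applies to both the and/but counts and subordinator
detection. The active mode is echoed into every artifact so profiles are
self-describing. `word_boundary` ≤ `substring` holds for any text.

## Normalization, composite, blocks

Each feature is standardized across the corpus, z = (x − μ)/σ, using the
**population** standard deviation (divide by n). The composite load score
is the unweighted mean of the four z-scores, so every z column has mean 0
and variance 1 and the composite column has mean 0 (asserted to 1e−9 in
tests). Population σ is a deliberate convention: the corpus *is* the
population being profiled, not a sample from which a variance is being
estimated, and the test suite verifies empirically that only this choice
reproduces the reference composites (the sample-σ variant misses the
largest composite by ~0.03, an order of magnitude beyond the ±0.005
reproduction tolerance).

Composites are always computed from full-precision features (exact
fractions like 7/14, exact quotients like 220/14), never from 2-decimal
display values; rounding is confined to reports.

Blocks are assigned by rank: with n stimuli and k = 3 labels, the
stimulus of rank r (ascending composite, stable order) receives block
⌊r·k/n⌋, so the top third is High. For n divisible by 3 with distinct
composites the split is exactly equal (4/4/4 at n = 12); otherwise sizes
differ by at most one, the larger blocks at the low end. This matches the
behavior of quantile-cut binning at the corpus size the package was
validated on; for n not divisible by 3 the equal-size rank rule is used
because it has an unambiguous independent oracle (sort, slice into
near-equal thirds). Ties straddling a boundary are broken by input order
with a warning — equal composites have no principled ordering, and real
feature tables essentially never tie.

Degenerate inputs raise rather than propagate NaNs: a constant feature
column (σ = 0), fewer than 3 stimuli, or an all-equal composite vector
are errors naming the offending quantity.

## Outcome analysis

Produced-IU gains are role-specific: treated stimuli use the
within-session change (post − pre); evaluation-only stimuli use the
delayed change (Post2 − Pre), with the full interval decomposition
(Post1−Pre, Post2−Pre, Post2−Post1) carried alongside — the intervals
telescope by construction. The summary reports Pearson correlations
between composite and gain for the all/treated/evaluation subsets, mean
gains per load block, per condition, and per treated-only block.
Correlation of a present subset with n < 3 pairs or zero variance raises;
an absent role is simply skipped. p-values are off by default — at these
sample sizes they would invite over-interpretation — and available behind
a flag that warns about n.

## Synthetic stimuli

The generator inverts the extractors: given targets (sentence count S,
word count W, complex-numerator C, IU count K) it allocates per-sentence
word budgets (≥ 1 word each, ≥ 3 for complex sentences), fills them from
a closed vocabulary, places exactly one subordinator in the interior of
each complex sentence, and realizes the K IU events as a seeded-random
mix of "and"/"but" word substitutions (word-count neutral by replacement)
and commas appended to words. Counts are tracked during assembly, so the
extracted features equal the targets exactly — no post-hoc search — and
the result is verified by re-extraction before return. Achievability
requires W ≥ S + 2C; violations raise an error naming the failed
constraint. The vocabulary contains no keyword as a substring, so
`word_boundary` and `substring` extraction agree on every generated text.

Generated texts exercise the counting rules, nothing more: they are
grammatically empty filler and carry none of the properties of real
narratives (semantics, cohesion, schema structure, topic familiarity).
Round-trip tests on them certify the extractors and the pipeline
plumbing; they say nothing about how well the four features capture the
load of real stories.

Default corpus-generation ranges mirror the profiled study corpus of 12
short narratives: 11–16 sentences, 150–230 words, complex ratio
0.10–0.90, 10–22 estimated IUs. All generation is deterministic given a
seed.

## Packaged reference data

The original 12 story texts are adaptations of the Discourse
Comprehension Test and cannot be redistributed, so the package ships the
published per-stimulus tables instead: raw features with printed
composites and blocks, per-stimulus IU gains with roles (evaluation-only:
Gas, Library, Loan), and the three evaluation-stimulus IU trajectories.
Printed composite strings are preserved verbatim (the two source tables
print one stimulus at different precision) alongside parsed floats.
Full-precision feature vectors are reconstructed from the printed values
as word_count/sentence_count and round(ratio·n)/n; reconstruction rather
than storage of rounded values is what lets the pipeline reproduce the
printed composites to ±0.005.

## Problem sizes and limitations

All computations are desk-scale: the reference corpus has 12 stimuli,
property tests sweep corpus sizes 3–30 and ~100 random generator specs,
and the whole suite plus the acceptance script run in seconds.

Known limitations: the sentence splitter is intentionally naive (override
is the remedy); estimated IUs conflate commas of style with commas of
structure; the composite weights the four z-scores equally with no
empirical weighting; block labels depend on the corpus being profiled
(adding a stimulus can move another's block); and the outcome analysis is
descriptive — a single participant and twelve stimuli support directional
statements only.
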