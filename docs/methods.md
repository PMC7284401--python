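# Methods

## The categorization model

Each message line is treated as a bag of words: lower-cased, split on
non-alphanumeric boundaries, stop words removed, remaining tokens counted as
raw term frequencies. A category is defined by a keyword set; a line is
assigned *every* category for which at least one keyword has a positive
score, so the classifier is multi-label by construction and assignment is a
pure union over categories — there is no scoring competition between
categories and no tie-breaking. A line matching no keyword in any category
receives the fallback label (*miscellaneous*), and the fallback is exclusive:
a line is miscellaneous precisely because nothing else matched, so the
fallback code never co-occurs with another code.

Keywords are normalized token sequences. Unigrams are matched through the
stop-word-filtered bag. Multi-word keywords ("blood test", "follow up") are
matched as contiguous token runs in the normalized raw line with stop words
*retained*, since phrases can legitimately contain function words ("follow
up"). Whether a deployment should match stems, exact tokens, or phrases is
genuinely open in this class of rule-based systems; this package declares
the exact-token + contiguous-phrase mechanism and applies it uniformly. No
stemming, lemmatization, spelling correction, or negation handling is
performed — the model is deliberately the simplest auditable rule system.

A keyword may appear in several categories (topic overlap is a feature of
clinical messages), but the shipped default lexicon is constructed
collision-free — no unigram of one category appears inside another
category's phrase — so that synthetic recovery tests are exact. The shipped
lexicon is a stand-in assembled from category-typical clinical vocabulary;
it is **not** any study's reviewed keyword list, and results on real logs
depend entirely on the lexicon supplied.

## Exclusion filtering

Two line types are removed before categorization, because they carry no
topical intent and would inflate the denominator:

* **automated** — exact match of the normalized (lower-cased,
  punctuation-stripped, single-spaced) line against a template list. App
  platforms emit these verbatim, so exact matching is both sufficient and
  the safest rule.
* **greeting-only** — every non-stop-word token of the line belongs to the
  vocabulary spanned by the greeting templates. This subset rule (rather
  than exact match) excludes "Thanks!!" and "hello hello" as intended. A
  line with no informative tokens at all is classed greeting-only.

Automated matching has priority; the two template lists and the stop-word
list are plain-text data files and fully overridable. Direction filtering
(keep patient→HCP) is applied before exclusion filtering; the order is a
package decision, configurable by simply composing the functions the other
way.

## Reporting

Per-category percentages use the number of categorized lines as the common
denominator and are rounded half-up to two decimals; because labels overlap
they intentionally sum past 100. The co-occurrence matrix is indexed by the
non-fallback categories: off-diagonal M[a][b] counts lines whose label set
contains both a and b; the diagonal M[a][a] counts lines labeled *exactly*
{a} (solo counts). Reading the diagonal as solo counts rather than total
occurrences is a declared choice — both are computable from the label sets,
and the solo reading makes the matrix answer "which topics stand alone?".
Only pairwise overlap is tabulated; triples and higher orders exist in the
data but have no natural place in a two-dimensional heat map.

## Keyword mining

Candidate keywords for a category are tokens whose summed term frequency
over the lines labeled with that category reaches a threshold, default 10 —
an exact, configurable integer. Candidates are ranked by frequency then
lexicographically and are advisory: in a real deployment a clinician reviews
them before they enter the lexicon, which is why mining output never feeds
back into the classifier automatically. Raising the threshold can only
shrink the candidate set (monotonicity, property-tested).

## Rater agreement

Against one rater, a line's overclassification is |algorithm \ rater| and
its underclassification is |rater \ algorithm|. A nonzero difference is
*minor* when over ≤ 2 and under ≤ 1, else *major*; the bounds are module
constants. The asymmetry encodes the domain judgment that adding a secondary
topic is cheap while missing the rater's intent is not. A line breaching
either bound (e.g. over = 3 with under = 1) is major. The headline metric is
the fraction of lines with minor or no differences. When a summary is
rebuilt from published-style histograms, each differing line is assumed to
contribute to one side only — the natural reading of a two-column histogram.

Inter-rater reliability is Krippendorff's alpha for nominal data via the
coincidence matrix: with o_ck the coincidence counts (each unit of m ratings
contributes its ordered rating pairs with weight 1/(m−1)), marginals n_c and
total n, alpha = 1 − D_o/D_e where D_o = Σ_{c≠k} o_ck / n and
D_e = Σ_{c≠k} n_c n_k / (n(n−1)). Units rated by fewer than two raters are
dropped; all-identical ratings give alpha = 1 by convention. The unit value
is the whole canonical label-code string (ascending digits, no separators),
so "12" versus "1" is simply one disagreement; a per-category binary
variant, macro-averaged over categories, is available behind a flag for
sensitivity analysis. No chance-corrected multi-label distance (MASI etc.)
is attempted.

## Synthetic corpus generator

The generator emulates only what the classifier consumes: token-level
structure. Each line is greeting, automated, or labeled, by one seeded roll
against the configured fractions. Labeled lines sample a base category from
the prevalence weights, then add each other category pairwise with its
overlap probability (higher-order overlap arises implicitly; only pairwise
overlap is controlled, matching what the reporting tabulates). Content is
`keywords_per_line` draws from each truth category's keyword set, phrases
kept intact, shuffled with 1–3 filler tokens from a vocabulary disjoint from
all keywords. A base draw of the fallback category produces a filler-only
line. Timestamps advance in fixed 1-minute steps (time plays no role in the
analysis); all generated lines are patient→HCP; identifiers are sequential
and unique. Same spec + seed gives a byte-identical log.

Defaults are fixed to the study conditions this generator stands in for:
eight categories with base weights proportional to the published final
category counts (symptoms 2033 … miscellaneous 624 of 6193); greeting
fraction 0.176 and automated fraction 0.08, together reproducing the
published overall exclusion rate (2131 of 8324, with the automated share
near the published 666/8324); pairwise overlap concentrated on
symptoms–medications (0.30) and symptoms–communications (0.25), the pairs
the published heat map shows co-occurring most. Message length and
per-patient message counts have no published distribution; the defaults
(2 keyword draws per category, 50 filler types, 1–3 fillers per line,
50 patients per 1000 lines) are arbitrary and exposed as configuration.

What passing the synthetic suites shows — and does not. With filler disjoint
from the lexicon, pipeline recovery of planted labels is *exact by
construction*; the tests therefore verify the machinery (tokenization,
matching, exclusion, bookkeeping), not classification quality on real
prose. Real messages contain misspellings, synonyms, negation, and topic
vocabulary absent from any fixed lexicon; nothing here estimates that gap.
The marginal category frequency equals the configured prevalence only when
pair overlap is empty (partners inflate marginals), so the binomial
prevalence check runs in that regime.

## Numerical and interface choices

* Percent rounding: decimal half-up to 2 places (bankers' rounding would
  disagree with printed two-decimal tables on ties).
* Logs are RFC-4180 CSV, UTF-8, header-mapped (not positional) with a
  documented alias table; unknown direction values and duplicate
  identifiers are hard errors, since silent row loss would bias every
  count; unparseable timestamps warn and retain the raw string because time
  is unused downstream.
* Rater code strings reject repeated digits as ambiguous rather than
  de-duplicating.
* Problem sizes in the test and acceptance suites (5000-line recovery
  corpus, 100 corpora of ≤ 50 lines for oracle equivalence, 100 replicates
  of 3 independent raters over 500 units) were chosen as the smallest sizes
  at which the stochastic properties are stable.

## Known limitations

* The default lexicon is a stand-in; quantitative results on any real log
  require the deployment's own reviewed lexicon.
* Greeting detection by vocabulary subset can over-exclude a line that is
  entirely greeting vocabulary yet meaningful in context ("ok great").
* Alpha on label-code strings treats "12" vs "1" the same as "3" vs "5";
  the per-category variant softens this but no partial-credit metric is
  implemented.
* The generator does not emulate HCP→patient replies, attachments, urgent
  flags, or demographic metadata beyond placeholders.
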