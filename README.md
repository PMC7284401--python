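# ibd-dialog

Rule-based categorization of patient-to-provider secure messages in
inflammatory bowel disease (IBD) care.

Patients with IBD exchange large volumes of short electronic messages with
their health care providers (HCPs) through care-management platforms. Before
any chatbot or triage automation can be built on such a log, one needs to
know *what* patients write about. This package implements a transparent,
fully rule-based pipeline for that question, aimed at health-informatics
researchers and clinical NLP practitioners:

1. **Ingestion** — parse a 10-field message-log export (identifier, names,
   timestamp, direction, content, attachment, HCP classification/response),
   anonymize it by nulling the name fields, and keep the patient→HCP lines.
2. **Exclusion** — drop greeting-only lines ("Thank you", "Hello") and
   platform-automated lines ("Patient has indicated there are no changes to
   medications.") so they do not distort the topic counts.
3. **Categorization** — a bag-of-words multi-label classifier: each line
   *d* is tokenized (lower-cased, stop words removed) into term frequencies
   tf(w, d), and receives every category *c* whose keyword lexicon K_c
   contains a positively scoring term,

       labels(d) = { c : ∃ w ∈ K_c with tf(w, d) > 0 },

   falling back to *miscellaneous* when no keyword matches. The shipped
   eight-category lexicon (symptoms, medications, appointments, laboratory
   investigations, finance/insurance, communications, procedures,
   miscellaneous) is a stand-in assembled from category-typical clinical
   vocabulary; swap in your own via a JSON file.
4. **Reporting** — per-category line counts and percentages (which sum past
   100 because labels overlap) and the symmetric pairwise co-occurrence
   matrix with solo counts on the diagonal, renderable as a heat map.
5. **Lexicon mining** — propose candidate keywords for a category as terms
   whose summed frequency over lines labeled with it reaches a threshold
   (default 10); proposals are advisory, pending expert review.
6. **Agreement** — compare algorithm label sets against human rater digit
   codes ("123" = categories 1, 2 and 3): per line, over = |algo \ rater|
   and under = |rater \ algo|; a nonzero difference is *minor* when
   over ≤ 2 and under ≤ 1 and *major* otherwise. Inter-rater reliability is
   Krippendorff's alpha on nominal label-code values,
   alpha = 1 − D_o/D_e, computed from the coincidence matrix.

Because no real clinical log ships with the package, a first-class synthetic
generator plants known category structure — labeled lines built from lexicon
keywords plus keyword-free filler, greeting and automated lines at chosen
fractions — so every stage can be verified against planted truth.

## Worked example

```python
import ibd_dialog as d

lex = d.load_lexicon()                     # shipped 8-category lexicon
spec = d.SyntheticSpec(n_lines=2000, seed=42)
corpus = d.generate_corpus(spec, lex)

kept, excluded, _ = d.apply_exclusions(corpus.records)
labels = d.categorize_corpus(kept, lex)
truth = corpus.labeled_truth()
print(excluded, sum(labels[i] == truth[i] for i in labels), len(labels))
print(d.frequency_report(labels, lex).to_frame(lex).head(3).to_string(index=False))
```

prints

```
534 1466 1466
 code     category  count  percent
    1     symptoms    432    29.47
    2  medications    415    28.31
    3 appointments    224    15.28
```

All 534 planted greeting/automated lines were excluded, all 1466 planted
label sets were recovered exactly, and 29.47% of the kept lines mention
symptoms (percentages across categories sum past 100 because one line can
carry several labels).

The numbered drivers under `analysis/` run the same pipeline end to end at
study scale (8324 lines) and write their tables under `results/`:

```bash
python analysis/01_simulate.py       # synthetic log + truth sidecar
python analysis/02_categorize.py     # frequencies, overlap matrix, heat map
python analysis/03_mine_keywords.py  # candidate keywords at threshold 10
python analysis/04_validate.py       # simulated raters, histograms, alpha
```

A thin CLI mirrors the ends of the pipeline: `ibd-dialog synth`,
`ibd-dialog categorize`, `ibd-dialog evaluate` (see `--help`).

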