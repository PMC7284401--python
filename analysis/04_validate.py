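"""Validate algorithm labels against simulated human raters.

Three synthetic raters re-label 100 random categorized lines each: a rater
starts from the planted truth and, with small probabilities, drops one
category or adds a spurious one (imperfect humans over a perfect truth).
The driver reports the over/under-classification histograms, the fraction of
lines with minor or no differences, and Krippendorff's alpha among the three
raters. It also re-runs the severity arithmetic on the published-style
histogram (71/29/5/3/1 over, 47/5/1 under, n=300) as a fixed reference.
"""

import csv
import json
from pathlib import Path

import numpy as np

from ibd_dialog.agreement import (
    RaterSheet,
    compare_line,
    krippendorff_alpha,
    summarize,
    summary_from_histograms,
)
from ibd_dialog.labels import parse_code
from ibd_dialog.lexicon import load_lexicon

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 424
N_LINES_PER_RATER = 100
P_DROP, P_ADD = 0.08, 0.12  # rater deviates from truth per line


def simulate_rater(rater_id, ids, algo_labels, lexicon, rng):
    codes = {}
    usable = [c for c in lexicon.non_fallback_codes]
    for uid in ids:
        labels = set(algo_labels[uid])
        if len(labels) > 1 and rng.random() < P_DROP:
            labels.discard(sorted(labels)[int(rng.integers(len(labels)))])
        if lexicon.fallback_code not in labels and rng.random() < P_ADD:
            labels.add(usable[int(rng.integers(len(usable)))])
        codes[uid] = frozenset(labels)
    return RaterSheet(rater_id, codes)


def main() -> None:
    lexicon = load_lexicon()
    rng = np.random.default_rng(SEED)
    with (ROOT / "scratch" / "algorithm_labels.csv").open(encoding="utf-8") as fh:
        algo = {
            row["line_identifier"]: parse_code(row["code_string"], lexicon)
            for row in csv.DictReader(fh)
        }
    ids = sorted(algo)
    sample = [ids[i] for i in rng.choice(len(ids), size=N_LINES_PER_RATER, replace=False)]
    sheets = [
        simulate_rater(f"rater{j + 1}", sample, algo, lexicon, rng) for j in range(3)
    ]

    comparisons = [
        compare_line(algo[uid], sheet.codes[uid]) for sheet in sheets for uid in sample
    ]
    alpha = krippendorff_alpha(sheets, sample)
    summary = summarize(comparisons, alpha=alpha)

    ks = sorted(set(summary.over_histogram) | set(summary.under_histogram))
    with (RESULTS / "difference_histograms.csv").open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["k", "over_count", "under_count"])
        for k in ks:
            writer.writerow(
                [k, summary.over_histogram.get(k, 0), summary.under_histogram.get(k, 0)]
            )
    metrics = {
        "n_lines": summary.n_lines,
        "minor_or_none_fraction": round(summary.minor_or_none_fraction, 4),
        "alpha_between_raters": round(alpha, 4),
        "total_difference_instances": summary.total_difference_instances,
    }
    (RESULTS / "agreement_metrics.json").write_text(
        json.dumps(metrics, indent=2) + "\n", encoding="utf-8"
    )
    print("simulated-rater validation:", json.dumps(metrics))

    reference = summary_from_histograms(
        over_histogram={1: 71, 2: 29, 3: 5, 4: 3, 5: 1},
        under_histogram={1: 47, 2: 5, 3: 1, 4: 0, 5: 0},
        n_lines=300,
    )
    print(
        "reference histogram arithmetic: "
        f"minor-or-none {reference.minor_or_none_fraction:.1%} "
        f"({round(reference.minor_or_none_fraction * 300)}/300), "
        f"{reference.total_difference_instances} difference instances"
    )


if __name__ == "__main__":
    main()
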