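"""Run the categorization pipeline on the simulated log.

Parses and anonymizes the log written by 01_simulate.py, keeps patient->HCP
lines, excludes greeting-only and automated lines, assigns label sets, and
writes the per-category frequency table, the pairwise overlap matrix, and a
rendered heat map under results/. Also verifies the planted truth is
recovered exactly (the corpus is noise-free by construction).
"""

import csv
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import seaborn as sns

from ibd_dialog.categorizer import categorize_corpus, frequency_report, overlap_matrix
from ibd_dialog.dialog_io import anonymize, parse_log, select_patient_messages
from ibd_dialog.labels import label_code
from ibd_dialog.lexicon import load_lexicon
from ibd_dialog.synthetic import read_truth_sidecar
from ibd_dialog.text_prep import apply_exclusions

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
LOG = ROOT / "scratch" / "synthetic" / "messages.csv"


def main() -> None:
    lexicon = load_lexicon()
    records = anonymize(parse_log(LOG))
    patient = select_patient_messages(records)
    kept, excluded, _ = apply_exclusions(patient)
    print(f"{len(records)} lines parsed; {len(patient)} patient->HCP")
    print(f"{excluded} lines excluded (greeting/automated); {len(kept)} left for categorization")

    labels = categorize_corpus(kept, lexicon)
    truth = {
        i: ls for i, ls in read_truth_sidecar(LOG.with_suffix(".csv.labels.csv")).items() if ls
    }
    recovered = sum(1 for i, ls in labels.items() if truth.get(i) == ls)
    print(f"planted label sets recovered: {recovered}/{len(labels)}")

    with (ROOT / "scratch" / "algorithm_labels.csv").open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["line_identifier", "code_string"])
        for identifier, ls in labels.items():
            writer.writerow([identifier, label_code(ls)])

    report = frequency_report(labels, lexicon)
    frame = report.to_frame(lexicon)
    frame.to_csv(RESULTS / "category_frequencies.csv", index=False)
    print("\nCategory frequencies (percent of", report.denominator, "lines; overlap",
          "means they sum past 100):")
    print(frame.to_string(index=False))

    matrix = overlap_matrix(labels, lexicon)
    named = matrix.copy()
    named.index = named.columns = [lexicon.name_of(c) for c in matrix.index]
    named.to_csv(RESULTS / "overlap_matrix.csv")

    fig, ax = plt.subplots(figsize=(7, 6))
    sns.heatmap(named, annot=True, fmt="d", cmap="viridis", square=True, ax=ax)
    ax.set_title("Pairwise category overlap (diagonal = solo counts)")
    fig.tight_layout()
    fig.savefig(RESULTS / "overlap_heatmap.png", dpi=150)
    print(f"\nwrote tables and heat map under {RESULTS}")


if __name__ == "__main__":
    main()
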