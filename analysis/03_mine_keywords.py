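"""Mine candidate keywords from a labeled sample with the frequency rule.

Takes the first 400 labeled lines of the simulated corpus (the same size
sample a human reviewer would read to seed a lexicon), sums term frequencies
per truth category, and proposes every term reaching 10 occurrences. On a
corpus built from the lexicon itself the proposals should rediscover the
planted unigram keywords — a closed-loop check of the mining rule.
"""

from pathlib import Path

import pandas as pd

from ibd_dialog.lexicon import load_lexicon, mine_keywords
from ibd_dialog.synthetic import read_truth_sidecar
from ibd_dialog.dialog_io import parse_log
from ibd_dialog.text_prep import tokenize

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
LOG = ROOT / "scratch" / "synthetic" / "messages.csv"
SAMPLE_SIZE = 400
THRESHOLD = 10


def main() -> None:
    lexicon = load_lexicon()
    truth = read_truth_sidecar(LOG.with_suffix(".csv.labels.csv"))
    labeled = [
        (tokenize(rec.content, source_identifier=rec.identifier), truth[rec.identifier])
        for rec in parse_log(LOG)
        if truth[rec.identifier]
    ][:SAMPLE_SIZE]
    proposals = mine_keywords(labeled, threshold=THRESHOLD)

    rows = []
    for code, candidates in proposals.items():
        planted = {
            kw for kw in lexicon.by_code(code).keywords if " " not in kw
        }
        for token, freq in candidates:
            rows.append(
                {
                    "code": code,
                    "category": lexicon.name_of(code),
                    "token": token,
                    "frequency": freq,
                    "is_planted_keyword": token in planted,
                }
            )
    frame = pd.DataFrame(rows)
    frame.to_csv(RESULTS / "keyword_candidates.csv", index=False)
    n_planted = int(frame["is_planted_keyword"].sum())
    print(f"{len(frame)} candidate keywords proposed from {len(labeled)} labeled lines "
          f"(threshold {THRESHOLD}); {n_planted} are planted lexicon unigrams, "
          f"{len(frame) - n_planted} are filler noise that cleared the threshold")
    print(frame.groupby("category", sort=False).head(3).to_string(index=False))


if __name__ == "__main__":
    main()
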