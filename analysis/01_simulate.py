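"""Generate the working synthetic message corpus.

Writes a 10-field message log plus its planted-truth sidecar under
scratch/synthetic/ (regenerable; kept out of version control). The generator's defaults emulate the study conditions:
8 categories with base weights proportional to the final published category
counts, pairwise category overlap concentrated on symptoms-medications and
symptoms-communications, and greeting/automated fractions reproducing the
published overall exclusion rate.
"""

from pathlib import Path

from ibd_dialog.lexicon import load_lexicon
from ibd_dialog.synthetic import SyntheticSpec, generate_corpus, write_log

SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "synthetic"
SEED = 20180101
N_LINES = 8324  # the size of the patient->HCP side of the study log


def main() -> None:
    lexicon = load_lexicon()
    spec = SyntheticSpec(n_lines=N_LINES, n_patients=424, seed=SEED)
    corpus = generate_corpus(spec, lexicon)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    log = SCRATCH / "messages.csv"
    n = write_log(corpus, log)

    planted_excluded = sum(1 for ls in corpus.truth_labels.values() if not ls)
    multi = sum(1 for ls in corpus.truth_labels.values() if len(ls) > 1)
    print(f"wrote {n} records to {log}")
    print(f"  planted greeting/automated lines: {planted_excluded}")
    print(f"  labeled lines: {n - planted_excluded} ({multi} with overlapping categories)")


if __name__ == "__main__":
    main()
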