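#!/usr/bin/env python
"""Score the simulated scan pair from disk and evaluate against truth.

Re-reads the GPR pair emitted by 02_simulate_assay.py (running it first
if needed), applies the SNR/Calling-Score pipeline at the published
thresholds (SNR(-) >= 3, score >= 2.5), and compares the called set
with the latent ground truth.  Writes the called candidates to
results/simulated_candidates.tsv and the confusion matrix to
results/simulated_evaluation.tsv.
"""

import runpy
from pathlib import Path

from glycocall import (
    Condition,
    GroundTruth,
    evaluate_calls,
    read_gpr,
    score_pair,
    write_report,
)

ROOT = Path(__file__).resolve().parents[1]
ASSAY = ROOT / "scratch" / "simulated_assay"


def main() -> None:
    if not (ASSAY / "minus_competitor.gpr").exists():
        runpy.run_path(str(ROOT / "analysis" / "02_simulate_assay.py"),
                       run_name="__main__")

    minus = read_gpr(ASSAY / "minus_competitor.gpr",
                     condition=Condition.MINUS_COMPETITOR)
    plus = read_gpr(ASSAY / "plus_competitor.gpr",
                    condition=Condition.PLUS_COMPETITOR,
                    competitor_name="chitin hydrolysate")
    truth = GroundTruth.read_tsv(ASSAY / "truth.tsv")

    scores = score_pair(minus, plus)
    evaluation = evaluate_calls(scores.results, truth)

    out_dir = ROOT / "results"
    out_dir.mkdir(exist_ok=True)
    candidates = scores.candidates()
    write_report(candidates, out_dir / "simulated_candidates.tsv",
                 evaluation=evaluation)

    prec = ("NA" if evaluation.precision is None
            else f"{evaluation.precision:.4f}")
    ev_lines = [
        "metric\tvalue",
        f"n_scored\t{len(scores)}",
        f"n_candidates\t{len(candidates)}",
        f"TP\t{evaluation.n_true_positive}",
        f"FP\t{evaluation.n_false_positive}",
        f"FN\t{evaluation.n_false_negative}",
        f"TN\t{evaluation.n_true_negative}",
        f"precision\t{prec}",
        f"recall\t{evaluation.recall:.4f}",
    ]
    (out_dir / "simulated_evaluation.tsv").write_text(
        "\n".join(ev_lines) + "\n", encoding="utf-8"
    )

    print(f"scored {len(scores)} proteins, called {len(candidates)} candidates")
    print(f"TP={evaluation.n_true_positive} FP={evaluation.n_false_positive} "
          f"FN={evaluation.n_false_negative} TN={evaluation.n_true_negative} "
          f"precision={prec} recall={evaluation.recall:.4f}")
    print(f"wrote {out_dir / 'simulated_candidates.tsv'}")
    print(f"wrote {out_dir / 'simulated_evaluation.tsv'}")


if __name__ == "__main__":
    main()
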