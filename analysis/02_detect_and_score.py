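"""Simulate EMG, detect conditioned responses, and build learning series.

Re-simulates the cohort's per-trial EMG deterministically from the seed
(traces are regenerated rather than stored), runs the multi-criterion CR/UR
detector over every trial, and aggregates CR calls into blockwise
percentages: 6 Week-1 blocks + 3 Week-2 blocks of 10 trials each.

Outputs (under --outdir):
    trial_results.csv     per-trial CR/UR calls with rejection reasons
    learning_series.csv   subjects x 9-block CR% matrix
"""

import argparse
from pathlib import Path

import pandas as pd

from blinkcr.detect import classify_session, results_to_frame
from blinkcr.score import assemble_learning_matrix
from blinkcr.synthdata import sample_cohort, simulate_study


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n", type=int, default=54)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cohort = sample_cohort(n=args.n, seed=args.seed)
    study = simulate_study(cohort, seed=args.seed)

    frames, by_subject = [], {}
    for (sid, week), traces in study.traces.items():
        sched = study.schedules[(sid, week)]
        res = classify_session(traces, list(sched.trials))
        by_subject.setdefault(sid, {})[week] = [r for r in res if r.trial.has_cs]
        frames.append(results_to_frame(res, subject_id=sid, week=int(week)))
    trials = pd.concat(frames, ignore_index=True)
    trials.to_csv(args.outdir / "trial_results.csv", index=False)

    learning, excluded = assemble_learning_matrix(by_subject)
    learning.to_csv(args.outdir / "learning_series.csv")

    n_cr = int(trials["cr_present"].sum())
    planted = int(study.truth["cr_draw"].sum())
    print(f"scored {len(trials)} trials from {len(by_subject)} subjects")
    print(f"  CRs detected: {n_cr} (planted: {planted})")
    print(f"  subjects excluded: {len(excluded)}")
    print("  mean CR% per Week-1 block:",
          learning[[f'w1b{i}' for i in range(1, 7)]].mean().round(1).tolist())
    print("  mean CR% per Week-2 block:",
          learning[[f'w2b{i}' for i in range(1, 4)]].mean().round(1).tolist())


if __name__ == "__main__":
    main()
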