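"""Simulate the study cohort and conditioning schedules.

Draws a 54-veteran synthetic cohort with the published four-group structure
(PTSD x mTBI: 8/21/12/13) and questionnaire score distributions, assigns
latent learning profiles, and writes the cohort table plus one example
Week-1/Week-2 schedule pair.

Outputs (under --outdir):
    cohort.csv                 one row per subject, item-level responses
    schedule_s000_week1.csv    example Week-1 schedule (3 US-alone + 60 trials)
    schedule_s000_week2.csv    example Week-2 schedule (30 trials)
"""

import argparse
from collections import Counter
from pathlib import Path

from blinkcr.protocol import Week, generate_schedule, write_schedule_csv
from blinkcr.synthdata import cohort_to_frame, sample_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n", type=int, default=54)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cohort = sample_cohort(n=args.n, seed=args.seed)
    cohort_to_frame(cohort).to_csv(args.outdir / "cohort.csv", index=False)

    groups = Counter((s.ptsd_group, s.mtbi_group) for s in cohort)
    profiles = Counter(s.latent_profile.value for s in cohort)
    print(f"cohort: n={len(cohort)} seed={args.seed}")
    print("  groups (PTSD, mTBI):", dict(groups))
    print("  latent profiles:", dict(profiles))

    for week, tag in ((Week.WEEK1, "week1"), (Week.WEEK2, "week2")):
        sched = generate_schedule(week, seed=args.seed)
        write_schedule_csv(sched, args.outdir / f"schedule_s000_{tag}.csv")
        print(f"  {tag}: {len(sched.trials)} trials, counts {dict(sched.counts())}")


if __name__ == "__main__":
    main()
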