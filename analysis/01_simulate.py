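#!/usr/bin/env python
"""Simulate both escape-learning paradigms and write the canonical tables.

Builds a cohort of TD agents for the static paradigm (3 instrumental +
3 yoked Pavlovian sessions of 20 trials, 80/20 and 60/40 contingencies)
and one for the dynamic paradigm (8 sessions of 24 trials, random-walk
relief probabilities), attaches SCR-like amplitudes generated from the
hybrid-model associability and scheduled pain/relief ratings, and
writes the canonical trial tables plus the ground-truth parameter
table under results/.
"""

from pathlib import Path

from common import load_cfg, make_parser, write_manifest


def main():
    args = make_parser(__doc__).parse_args()
    cfg = load_cfg(args)
    out = Path(args.out)

    import csv

    from relieflearn.io import write_trial_table
    from relieflearn.pipeline import (attach_ratings, attach_scr,
                                      simulate_td_cohort)

    tables = {}
    for paradigm in ("exp1", "exp2"):
        cohort = simulate_td_cohort(
            n_subjects=cfg.n_subjects, seed=cfg.seed, paradigm=paradigm)
        attach_scr(cohort, seed=cfg.seed + 1)
        attach_ratings(cohort, seed=cfg.seed + 2)
        records = [t for sid in cohort.subjects for t in cohort.trials[sid]]
        path = out / f"{paradigm}_trials.tsv"
        write_trial_table(records, path)
        tables[paradigm] = (cohort, path)
        print(f"{paradigm}: {cfg.n_subjects} subjects, "
              f"{len(records)} trials -> {path}")

    with open(out / "ground_truth.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["paradigm", "subject", "model", "parameter", "value",
                    "seed"])
        for paradigm, (cohort, _) in tables.items():
            for sid in cohort.subjects:
                gt = cohort.truths[sid]
                for p, v in gt.params.items():
                    w.writerow([paradigm, sid, gt.model, p, repr(v), gt.seed])
    write_manifest(out, "01_simulate", cfg)
    print(f"ground truth -> {out / 'ground_truth.tsv'}")


if __name__ == "__main__":
    main()
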