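#!/usr/bin/env python
"""Fit the candidate choice models to every simulated subject.

Static paradigm: WSLS, TD and the Pearce-Hall action hybrid on the
instrumental sessions.  Dynamic paradigm: TD, action hybrid, HMM and
the hierarchical Gaussian filter.  Writes per-subject posterior-mode
parameters and Laplace free energies (choice_fits.tsv) and the
subjects x models evidence matrices (1 file per paradigm) consumed by
the model-comparison step.
"""

from pathlib import Path

from common import load_cfg, make_parser, write_manifest

EXP1_MODELS = ("wsls", "td", "hybrid_action")


def main():
    args = make_parser(__doc__).parse_args()
    cfg = load_cfg(args)
    out = Path(args.out)

    import pandas as pd

    from relieflearn.fitting import fit_choice_model
    from relieflearn.io import group_by_subject, read_trial_table
    from relieflearn.models import compile_subject

    rows, evid = [], {}
    for paradigm, models in (("exp1", EXP1_MODELS),
                             ("exp2", tuple(cfg.model_set))):
        table = out / f"{paradigm}_trials.tsv"
        if not table.exists():
            raise SystemExit(f"{table} missing - run 01_simulate.py first")
        by_subject = group_by_subject(read_trial_table(table))
        evid[paradigm] = {}
        for sid, trials in sorted(by_subject.items()):
            sd = compile_subject(
                [t for t in trials if t.paradigm != "exp1_pavlovian"])
            for m in models:
                fr = fit_choice_model(m, sd, subject=sid, n_starts=2,
                                      seed=cfg.seed, tol=1e-4)
                evid[paradigm].setdefault(sid, {})[m] = fr.free_energy
                for p, v in fr.native.items():
                    rows.append({"paradigm": paradigm, "subject": sid,
                                 "model": m, "parameter": p, "value": v,
                                 "free_energy": fr.free_energy})
            print(f"{paradigm} {sid}: fitted {len(models)} models")
        pd.DataFrame(evid[paradigm]).T.to_csv(
            out / f"{paradigm}_choice_evidence.tsv", sep="\t")
    pd.DataFrame(rows).to_csv(out / "choice_fits.tsv", sep="\t", index=False)
    write_manifest(out, "02_fit_choices", cfg)

    fits = pd.DataFrame(rows)
    means = fits.groupby(["paradigm", "model", "parameter"])["value"].mean()
    print("\ngroup-mean parameters:")
    print(means.round(3).to_string())


if __name__ == "__main__":
    main()
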