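#!/usr/bin/env python
"""Fit the SCR observation models to trial amplitudes.

For each subject the three observation models (Rescorla-Wagner value,
hybrid value, hybrid associability) predict the within-subject
log-transformed SCR amplitude as g(x) = Predictor + b with per-session
offsets.  The static paradigm is fitted separately for instrumental
and Pavlovian sessions (single recording side); the dynamic paradigm
fits both sides simultaneously as two data sources.  Writes
scr_fits.tsv and per-paradigm evidence matrices.
"""

from pathlib import Path

from common import load_cfg, make_parser, write_manifest


def main():
    args = make_parser(__doc__).parse_args()
    cfg = load_cfg(args)
    out = Path(args.out)

    import pandas as pd

    from relieflearn.fitting import fit_scr
    from relieflearn.io import group_by_subject, read_trial_table

    rows = {}
    for paradigm in ("exp1_instrumental", "exp1_pavlovian", "exp2"):
        table = out / f"{paradigm.split('_')[0]}_trials.tsv"
        if not table.exists():
            raise SystemExit(f"{table} missing - run 01_simulate.py first")
        by_subject = group_by_subject(read_trial_table(table))
        bilateral = paradigm == "exp2"
        evid = {}
        for sid, trials in sorted(by_subject.items()):
            sub = [t for t in trials
                   if paradigm == "exp2" or t.paradigm == paradigm]
            if not any(t.scr_left is not None for t in sub):
                continue
            for m in cfg.scr_model_set:
                fr = fit_scr(
                    m, sub, subject=sid,
                    sources=("left", "right") if bilateral else ("left",),
                    exclusion_source="right" if bilateral else None,
                    sigma_evolution=cfg.prior_sigma_scr_evolution,
                    n_starts=2, seed=cfg.seed,
                    threshold=cfg.scr_amplitude_threshold,
                    max_bad_fraction=cfg.scr_max_bad_fraction)
                evid.setdefault(sid, {})[m] = fr.free_energy
                for p, v in fr.native.items():
                    rows.setdefault(paradigm, []).append(
                        {"paradigm": paradigm, "subject": sid, "model": m,
                         "parameter": p, "value": v,
                         "free_energy": fr.free_energy})
        pd.DataFrame(evid).T.to_csv(out / f"{paradigm}_scr_evidence.tsv",
                                    sep="\t")
        print(f"{paradigm}: fitted {len(evid)} subjects")
    allrows = [r for v in rows.values() for r in v]
    pd.DataFrame(allrows).to_csv(out / "scr_fits.tsv", sep="\t", index=False)
    write_manifest(out, "03_fit_scr", cfg)

    fits = pd.DataFrame(allrows)
    print("\ngroup-mean SCR-fit parameters (cluster near 0.5 by design "
          "of the tight evolution priors):")
    print(fits.groupby(["paradigm", "model", "parameter"])["value"]
          .mean().round(3).to_string())


if __name__ == "__main__":
    main()
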