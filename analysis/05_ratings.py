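#!/usr/bin/env python
"""Which uncertainty signal predicts trial-by-trial pain ratings?

Dynamic paradigm: builds per-subject rating regressions with the
hybrid-model associability, HMM entropy, TD surprise, or no predictor
(null), using group-mean parameters from the choice/SCR fits when
available, and compares them by random-effects BMS.  Static paradigm:
per-subject Spearman correlations of pain ratings with associability
and with the prediction error, tested at the group level on Fisher-z
coefficients; plus mean pain/relief ratings per paradigm with the
instrumental-vs-Pavlovian paired test.  Writes rating_analysis.json.
"""

import json
from pathlib import Path

from common import load_cfg, make_parser, write_manifest


def _group_means(out, paradigm, model, fallback):
    import pandas as pd
    path = out / ("choice_fits.tsv" if model in ("td", "hmm")
                  else "scr_fits.tsv")
    if not path.exists():
        return dict(fallback)
    df = pd.read_csv(path, sep="\t")
    mask = df.paradigm.str.startswith(paradigm)
    name = {"hybrid_state": "hybrid_assoc"}.get(model, model)
    sub = df[mask & (df.model == name)]
    if sub.empty:
        return dict(fallback)
    means = sub.groupby("parameter")["value"].mean().to_dict()
    return {k: means.get(k, v) for k, v in fallback.items()}


def main():
    args = make_parser(__doc__).parse_args()
    cfg = load_cfg(args)
    out = Path(args.out)

    import numpy as np

    from relieflearn.io import group_by_subject, read_trial_table
    from relieflearn.models import run_model
    from relieflearn.pipeline import GROUP_PARAMS, Cohort, exp1_rating_correlations
    from relieflearn.ratings import (build_rating_design,
                                     compare_rating_models,
                                     subject_correlation_stats)
    from relieflearn.task import make_exp1_config

    report = {}

    # ---- dynamic paradigm: predictor model comparison --------------------
    table = out / "exp2_trials.tsv"
    if table.exists():
        by_subject = group_by_subject(read_trial_table(table))
        designs = {p: {} for p in cfg.rating_predictors}
        gm = {m: _group_means(out, "exp2", m, GROUP_PARAMS[m])
              for m in ("hybrid_state", "td", "hmm")}
        print("group-mean parameters for predictor construction:", gm)
        for sid, trials in sorted(by_subject.items()):
            for p in cfg.rating_predictors:
                model = {"associability": "hybrid_state", "entropy": "hmm",
                         "surprise": "td", "none": None}[p]
                traj = (run_model(model, gm[model], trials)
                        if model else None)
                designs[p][sid] = build_rating_design(
                    trials, traj, p, subject=sid,
                    intercept=cfg.rating_intercept_in_fit)
        res, fit_table, excluded = compare_rating_models(
            designs, seed=cfg.seed, n_samples=cfg.bms_n_samples,
            exclude_identical_above=cfg.identical_ratings_exclusion)
        report["exp2_rating_bms"] = res.to_dict()
        report["exp2_excluded"] = excluded
        coefs = fit_table[fit_table.predictor == "associability"]
        if "Predictor" in coefs:
            vals = coefs["Predictor"].to_numpy()
            t = subject_correlation_stats(
                {s: ([v], [0]) for s, v in zip(coefs.subject, vals)},
                test="one_sample_t")
            report["exp2_assoc_coefficient_test"] = t
        best = res.models[int(np.argmax(res.frequencies))]
        print(f"exp2 rating BMS: best={best} "
              f"freq={dict(zip(res.models, res.frequencies.round(3)))}")

    # ---- static paradigm: correlations and mean ratings ------------------
    table = out / "exp1_trials.tsv"
    if table.exists():
        by_subject = group_by_subject(read_trial_table(table))
        cohort = Cohort(config=make_exp1_config(), trials=by_subject,
                        truths={})
        gm1 = _group_means(out, "exp1", "hybrid_state",
                           GROUP_PARAMS["hybrid_state"])
        for stream, label in (("assoc_pre", "associability"), ("pe", "pe")):
            report[f"exp1_pain_vs_{label}"] = exp1_rating_correlations(
                cohort, params=gm1, uncertainty=stream)
            for paradigm, rep in report[f"exp1_pain_vs_{label}"].items():
                print(f"exp1 {label} {paradigm}: mean rho="
                      f"{rep['mean_rho']:.3f} T({rep['df']})="
                      f"{rep['statistic']:.2f} p={rep['p']:.3f}")
        # mean ratings per category and paradigm contrast
        means = {}
        for rtype in ("pain", "relief"):
            pairs = {}
            for sid, trials in by_subject.items():
                ins = [t.rating for t in trials if t.rating_type == rtype
                       and t.paradigm == "exp1_instrumental"
                       and t.rating is not None]
                pav = [t.rating for t in trials if t.rating_type == rtype
                       and t.paradigm == "exp1_pavlovian"
                       and t.rating is not None]
                if ins and pav:
                    pairs[sid] = (ins, pav)
            if len(pairs) >= 2:
                rep = subject_correlation_stats(pairs, test="paired_t")
                means[rtype] = rep
                print(f"exp1 {rtype} instrumental-vs-Pavlovian paired t: "
                      f"T({rep['df']})={rep['statistic']:.2f} p={rep['p']:.3f}")
        report["exp1_rating_contrasts"] = means

    with open(out / "rating_analysis.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    write_manifest(out, "05_ratings", cfg)


if __name__ == "__main__":
    main()
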