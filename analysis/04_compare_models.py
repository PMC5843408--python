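#!/usr/bin/env python
"""Random-effects Bayesian model selection over the fitted evidences.

Reads the evidence matrices written by 02/03 and reports, for each
paradigm and data stream, the model frequencies, exceedance
probabilities, Bayes omnibus risk and protected exceedance
probabilities.  Writes bms_results.json.
"""

import json
from pathlib import Path

from common import load_cfg, make_parser, write_manifest


def main():
    args = make_parser(__doc__).parse_args()
    cfg = load_cfg(args)
    out = Path(args.out)

    import pandas as pd

    from relieflearn.bms import rfx_bms

    results = {}
    for stem in ("exp1_choice", "exp2_choice", "exp1_instrumental_scr",
                 "exp1_pavlovian_scr", "exp2_scr"):
        path = out / f"{stem}_evidence.tsv"
        if not path.exists():
            print(f"skipping {stem}: {path} not found")
            continue
        lme = pd.read_csv(path, sep="\t", index_col=0)
        res = rfx_bms(lme, seed=cfg.seed, n_samples=cfg.bms_n_samples)
        results[stem] = res.to_dict()
        best = res.models[int(res.frequencies.argmax())]
        print(f"{stem}: best={best} "
              f"freq={dict(zip(res.models, res.frequencies.round(3)))} "
              f"xp={dict(zip(res.models, res.exceedance.round(3)))} "
              f"bor={res.bor:.3f}")
    with open(out / "bms_results.json", "w") as fh:
        json.dump(results, fh, indent=2)
    write_manifest(out, "04_compare_models", cfg)


if __name__ == "__main__":
    main()
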