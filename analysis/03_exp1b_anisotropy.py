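"""Vernier paradigm: inward-outward anisotropy of threshold elevation.

Runs the full visual system on the three conditions (unflanked, inner bar,
outer bar) at 3.89 deg for 10 sessions of 20 trials, writes the trial table
and per-session elevations, and reports the session-wise sign test of
E_outer > E_inner.
"""

from pathlib import Path

import numpy as np
from scipy.stats import binomtest

import crowdsim

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed=1):
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = crowdsim.RunConfig(experiment_id="exp1b", n_trials=20,
                             n_sessions=10, master_seed=seed)
    rep = crowdsim.run_experiment(cfg)
    rep.trials.to_csv(OUT / "exp1b_trials.csv", index=False)
    rep.elevations.to_csv(OUT / "exp1b_elevations.csv", index=False)

    el = rep.elevations
    for fl in ("none", "inner", "outer"):
        sub = el[el.flanker == fl].E
        print(f"E_{fl:6s} = {sub.mean():.3f}  (sd over sessions {sub.std():.3f})")
    diff = rep.session_difference()
    k = int((diff > 0).sum())
    p = binomtest(k, len(diff), 0.5, alternative="greater").pvalue
    print(f"\nsessions with E_outer > E_inner: {k}/{len(diff)} "
          f"(sign test p = {p:.4f})")
    tr = rep.trials
    print("segmentation success:",
          {fl: round(tr[tr.flanker == fl].success.mean(), 2)
           for fl in ("none", "inner", "outer")})
    print("\nAn outer bar crowds the Vernier more than an inner bar: the "
          "inner bar is magnified onto more cortical tissue, farther from "
          "the target, so the selection signal separates it more reliably.")


if __name__ == "__main__":
    main()
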