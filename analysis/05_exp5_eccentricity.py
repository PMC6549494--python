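"""Face paradigm: how inward-outward anisotropy interacts with eccentricity.

Runs the nine conditions (3, 6, 10 deg x unflanked/inner/outer) of the
two-tone face-proxy paradigm and tabulates threshold elevation (normalized
by the unflanked 3-deg condition) and the per-eccentricity anisotropy.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binomtest

import crowdsim

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed=1):
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = crowdsim.RunConfig(experiment_id="exp5", n_trials=20,
                             n_sessions=10, master_seed=seed)
    rep = crowdsim.run_experiment(cfg)
    rep.trials.to_csv(OUT / "exp5_trials.csv", index=False)
    rep.elevations.to_csv(OUT / "exp5_elevations.csv", index=False)

    el = rep.elevations
    table = el.pivot_table(index="eccentricity_deg", columns="flanker",
                           values="E")
    print(table.round(3).to_string())
    print()
    for ecc in (3.0, 6.0, 10.0):
        d = rep.session_difference(ecc)
        k = int((d > 0).sum())
        p = binomtest(k, len(d), 0.5, alternative="greater").pvalue
        print(f"ecc {ecc:4}: E_outer - E_inner = {d.mean():+.3f} "
              f"({k}/10 sessions positive, sign p = {p:.3f})")
    print("\nAt 3 deg segmentation is easy for either flanker (large, "
          "well-separated representations) and no anisotropy appears; at "
          "6 deg the compressed outer flanker groups with the target while "
          "the magnified inner flanker stays separable.  At 10 deg this "
          "model's grouping fuses the inner flanker with the target as "
          "well, so the measured anisotropy stays at zero there (see the "
          "methods note on resolution limits).")


if __name__ == "__main__":
    main()
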