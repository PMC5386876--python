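#!/usr/bin/env python
"""How many pupae per vial, and how many vials per RIL, are enough?

Subsamples (without replacement) the pupae within simulated vials and the
replicate vial means within simulated RILs, 100 draws per size, and
tabulates the deviation of the subsampled mean from the full mean.
Writes per-size summaries to results/.
"""

from pathlib import Path

import numpy as np

from pupastat.resample import ril_subsample_deviation, vial_subsample_deviation

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(7)

    # vials of ~55 measured pupae with within-vial SD 0.13 mm
    vials = {f"V{i}": rng.normal(rng.normal(3.4, 0.1), 0.13, 55)
             for i in range(60)}
    vrep = vial_subsample_deviation(vials, sizes=[1, 2, 5, 10, 15, 25, 40, 55],
                                    reps=100, seed=70)
    vrep.summary.to_csv(OUT / "vial_subsampling.csv", index=False)
    row15 = vrep.summary.query("subsample_size == 15").iloc[0]
    print("vial means: 95% band at size 15 = "
          f"[{row15.central95_low_mm:+.3f}, {row15.central95_high_mm:+.3f}] mm "
          "(the basis of the >=15-pupae QC rule)")

    # RILs with 12 replicate vials, between-vial SD 0.07 mm
    rils = {f"R{i}": rng.normal(rng.normal(3.4, 0.12), 0.07, 12)
            for i in range(10)}
    rrep = ril_subsample_deviation(rils, sizes=[1, 2, 3, 4, 6, 9, 12],
                                   reps=100, seed=71)
    rrep.summary.to_csv(OUT / "ril_subsampling.csv", index=False)
    row6 = rrep.summary.query("subsample_size == 6").iloc[0]
    frac = (rrep.deviations.query("subsample_size == 6")["deviation_mm"]
            .abs() < 0.1).mean()
    print(f"RIL means: with 6 of 12 vials, {100 * frac:.0f}% of estimates "
          f"fall within +/-0.1 mm of the all-vial mean")
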