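"""Phantom study: does the jet-angle pipeline recover a known tilt?

Sweeps ground-truth tilt angles and velocity-noise levels over tube
phantoms, measures each through the full landmark -> axis -> jet path,
and writes the recovery table.  Noise-free plug flow is recovered to
machine precision; at a clinically plausible 5 cm/s component noise the
error stays well under a degree.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from aortaflow.pipeline import measure_phantom_angle
from aortaflow.synthetic import PhantomConfig, generate_phantom

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    rng = np.random.default_rng(SEED)
    rows = []
    for tilt in (0.0, 5.0, 10.01, 17.54, 30.0):
        for noise in (0.0, 2.0, 5.0, 10.0):
            reps = 1 if noise == 0 else 25
            errs = []
            for _ in range(reps):
                ds = generate_phantom(
                    PhantomConfig(tilt_deg=tilt, azimuth_deg=40.0,
                                  noise_sd=noise), rng=rng)
                errs.append(measure_phantom_angle(ds)["angle_deg"] - tilt)
            rows.append({"tilt_deg": tilt, "noise_sd_cms": noise,
                         "n_reps": reps,
                         "mean_abs_error_deg": float(np.mean(np.abs(errs))),
                         "max_abs_error_deg": float(np.max(np.abs(errs)))})
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "phantom_recovery.csv", index=False)

    clean = table[table["noise_sd_cms"] == 0]["max_abs_error_deg"].max()
    noisy = table[table["noise_sd_cms"] == 5.0]["mean_abs_error_deg"].max()
    print(f"noise-free recovery: worst |error| = {clean:.2e} deg")
    print(f"at 5 cm/s noise:     worst mean |error| = {noisy:.3f} deg")
    print(f"table -> {OUT / 'phantom_recovery.csv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
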