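#!/usr/bin/env python
"""Live-cell relative allele motion: MSD curve and the single-allele
diffusion coefficient from an origin-constrained linear fit."""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import DATA, outdir, study_config

from chromaburst import dynamics, tracing_io as tio


def main() -> None:
    out = outdir("dynamics")
    trajs = tio.read_allele_trajectories(DATA / "allele_tracks.tsv")
    rel = dynamics.relative_positions(trajs)
    curve = dynamics.msd(rel, max_lag=3000.0, seed=0)
    d_fit = dynamics.fit_diffusion(curve, n_dims=2, relative=True)

    pd.DataFrame(
        {
            "lag_s": curve.lags,
            "msd_um2": curve.msd,
            "ci95_lo": curve.ci95[0],
            "ci95_hi": curve.ci95[1],
            "n_obs": curve.n_observations,
        }
    ).to_csv(out / "msd.tsv", sep="\t", index=False)
    with open(out / "diffusion.json", "w") as fh:
        json.dump(
            {
                "diffusion_um2_per_s": d_fit,
                "planted_um2_per_s": study_config().diffusion_coeff,
                "n_relative_tracks": len(rel),
            },
            fh,
            indent=1,
        )
    print(f"fitted single-allele D = {d_fit:.3e} um^2/s "
          f"(planted {study_config().diffusion_coeff:.3e})")
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
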