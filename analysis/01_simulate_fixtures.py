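#!/usr/bin/env python
"""Generate the synthetic study bundles all downstream analyses consume.

Two cryo-ET-style contour conditions (capped ends with short flares vs
uncapped ends with long flares), single-molecule spot fields for the
monomer / dimer / tip-count ladder, and kymograph trace tables for a
control and a slow-growth regime.  Everything is seeded and goes to
results/data/ together with truth.json files.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import tifffile

from tipshape.io import write_contour_table, write_kymo_table
from tipshape.kymo_dynamics import Calibration
from tipshape.synthetic import (EventGroundTruth, FlareGroundTruth,
                                SpotFieldGroundTruth, gen_event_series,
                                gen_flared_ends, gen_spot_field,
                                histories_to_segments)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    # --- contours: capped ends flare short, uncapped flare long -----------
    capped = gen_flared_ends(FlareGroundTruth(flare_arc_length=15.0,
                                              noise_sigma=1.0,
                                              seed=args.seed), 25, grid_id="g0")
    for e in capped:
        e.cap_state = "full"
        e.mt_id = "cap_" + e.mt_id
    uncapped = gen_flared_ends(FlareGroundTruth(flare_arc_length=45.0,
                                                noise_sigma=1.0,
                                                seed=args.seed + 1), 25,
                               grid_id="g1")
    for e in uncapped:
        e.mt_id = "free_" + e.mt_id
    write_contour_table(capped + uncapped, out / "contours.csv")
    (out / "contours_truth.json").write_text(json.dumps(
        {"capped": {"flare_arc_length_nm": 15.0, "n_ends": 25},
         "uncapped": {"flare_arc_length_nm": 45.0, "n_ends": 25},
         "radius_nm": 25.0, "noise_sigma_nm": 1.0, "seed": args.seed},
        indent=2))

    # --- spot fields: monomer, dimer, six-molecule tips --------------------
    for name, n_mol in (("monomer", 1), ("dimer", 2), ("tip6", 6)):
        truth = SpotFieldGroundTruth(molecules_per_spot=np.full(150, n_mol),
                                     seed=args.seed + 10 * n_mol)
        frame = gen_spot_field(truth, shape=(384, 384))
        tifffile.imwrite(out / f"spots_{name}.tiff",
                         frame.pixels.astype(np.float32))
        (out / f"spots_{name}_truth.json").write_text(json.dumps(
            {"molecules_per_spot": n_mol, "n_spots": 150, "mu": truth.mu,
             "sigma_log": truth.sigma_log, "seed": truth.seed}, indent=2))

    # --- kymographs: control vs slow-growth regime -------------------------
    calib = Calibration()
    control = EventGroundTruth(growth_rate_mean=2.0, growth_rate_sd=0.4,
                               catastrophe_rate=0.2,
                               pause_entry_rate=0.2, seed=args.seed + 100)
    slow = EventGroundTruth(growth_rate_mean=0.075, growth_rate_sd=0.01,
                            catastrophe_rate=0.02, pause_entry_rate=0.0,
                            seed=args.seed + 101)
    for name, truth, n in (("control", control, 150), ("slow", slow, 150)):
        hist = gen_event_series(truth, n)
        write_kymo_table(histories_to_segments(hist, calib),
                         out / f"kymo_{name}.csv")
        (out / f"kymo_{name}_truth.json").write_text(json.dumps(
            {"growth_rate_mean": truth.growth_rate_mean,
             "catastrophe_rate": truth.catastrophe_rate,
             "pause_entry_rate": truth.pause_entry_rate,
             "n_mts": n, "seed": truth.seed}, indent=2))

    print(f"wrote fixture bundles to {out}/ "
          f"(50 MT ends, 3 spot fields, 2 kymograph conditions)")


if __name__ == "__main__":
    main()
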