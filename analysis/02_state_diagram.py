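#!/usr/bin/env python
"""Morphology state diagram over block solvophobicities (aES, aFS).

Sweeps the E–solvent and F–solvent repulsion amplitudes at fp = 0.10 and
labels the final frame of each run.  At published scale the sweep covers
aES in [26, 97.9] and aFS in [26, 125] in a 40 rc box for 5e5 steps per
point (days of CPU); the default desk scale uses a coarse grid in a small
box and recovers the qualitative corners: dissolved chains at low/low,
aggregates with increasing enclosure toward high/high.

Writes results/state_diagram.tsv (a_ES, a_FS, label, n_aggregates, ...).
"""

import argparse
from pathlib import Path

from stardpd import experiments


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--scale", choices=["paper", "desk"], default="desk")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = experiments.PRESETS[f"state_diagram_{args.scale}"]
    if args.scale == "paper":
        a_es = [26.0, 38.0, 50.0, 62.0, 74.0, 86.0, 97.9]
        a_fs = [26.0, 51.0, 76.0, 101.0, 111.0, 126.0]
    else:
        a_es = [26.0, 62.0, 97.9]
        a_fs = [26.0, 76.0, 125.0]

    print(f"{args.scale}-scale sweep: {len(a_es)}x{len(a_fs)} grid, "
          f"L={cfg.box_length}, {cfg.steps} steps/point")
    df = experiments.run_state_diagram(a_es, a_fs, cfg, seed=args.seed,
                                       out_dir=args.out, progress=True)
    print(df.pivot(index="a_FS", columns="a_ES", values="label").to_string())
    print(f"wrote {args.out / 'state_diagram.tsv'}")


if __name__ == "__main__":
    main()
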