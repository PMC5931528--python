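#!/usr/bin/env python
"""Generate the synthetic study the downstream analyses run on.

Writes TDR, GPS, isotope, prey and bird tables under results/data/. The
default cohort is scaled to 8 birds per stage so the whole analysis
chain runs in a couple of minutes; pass --full for the 25-per-stage
study design.
"""

import argparse
from pathlib import Path

from penguinforage import synthetic as syn


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--full", action="store_true", help="25 birds per stage")
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    truth = syn.default_truth(seed=args.seed)
    if not args.full:
        truth.n_birds_per_stage = 8
        truth.isotope_n_per_stage = 6
        truth.gps_birds = {"incubation": 2, "chick-rearing": 3}
        truth.class_params["krill"].n_birds = 10
        truth.class_params["fish"].n_birds = 2
    study = syn.generate_population(truth)
    paths = syn.write_study(study, args.out)
    n_samples = sum(s.depth.size for s in study.tdr.values())
    print(f"study: {len(study.birds)} birds, {n_samples:,} depth samples, "
          f"{len(study.isotopes)} plasma samples, {len(study.prey)} prey samples")
    for k, v in paths.items():
        print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
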