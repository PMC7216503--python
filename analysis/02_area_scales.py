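#!/usr/bin/env python
"""Build the three area contextual scales and their lowest-quartile flags.

Reads the scale sample written by 01_simulate.py (all ever-married women
15-49), computes the weighted gendered-context, environmental-development
and health-system scales per area, dichotomizes each at the lowest
quartile, and reports how concentrated the flagged areas are.
"""

import argparse
from pathlib import Path

import pandas as pd

from parityineq.area_scales import build_area_scales


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    records = pd.read_csv(args.data / "scale_sample.csv")
    tbl = build_area_scales(records, weighted=True)
    args.out.mkdir(parents=True, exist_ok=True)
    tbl.to_csv(args.out / "area_scales.csv")

    print(f"{len(tbl)} areas; scale ranges:")
    for c in ("gendered_scale", "env_scale", "health_scale"):
        print(f"  {c}: {tbl[c].min():.3f} - {tbl[c].max():.3f} "
              f"({int(tbl[c.replace('_scale', '_lowq')].sum())} areas "
              "in the lowest quartile)")
    print(f"wrote {args.out / 'area_scales.csv'}")


if __name__ == "__main__":
    main()
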