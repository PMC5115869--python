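"""Render summary figures from a completed run directory.

Produces the binding curve, dwell histograms with mixture overlays, the
per-molecule contour plot, the delta-AIC bar chart and the resimulation KS
overview as PNGs inside the run directory.

Usage: python analysis/05_figures.py [--out results/run]
"""

import argparse
import sys

from zmwbind.pipeline import make_figures


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results/run")
    args = ap.parse_args(argv)
    made = make_figures(args.out)
    for p in made:
        print(f"wrote {p}")


if __name__ == "__main__":
    sys.exit(main())
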