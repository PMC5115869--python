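"""Idealize the cohort and apply the quality gates.

Reads the traces written by 01_simulate_cohort.py, counts acceptor bleach
steps in I_AA (single step required), subtracts 10 % donor cross-talk and
the post-bleach baseline from I_AD, idealizes the pre-bleach smFRET segment
with a two-level HMM, and rejects molecules with S/N < 2.  Writes
idealizations, the QC table and the gamma fit of the S/N distribution.

Usage: python analysis/02_process_traces.py [--seed 7]
"""

import argparse
import json
import pathlib
import sys

from zmwbind.config import RunConfig
from zmwbind.pipeline import run_pipeline


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", default="results/run")
    args = ap.parse_args(argv)

    cfg = RunConfig(out_dir=args.out, stages=["process"], seed=args.seed)
    out = run_pipeline(cfg)
    man = json.loads((pathlib.Path(out) / "manifest.json").read_text())
    st = man["stages"]["process"]
    print(f"accepted {st['n_accepted']}/{st['n_in']} molecules "
          f"({st['n_rejected']} rejected by bleach/idealization/SNR gates)")


if __name__ == "__main__":
    sys.exit(main())
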