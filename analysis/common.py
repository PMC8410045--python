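"""Shared plumbing for the numbered analysis drivers: argument parsing and
the results directory layout.  Each driver reads the files earlier drivers
wrote, so the sequence 01..07 can be rerun from any stage."""

import argparse
from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"


def stage_args(description):
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=0, help="master seed for the run")
    ap.add_argument("--results", type=Path, default=RESULTS,
                    help="directory shared by all analysis stages")
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)
    return args
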