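"""Shared argument handling for the numbered analysis drivers."""

import argparse

from craniomod.pipeline import AnalysisConfig


def parse_config(description: str) -> AnalysisConfig:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1, help="master seed (default 1)")
    ap.add_argument("--out", default="results", help="output directory")
    ap.add_argument("--permutations", type=int, default=1000)
    args = ap.parse_args()
    return AnalysisConfig(
        out_dir=args.out, seed=args.seed, n_permutations=args.permutations
    )
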