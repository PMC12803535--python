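"""Shape-map covariation per region: two-block partial least squares.

For each region, the specimens-by-cells %BR block is paired with the
Procrustes shape block; the SVD of their cross-covariance yields singular
warps.  Permuting specimens in one block gives each pair's p-value.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import parse_config

from craniomod.pipeline import run_pipeline


def main() -> None:
    cfg = parse_config(__doc__)
    bundle = run_pipeline(cfg, until="pls")
    print("first singular-warp pair per region:")
    print(f"  {'region':18s} {'sing.val':>8s} {'%totcov':>8s} {'corr R':>7s} {'p':>7s}")
    for _, row in bundle["pls_table"].iterrows():
        print(f"  {row['region']:18s} {row['singular_value']:8.3f} "
              f"{row['pct_total_covariance']:8.2f} {row['correlation_R']:7.3f} "
              f"{row['p_value']:7.3f}")


if __name__ == "__main__":
    main()
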