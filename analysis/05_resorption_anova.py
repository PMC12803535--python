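"""Does %BR differ between facial regions?  One-way ANOVA + Tukey HSD.

A single-factor fixed-effects ANOVA of region %BR on facial region
(Type III and sequential sums of squares coincide for one factor),
followed by Tukey-Kramer pairwise comparisons for the unequal group sizes.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import parse_config

from craniomod.pipeline import run_pipeline


def main() -> None:
    cfg = parse_config(__doc__)
    bundle = run_pipeline(cfg, until="stats")
    f, p = bundle["anova"]
    print(f"region ANOVA: F = {f:.2f}, p = {p:.3g}")
    print("\nTukey HSD pairwise comparisons (diff, 95% interval, adjusted p):")
    tukey = bundle["tukey"]
    for _, row in tukey.iterrows():
        star = " *" if row["p_adjusted"] < 0.05 else ""
        print(f"  {row['pair']:38s} {row['diff']:7.2f} "
              f"[{row['lwr']:7.2f}, {row['upr']:7.2f}]  p={row['p_adjusted']:.3g}{star}")


if __name__ == "__main__":
    main()
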