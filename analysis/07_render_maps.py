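"""Render age-group mean bone-modeling maps as colored PLY meshes.

Projects each mean map onto a planar stand-in surface (one 5 mm quad per
grid cell) and writes ASCII PLY files with %BR as vertex color: cold tones
mark high resorption, warm tones formation, gray marks missing cells.
"""

import sys
from dataclasses import replace
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import parse_config

from craniomod.pipeline import run_pipeline


def main() -> None:
    cfg = replace(parse_config(__doc__), render_meshes=True)
    run_pipeline(cfg, until="render")
    n = len(list(Path(cfg.out_dir).glob("mean_map_*.ply")))
    print(f"rendered {n} mean-map meshes to {cfg.out_dir}")


if __name__ == "__main__":
    main()
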