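"""Unmix the simulated delay stacks into eumelanin/pheomelanin maps.

Reads the stacks written by 01_simulate_phantoms.py, applies DC
normalization and the two-delay separation (S_eu = −S(500 fs),
S_ph = S(0) + S(500 fs), negatives clamped to zero), and writes the pigment
maps plus red/cyan composites next to each stack.
"""

from pathlib import Path

import numpy as np

from pumpprobe import io
from pumpprobe.unmixing import unmix_stack

PHANTOMS = Path(__file__).resolve().parents[1] / "results" / "phantoms"


def main() -> None:
    stacks = sorted(PHANTOMS.glob("*/stack.tif"))
    if not stacks:
        raise SystemExit("no stacks found - run analysis/01_simulate_phantoms.py first")
    for stack_path in stacks:
        stack = io.read_stack(stack_path)
        maps = unmix_stack(stack, normalize=True)
        io.write_pigment_maps(maps, stack_path.parent / "pigment_maps.tif")
        io.write_rgb_composite(maps, stack_path.parent / "composite_rgb.tif")
        eu_frac = float(
            maps.eumelanin.sum() / max(maps.eumelanin.sum() + maps.pheomelanin.sum(), 1e-12)
        )
        print(
            f"{stack_path.parent.name}: frames {maps.source_delays_ps} ps, "
            f"eumelanin share of total pigment signal {eu_frac:.2f}, "
            f"peak eu {maps.eumelanin.max():.3f}, peak ph {maps.pheomelanin.max():.3f}"
        )


if __name__ == "__main__":
    main()
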