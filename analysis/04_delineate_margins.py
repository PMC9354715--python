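"""Delineate tumor margins from the pigment maps and score against truth.

Reads the pigment maps from 03_unmix_pigments.py and the ground-truth label
maps from 01, segments the eumelanin-dominated region (smoothed
eumelanin-fraction threshold at 0.5), and reports Dice overlap and boundary
distances per layout in results/margin_metrics.csv.
"""

import json
from pathlib import Path

import pandas as pd

from pumpprobe import io
from pumpprobe.delineation import delineate

PHANTOMS = Path(__file__).resolve().parents[1] / "results" / "phantoms"
PIXEL_SIZE_UM = 212.0 / 256.0  # 256 px over the standard 212 um field


def main() -> None:
    map_files = sorted(PHANTOMS.glob("*/pigment_maps.tif"))
    if not map_files:
        raise SystemExit("no pigment maps found - run analysis/03_unmix_pigments.py first")
    rows = []
    for maps_path in map_files:
        layout = maps_path.parent.name
        maps = io.read_pigment_maps(maps_path)
        phantom = io.read_phantom(maps_path.parent / "phantom.tif")
        result = delineate(maps, PIXEL_SIZE_UM, truth=phantom.truth_tumor_mask)
        io.write_mask(result.tumor_mask, maps_path.parent / "tumor_mask.tif")
        rows.append(
            {
                "layout": layout,
                "dice": result.dice,
                "mean_boundary_distance_um": result.mean_boundary_distance_um,
                "hausdorff_distance_um": result.hausdorff_distance_um,
                "tumor_area_fraction": float(result.tumor_mask.mean()),
            }
        )
        (maps_path.parent / "metrics.json").write_text(json.dumps(rows[-1], indent=2) + "\n")
    df = pd.DataFrame(rows)
    df.to_csv(PHANTOMS.parent / "margin_metrics.csv", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
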