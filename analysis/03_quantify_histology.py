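"""Quantify synthetic histology: stain densities and cortical thickness.

Renders a batch of DAB-style micrographs per group (NF-H axonal fields with
planted area fractions and soma inventories), runs the density chain
(enhance -> 30% threshold -> soma removal -> area fraction), and measures
cortical thickness on synthetic montages with the five-perpendicular-lines
protocol.

Writes: results/analysis/histology_density.csv, cortical_thickness.csv.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "analysis"

from cmscortex.pipeline import run_histology_stage, run_thickness_stage


def main(seed: int = 1):
    OUT.mkdir(parents=True, exist_ok=True)

    dens = run_histology_stage(seed=seed)
    dens.to_csv(OUT / "histology_density.csv", index=False, float_format="%.6g")
    err = (dens.density_pct - dens.truth_pct).abs()
    print(f"density chain on {len(dens)} fields: "
          f"mean |error| {err.mean():.2f} pp, max {err.max():.2f} pp")
    miss = (dens.bodies_detected - dens.bodies_planted).abs()
    print(f"soma detection: planted {dens.bodies_planted.iloc[0]} per field, "
          f"max miscount {int(miss.max())}")

    thick = run_thickness_stage(seed=seed)
    thick.to_csv(OUT / "cortical_thickness.csv", index=False, float_format="%.6g")
    by_roi = thick.groupby("roi").agg(mean_um=("thickness_um", "mean"),
                                      truth_um=("truth_um", "first"))
    by_roi["rel_err_pct"] = 100 * (by_roi.mean_um - by_roi.truth_um).abs() / by_roi.truth_um
    print(by_roi.to_string(float_format=lambda v: f"{v:.1f}"))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
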