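"""Reduced-size validation experiments (quick look).

Runs scaled-down versions of the recovery/calibration experiments so the
whole script finishes in about a minute; the canonical sizes (100-point
hypercube, 200 Rician replicates, 2000 null simulations, 100 cohort runs)
are what scripts/acceptance.py executes.

Writes: results/analysis/validation_quick.json.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "analysis"

from cmscortex.experiments import (
    deff_contrast_power,
    lmm_type1_error,
    monotone_power_check,
    neurite_noiseless_recovery,
    neurite_rician_recovery,
)


def main(seed: int = 1):
    OUT.mkdir(parents=True, exist_ok=True)
    out = {
        "noiseless_recovery": neurite_noiseless_recovery(n_points=20, seed=seed),
        "rician_recovery": neurite_rician_recovery(n_replicates=40, seed=seed),
        "lmm_type1": lmm_type1_error(n_sims=400, seed=seed),
        "deff_power": deff_contrast_power(n_runs=10, seed_base=seed),
        "power_monotonicity": monotone_power_check(seed=seed, n_runs=20),
    }
    (OUT / "validation_quick.json").write_text(json.dumps(out, indent=2))
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
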