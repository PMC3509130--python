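#!/usr/bin/env python
"""Reduced calibration battery for a quick look (the full battery lives in
scripts/acceptance.py).

Runs scaled-down versions of the recovery, null, FDR, deviation and
prediction-interval experiments and writes results/calibration.json.
"""

import json
from pathlib import Path

from mproteo.experiments import (
    run_deviation_experiment,
    run_fdr_calibration,
    run_interval_calibration,
    run_mcl_component_check,
    run_null_calibration,
    run_recovery,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    out = {
        "mcl_component_check": run_mcl_component_check(100, base_seed=1),
        "fdr_calibration": run_fdr_calibration(5, base_seed=1),
        "recovery": run_recovery(5, base_seed=1),
        "null_calibration": run_null_calibration(10, base_seed=1),
        "deviation": run_deviation_experiment(10, base_seed=1),
        "interval_calibration": run_interval_calibration(base_seed=1),
    }
    (OUT / "calibration.json").write_text(json.dumps(out, indent=2) + "\n")
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
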