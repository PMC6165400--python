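#!/usr/bin/env python
"""Extract the 8-features-per-sensor matrix from the simulated dataset.

Reads the raw records written by 01_simulate.py, applies baseline calibration
(V = Vs - V0) and per-sensor feature extraction (Vmax, Vint, and min/max of
the EMA-of-derivative at three smoothing factors), and writes the
samples x 128 feature matrix to results/features.csv.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from enosecp import build_feature_matrix
from enosecp.io import read_dataset, write_feature_matrix

IN = ROOT / "scratch" / "analysis" / "dataset"
OUT = ROOT / "results" / "features.csv"


def main() -> int:
    if not (IN / "manifest.csv").exists():
        print("run analysis/01_simulate.py first", file=sys.stderr)
        return 1
    records = read_dataset(IN)
    fm = build_feature_matrix(records)
    OUT.parent.mkdir(parents=True, exist_ok=True)
    write_feature_matrix(fm, OUT)
    print(f"feature matrix {fm.n_samples} x {fm.n_features} -> {OUT}")
    print(f"first sensor's columns: {fm.feature_names[:8]}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
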