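#!/usr/bin/env python
"""Generate the working synthetic e-nose dataset.

12 herbal-medicine-like categories x 10 samples on a 16-sensor panel at the
scaled record resolution (10 Hz, 34 s, same phase proportions as the full
100 Hz / 340 s protocol).  Raw per-sample CSVs are bulky and therefore go to
scratch/ (regenerate them with this script); the manifest location is printed.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from enosecp import SimulationConfig, make_class_profiles, simulate_dataset
from enosecp.io import write_dataset

SEED = 7
OUT = ROOT / "scratch" / "analysis" / "dataset"


def main() -> int:
    sim = SimulationConfig(samples_per_class=10, seed=SEED)
    profiles = make_class_profiles(12, 16, separation=1.0, seed=SEED,
                                   timescale=sim.timescale)
    records = simulate_dataset(profiles, sim)
    write_dataset(records, OUT)
    print(f"wrote {len(records)} records "
          f"({records[0].n_sensors} sensors x {records[0].n_timepoints} points, "
          f"injection at index {records[0].injection_index}) to {OUT}")
    print("labels are balanced: 12 classes x 10 samples")
    return 0


if __name__ == "__main__":
    sys.exit(main())
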