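#!/usr/bin/env python
"""Simulate the study cohort and extract along-level profiles.

Generates 46 healthy controls and 54 patients at desk scale (24 x 24 x 40
voxels, 0.5 mm isotropic) with the default group effects (WM FA -0.02,
GM FA -0.04), focal lesions in patients, the 15-direction b=750 s/mm^2
acquisition with 3 averages at snr 20, fits diffusion tensors per subject,
and writes the per-(region, sub-level) profile table plus the subject
metadata and ground-truth profiles under results/analysis/.
"""

import time
from pathlib import Path

from cordlevel.phantom import AcquisitionSpec, CohortConfig
from cordlevel.pipeline import run_cohort_in_memory

OUT = Path("results/analysis")
SEED = 20260301


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = CohortConfig(seed=SEED)
    t0 = time.time()
    profiles, records, truth = run_cohort_in_memory(cfg, AcquisitionSpec(),
                                                    fit=True)
    profiles.to_csv(OUT / "profiles.csv", index=False)
    records.to_csv(OUT / "subjects.csv", index=False)
    truth.to_csv(OUT / "truth_profiles.csv", index=False)
    n = len(records)
    print(f"simulated + fitted {n} subjects in {time.time() - t0:.0f} s")
    print(f"profiles: {len(profiles)} rows -> {OUT / 'profiles.csv'}")
    by_group = records.groupby("group").agg(
        n=("id", "size"), age=("age", "mean"), tug_s=("tug_s", "mean"),
        t25_s=("t25_s", "mean"))
    print(by_group.round(2).to_string())


if __name__ == "__main__":
    main()
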