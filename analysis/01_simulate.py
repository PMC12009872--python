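#!/usr/bin/env python
"""Generate the synthetic study cohort as OpenFace-dialect CSVs.

Writes one 5-second, 30-Hz recording per participant (10 TD, 10 ASD-HS,
10 ASD-HS-apraxia; resting task) plus the generating truth table.  The
raw per-frame CSVs are bulky and fully regenerable from the seed, so they
go under scratch/; the truth table is copied into results/ for reference.
"""

from pathlib import Path

from facemms.openface_io import write_table
from facemms.pipeline import save_cohort
from facemms.synthetic_cohort import CohortConfig, generate_cohort

ROOT = Path(__file__).resolve().parents[1]
SEED = 0


def main() -> None:
    config = CohortConfig(
        counts={"TD": 10, "ASD-HS": 10, "ASD-HS-apraxia": 10},
        tasks=("resting",),
        seed=SEED,
    )
    recordings, truth = generate_cohort(config)
    cohort_dir = ROOT / "scratch" / "cohort"
    save_cohort(recordings, truth, cohort_dir)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    write_table(truth, results / "cohort_truth.csv")
    print(f"wrote {len(recordings)} recordings to {cohort_dir} (seed={SEED})")
    print(f"groups: {sorted(set(truth.group))}, {config.n_frames} frames each")


if __name__ == "__main__":
    main()
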