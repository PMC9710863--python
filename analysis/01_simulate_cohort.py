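#!/usr/bin/env python
"""Simulate the study cohort analogue.

Draws a matched cohort of 1-year cancer survivors and cancer-free controls
at the package's default study conditions, applies the eligibility filters,
injects predictor missingness, and writes the cohort table plus the
exclusion accounting and the generating-truth sidecar under results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from oncorisk.cohort import (  # noqa: E402
    SimulationConfig,
    apply_exclusions,
    generate_cohort,
    inject_missingness,
    write_ground_truth,
)
from oncorisk.pipeline import write_cohort  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20221129
N_SETS = 3000


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = SimulationConfig(n_matched_sets=N_SETS, seed=SEED)
    cohort = generate_cohort(cfg).drop(columns=["true_linear_predictor"])
    print(f"generated {len(cohort)} records in {N_SETS} matched sets")

    kept, report = apply_exclusions(cohort)
    print(report.to_frame().to_string(index=False))

    kept = inject_missingness(kept, cfg.missingness_rates, seed=SEED + 1)
    frac = kept[list(cfg.missingness_rates)].isna().mean()
    print("missing fractions after injection:")
    print(frac.round(3).to_string())

    write_cohort(kept, OUT / "cohort.csv")
    write_ground_truth(cfg, OUT / "cohort_ground_truth.yaml")
    print(f"wrote {OUT / 'cohort.csv'} ({len(kept)} records)")


if __name__ == "__main__":
    main()
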