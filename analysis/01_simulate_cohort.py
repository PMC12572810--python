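"""Generate the synthetic study cohort.

Draws 1000 patients whose first-year AF-burden distribution matches the
study targets (zero point-mass ~29.5%, median ~6%, IQR ~0-22%), realises a
per-day SR/AF trajectory for each patient, and attaches post-landmark event
times whose hazard increases by 1% per percentage point of burden.

Writes results/cohort/{patients.csv,timelines.csv,config.json}.
"""

from pathlib import Path

import numpy as np

from afburden import synthetic as syn

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    cohort = syn.generate_cohort(
        n=1000, outcome_beta=float(np.log(1.01)), followup_years=4.1, seed=2026
    )
    cohort.to_csv(OUT)
    b = cohort.patients["burden_true"]
    print(f"cohort of {len(b)} patients written to {OUT}")
    print(f"  zero-burden fraction: {(b == 0).mean():.1%}")
    q25, q50, q75 = np.percentile(b, [25, 50, 75])
    print(f"  burden median [IQR]: {q50:.1%} [{q25:.1%}; {q75:.1%}]")
    print(f"  primary events: {(cohort.patients.event_type == 'primary').sum()}")


if __name__ == "__main__":
    main()
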