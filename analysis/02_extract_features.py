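"""Extract RR features from a labelled batch of synthetic 30-s ECGs.

Synthesises 300 records across the four classes, runs QRS detection and the
13-feature extraction, and writes the per-record feature table (plus heart
rate and recurrence-plot irregularity) to results/features.csv.
"""

from pathlib import Path

import numpy as np

from afburden import features as feat
from afburden import synthetic as syn

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rng = np.random.default_rng(7)
    ecgs = []
    for i in range(300):
        rhythm = ["SR", "AF", "OTHER", "NOISE"][i % 4]
        base = "SR" if rhythm == "NOISE" else rhythm
        rr = syn.generate_rr_series(
            base, 30.0, float(rng.uniform(50, 110)), seed=1000 + i
        )
        level = 3.0 if rhythm == "NOISE" else float(rng.uniform(0.0, 0.15))
        ecgs.append(
            syn.synthesize_ecg(rr, base, level, seed=2000 + i,
                               patient_id=f"P{i % 75:03d}")
        )
    table = feat.feature_table(ecgs)
    OUT.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT / "features.csv", index=False)
    ok = table["ok"]
    print(f"features for {len(table)} records -> {OUT / 'features.csv'}")
    print(f"  feature extraction succeeded on {ok.sum()} records "
          f"({(~ok).sum()} routed to noise/unclassifiable)")
    by = table[ok].groupby("true_label")[["rmssd", "cosen", "irregularity"]].mean()
    print(by.round(3).to_string())


if __name__ == "__main__":
    main()
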