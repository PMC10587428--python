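"""Derive per-subject metrics from the fits and vitals.

SUV peak statistics per region, RPP-scaled myocardial uptake, oxygen
consumption (MVO2) and blood flow (MBF) from the acetate fits, K1/k2 ratios,
and the pelvis double-peak statistics.  Writes metrics.csv.
"""

import pandas as pd

from config import CFG
from tackit.pipeline import derive_stage

if __name__ == "__main__":
    derive_stage(CFG)
    m = pd.read_csv(CFG.out_dir / "metrics.csv")
    means = m.groupby(["organ", "metric", "tracer"])["value"].agg(["mean", "std", "count"])
    for organ in ("heart_lv", "renal_cortex", "renal_pelvis"):
        print(f"\n{organ}:")
        print(means.loc[organ].round(3))
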