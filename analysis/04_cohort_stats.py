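"""Cohort statistics: the tracer-comparison summary table.

Paired tracer contrasts per (organ, metric) with significance markers,
plus between-organ fold differences in both conventions.  Writes
cohort_summary.csv and report.txt.
"""

import pandas as pd

from config import CFG
from tackit.pipeline import cohort_stage

if __name__ == "__main__":
    cohort_stage(CFG)
    summary = pd.read_csv(CFG.out_dir / "cohort_summary.csv")
    summary["marker"] = summary["marker"].fillna("")
    kinetic = summary[summary["metric"].str.startswith(("K1", "k2", "k3", "mbf", "mvo2"))]
    print("kinetic summary (mean (SD), marker vs acetate):")
    for _, r in kinetic.iterrows():
        print(
            f"  {r['organ']:>13} {r['metric']:>9} {r['tracer']:>4}: "
            f"{r['mean']:.3f} ({r['sd']:.3f}){r['marker']}"
        )
    print("\nfull report: results/report.txt")
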