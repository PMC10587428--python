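"""Shared run configuration for the numbered analysis drivers.

One 10-subject dual-tracer virtual cohort at the default study conditions;
every driver reads and writes ``results/``.
"""

from pathlib import Path

from tackit.pipeline import RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"

CFG = RunConfig(out_dir=RESULTS, n_subjects=10, seed=11)
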