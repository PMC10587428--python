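"""CSV formats for TACs, kinetic truth, vitals, input functions and fits.

The TAC dialect is a flat RFC-4180 CSV with one row per frame:

    subject_id, tracer, region, frame_start_s, frame_end_s, value,
    value_units, decay_corrected

Frames must be ordered and non-overlapping within each (subject, tracer,
region) group and units consistent within a group.  Malformed rows are
reported with their (1-based, header-inclusive) line numbers.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .aif import FengParams
from .kinetics import TableMetabolites
from .metrics import SubjectVitals
from .schedule import FrameSchedule, TimeActivityCurve

__all__ = [
    "TacFormatError",
    "TAC_COLUMNS",
    "tacs_to_table",
    "table_to_tacs",
    "write_tac_csv",
    "read_tac_csv",
    "write_truth_csv",
    "write_vitals_csv",
    "read_vitals_csv",
    "write_aif_csv",
    "read_aif_csv",
    "read_metabolite_table",
    "write_fit_results_csv",
]

TAC_COLUMNS = [
    "subject_id",
    "tracer",
    "region",
    "frame_start_s",
    "frame_end_s",
    "value",
    "value_units",
    "decay_corrected",
]


class TacFormatError(ValueError):
    """Malformed TAC table (missing column, bad frames, mixed units)."""


def tacs_to_table(tacs: dict) -> pd.DataFrame:
    """Flatten {(subject_id, tracer, region): TimeActivityCurve} to the dialect."""
    rows = []
    for (subject, tracer, region), tac in tacs.items():
        for s, e, v in zip(tac.schedule.frame_start_s, tac.schedule.frame_end_s, tac.values):
            rows.append((subject, tracer, region, s, e, v, tac.units, tac.decay_corrected))
    return pd.DataFrame(rows, columns=TAC_COLUMNS)


def _validate_table(df: pd.DataFrame) -> None:
    missing = [c for c in TAC_COLUMNS if c not in df.columns]
    if missing:
        raise TacFormatError(f"missing required column(s): {', '.join(missing)}")
    bad = df.index[df["frame_end_s"] <= df["frame_start_s"]]
    if len(bad):
        # +2: 1-based data rows below a header line
        raise TacFormatError(f"frame_end_s <= frame_start_s at file row {bad[0] + 2}")
    for key, grp in df.groupby(["subject_id", "tracer", "region"], sort=False):
        starts = grp["frame_start_s"].to_numpy(dtype=float)
        ends = grp["frame_end_s"].to_numpy(dtype=float)
        if np.any(starts[1:] < ends[:-1] - 1e-9):
            row = grp.index[1 + int(np.argmax(starts[1:] < ends[:-1] - 1e-9))] + 2
            raise TacFormatError(f"non-monotone/overlapping frames for {key} at file row {row}")
        if grp["value_units"].nunique() > 1 or grp["decay_corrected"].nunique() > 1:
            raise TacFormatError(f"mixed units or decay state within group {key}")


def table_to_tacs(df: pd.DataFrame) -> dict:
    """Parse the dialect into {(subject_id, tracer, region): TimeActivityCurve}."""
    _validate_table(df)
    out = {}
    for (subject, tracer, region), grp in df.groupby(["subject_id", "tracer", "region"], sort=False):
        schedule = FrameSchedule(
            grp["frame_start_s"].to_numpy(dtype=float), grp["frame_end_s"].to_numpy(dtype=float)
        )
        out[(subject, tracer, region)] = TimeActivityCurve(
            schedule,
            grp["value"].to_numpy(dtype=float),
            units=str(grp["value_units"].iloc[0]),
            decay_corrected=bool(grp["decay_corrected"].iloc[0]),
            meta={"subject_id": subject, "tracer": tracer, "region": region},
        )
    return out


def write_tac_csv(tacs: dict, path) -> None:
    tacs_to_table(tacs).to_csv(path, index=False)


def read_tac_csv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover
        raise TacFormatError(f"cannot parse {path}: {exc}") from exc
    _validate_table(df)
    return df


# ---------------------------------------------------------------------------
# cohort sidecar files


def write_truth_csv(cohort, path) -> None:
    rows = []
    for subj in cohort.subjects:
        for (tracer, region), rec in subj.regions.items():
            t = rec.truth
            sp = t.second_peak
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "tracer": tracer,
                    "region": region,
                    "K1": t.params.K1,
                    "k2": t.params.k2,
                    "k3": t.params.k3,
                    "Vb": t.params.Vb,
                    "early_fraction": t.early_fraction,
                    "second_amplitude": sp.amplitude if sp else np.nan,
                    "second_mode_min": sp.mode_min if sp else np.nan,
                    "seed": cohort.seed,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_vitals_csv(cohort, path) -> None:
    rows = [
        {"subject_id": s.subject_id, **dataclasses.asdict(s.vitals)} for s in cohort.subjects
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_vitals_csv(path) -> dict:
    df = pd.read_csv(path)
    return {
        r["subject_id"]: SubjectVitals(
            hr=r["hr"], sbp=r["sbp"], dose_mbq=r["dose_mbq"], weight_kg=r["weight_kg"]
        )
        for _, r in df.iterrows()
    }


def write_aif_csv(cohort, path) -> None:
    rows = []
    for s in cohort.subjects:
        for tracer, p in s.aif_params.items():
            rows.append({"subject_id": s.subject_id, "tracer": tracer, **dataclasses.asdict(p)})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_aif_csv(path) -> dict:
    df = pd.read_csv(path)
    fields = [f.name for f in dataclasses.fields(FengParams)]
    return {
        (r["subject_id"], r["tracer"]): FengParams(**{f: r[f] for f in fields})
        for _, r in df.iterrows()
    }


def read_metabolite_table(path) -> TableMetabolites:
    """Two-column CSV (time_min, parent_fraction) -> interpolated model."""
    df = pd.read_csv(path)
    for col in ("time_min", "parent_fraction"):
        if col not in df.columns:
            raise TacFormatError(f"metabolite table missing column {col!r}")
    return TableMetabolites(df["time_min"].to_numpy(float), df["parent_fraction"].to_numpy(float))


def write_fit_results_csv(fits: list[dict], path) -> None:
    """Serialize fit records (flat dicts built by the pipeline) to CSV."""
    pd.DataFrame(fits).to_csv(path, index=False)
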