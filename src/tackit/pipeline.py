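"""Config-driven pipeline: simulate -> fit -> derive -> cohort.

Each stage is a plain function over files in ``out_dir`` so the numbered
analysis drivers, the CLI and tests all share one code path.  Every source of
randomness flows from the config seed; rerunning an identical config
reproduces identical outputs (and therefore identical manifest hashes).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aif import FengInput
from .cohort import build_summary_table, fold_summary, paired_compare, PairedSample
from .fitting import FitConfig, compare_models, fit_model
from .io import (
    read_aif_csv,
    read_tac_csv,
    read_vitals_csv,
    table_to_tacs,
    write_aif_csv,
    write_fit_results_csv,
    write_tac_csv,
    write_truth_csv,
    write_vitals_csv,
)
from .kinetics import default_metabolite_model, metabolite_correct
from .metrics import (
    detect_peaks,
    kinetic_ratio,
    mbf_from_k1_acetate,
    mvo2_from_k2,
    peak_stats,
    rate_pressure_product,
    scaled_k1,
    suv_curve,
)
from .synthetic import generate_cohort

log = logging.getLogger("tackit")

STAGES = ("simulate", "fit", "derive", "cohort")

#: organ label used for myocardial rows in metrics/summary tables
HEART = "heart_lv"


@dataclass
class RunConfig:
    out_dir: Path = Path("results")
    n_subjects: int = 10
    seed: int = 0
    tracers: tuple = ("acac", "ac")
    noise_scale: float = 0.05
    fit_window_min: tuple = (0.0, 15.0)
    multi_start: int = 5
    cortex_vb: float = 0.10
    min_prominence_suv: float = 0.5
    early_window_min: tuple = (0.0, 2.0)
    stages: tuple = STAGES

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        for tr in self.tracers:
            if tr not in ("acac", "ac"):
                raise ValueError(f"unknown tracer {tr!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("tracers", "fit_window_min", "early_window_min", "stages"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _files(cfg: RunConfig) -> dict:
    d = cfg.out_dir
    return {
        "tacs": d / "tacs.csv",
        "truth": d / "truth.csv",
        "vitals": d / "vitals.csv",
        "aif": d / "aif.csv",
        "fits": d / "fits.csv",
        "metrics": d / "metrics.csv",
        "summary": d / "cohort_summary.csv",
        "report": d / "report.txt",
    }


# ---------------------------------------------------------------------------


def simulate_stage(cfg: RunConfig) -> list[Path]:
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    f = _files(cfg)
    cohort = generate_cohort(
        cfg.n_subjects, seed=cfg.seed, noise_scale=cfg.noise_scale, tracers=cfg.tracers
    )
    tacs = {
        (s.subject_id, tracer, region): rec.tac
        for s in cohort.subjects
        for (tracer, region), rec in s.regions.items()
    }
    write_tac_csv(tacs, f["tacs"])
    write_truth_csv(cohort, f["truth"])
    write_vitals_csv(cohort, f["vitals"])
    write_aif_csv(cohort, f["aif"])
    log.info("simulated %d subjects x %s", cfg.n_subjects, "/".join(cfg.tracers))
    return [f["tacs"], f["truth"], f["vitals"], f["aif"]]


def fit_stage(cfg: RunConfig) -> list[Path]:
    f = _files(cfg)
    tacs = table_to_tacs(read_tac_csv(f["tacs"]))
    aifs = read_aif_csv(f["aif"])
    base = FitConfig(window_min=cfg.fit_window_min, multi_start=cfg.multi_start, seed=cfg.seed)
    cortex_cfg = dataclasses.replace(base, fit_vb=False, fixed_vb=cfg.cortex_vb)

    records = []
    plans = {"myocardium": [("1tc", base)], "renal_cortex": [("1tc", cortex_cfg)]}
    for (subject, tracer, region), tac in tacs.items():
        if region not in plans:
            continue
        aif = FengInput(aifs[(subject, tracer)])
        cp = metabolite_correct(aif, default_metabolite_model(tracer))
        models = list(plans[region])
        if region == "renal_cortex" and tracer == "acac":
            models.append(("2tc", cortex_cfg))
        fits = {}
        for model, fcfg in models:
            res = fit_model(tac, cp, aif, model=model, cfg=fcfg)
            fits[model] = res
            records.append(
                {
                    "subject_id": subject,
                    "tracer": tracer,
                    "region": region,
                    "model": model,
                    "K1": res.params.K1,
                    "k2": res.params.k2,
                    "k3": res.params.k3,
                    "Vb": res.params.Vb,
                    "rss": res.rss,
                    "n_frames": res.n,
                    "n_params": res.p,
                    "aic": res.aic,
                    "converged": res.converged,
                    "degenerate": res.degenerate,
                }
            )
        if len(fits) == 2:
            cmpres = compare_models(fits["1tc"], fits["2tc"])
            records[-2]["delta_aic_1tc_minus_2tc"] = cmpres.delta_aic
            records[-1]["delta_aic_1tc_minus_2tc"] = cmpres.delta_aic
    write_fit_results_csv(records, f["fits"])
    log.info("fitted %d TAC/model combinations", len(records))
    return [f["fits"]]


def _suv_metrics(tac, vitals, organ, cfg: RunConfig) -> list[tuple]:
    suv = suv_curve(tac, vitals)
    peak = peak_stats(suv)
    rows = [(organ, "suv_max", peak.suv_max), (organ, "t_max_min", peak.t_max_min)]
    if organ == "renal_pelvis":
        lo, hi = cfg.early_window_min
        mids = suv.t_mid_min
        early = (mids >= lo) & (mids <= hi)
        rows.append((organ, "sum_early", float(np.sum(suv.values[early]))))
        peaks = detect_peaks(suv, min_prominence=cfg.min_prominence_suv)
        rows[1] = (organ, "t_max_min", peaks[0].t_max_min if peaks else peak.t_max_min)
        if len(peaks) > 1:
            rows.append((organ, "suv_max_2nd", peaks[1].suv_max))
            rows.append((organ, "t_max_2nd_min", peaks[1].t_max_min))
    return rows


def derive_stage(cfg: RunConfig) -> list[Path]:
    f = _files(cfg)
    tacs = table_to_tacs(read_tac_csv(f["tacs"]))
    vitals = read_vitals_csv(f["vitals"])
    fits = pd.read_csv(f["fits"])

    rows = []

    def put(subject, tracer, organ, metric, value):
        rows.append(
            {"subject_id": subject, "organ": organ, "metric": metric, "tracer": tracer, "value": value}
        )

    organ_of = {
        "lv_blood": "lv_blood",
        "myocardium": HEART,
        "renal_cortex": "renal_cortex",
        "renal_pelvis": "renal_pelvis",
    }
    for (subject, tracer, region), tac in tacs.items():
        for organ, metric, value in _suv_metrics(tac, vitals[subject], organ_of[region], cfg):
            put(subject, tracer, organ, metric, value)

    for _, r in fits.iterrows():
        organ = organ_of[r["region"]]
        tag = r["model"]
        put(r["subject_id"], r["tracer"], organ, f"K1_{tag}", r["K1"])
        put(r["subject_id"], r["tracer"], organ, f"k2_{tag}", r["k2"])
        if tag == "2tc":
            put(r["subject_id"], r["tracer"], organ, "k3_2tc", r["k3"])
        if tag == "1tc":
            put(r["subject_id"], r["tracer"], organ, "k1_over_k2", kinetic_ratio(r["K1"], r["k2"]))
        if organ == HEART and tag == "1tc":
            rpp = rate_pressure_product(vitals[r["subject_id"]])
            put(r["subject_id"], r["tracer"], organ, "rpp", rpp)
            put(r["subject_id"], r["tracer"], organ, "K1s_1tc", scaled_k1(r["K1"], rpp))
            if r["tracer"] == "ac":
                put(r["subject_id"], r["tracer"], organ, "mvo2", mvo2_from_k2(r["k2"]))
                put(r["subject_id"], r["tracer"], organ, "mbf", mbf_from_k1_acetate(r["K1"]))

    pd.DataFrame(rows).to_csv(f["metrics"], index=False)
    log.info("derived %d per-subject metric values", len(rows))
    return [f["metrics"]]


def cohort_stage(cfg: RunConfig) -> list[Path]:
    f = _files(cfg)
    metrics = pd.read_csv(f["metrics"])
    summary = build_summary_table(metrics)
    summary.to_csv(f["summary"], index=False)

    lines = ["cohort summary (mean (SD), n; markers vs 11C-Ac paired t)", ""]
    for _, r in summary.iterrows():
        sd = f"{r['sd']:.3g}" if np.isfinite(r["sd"]) else "-"
        p = f", p={r['p_vs_ref']:.3g}" if np.isfinite(r["p_vs_ref"]) else ""
        lines.append(
            f"{r['organ']:>13} {r['metric']:>14} {r['tracer']:>4}: "
            f"{r['mean']:.3g} ({sd}) n={r['n']}{r['marker']}{p}"
        )

    # between-organ fold differences per tracer, both conventions
    wide = metrics.pivot_table(
        index="subject_id", columns=["organ", "metric", "tracer"], values="value"
    )
    lines.append("")
    for tracer in cfg.tracers:
        for metric in ("K1_1tc", "k2_1tc"):
            try:
                cortex = wide[("renal_cortex", metric, tracer)].to_numpy()
                heart = wide[(HEART, metric, tracer)].to_numpy()
            except KeyError:
                continue
            fs = fold_summary(cortex, heart)
            lines.append(
                f"fold cortex/heart {metric} {tracer}: mean-of-ratios "
                f"{fs.mean_of_ratios:.2f} +/- {fs.sd_of_ratios:.2f}, "
                f"ratio-of-means {fs.ratio_of_means:.2f}"
            )
    f["report"].write_text("\n".join(lines) + "\n")
    log.info("wrote summary table (%d rows) and report", len(summary))
    return [f["summary"], f["report"]]


# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in order and write a manifest.

    Returns the manifest (inputs, seed, version, per-file SHA-256 hashes).
    A stage failure propagates after being logged with the stage name.
    """
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    stage_fns = {
        "simulate": simulate_stage,
        "fit": fit_stage,
        "derive": derive_stage,
        "cohort": cohort_stage,
    }
    outputs: list[Path] = []
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        try:
            outputs.extend(stage_fns[stage](cfg))
        except Exception:
            log.error("stage %r failed", stage)
            raise
    manifest = {
        "version": __version__,
        "config": {k: (str(v) if isinstance(v, Path) else list(v) if isinstance(v, tuple) else v)
                    for k, v in dataclasses.asdict(cfg).items()},
        "seed": cfg.seed,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (cfg.out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
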