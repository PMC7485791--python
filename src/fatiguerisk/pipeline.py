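"""Pipeline orchestration: simulate -> hrv -> risk -> associate -> report.

Each stage reads the CSV artifacts of its upstream stage from a run
directory and writes its own; `run_pipeline` executes any subset in
dependency order, fails with an actionable message when an upstream
artifact is missing, and stamps a manifest (config hash, seed, schema
version, per-artifact SHA-256) so reruns are verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
import yaml

from . import association, hrv, io, risk, synthetic

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "STAGES"]

log = logging.getLogger("fatiguerisk")

STAGES = ("simulate", "hrv", "risk", "associate", "report")

#: artifacts each stage requires / produces (file names inside outdir)
_REQUIRES = {
    "simulate": [],
    "hrv": ["rri.csv", "drivers.csv"],
    "risk": ["events.csv", "annotations.csv", "cohort.csv"],
    "associate": ["hrv.csv", "daily.csv", "vas.csv"],
    "report": ["results.json"],
}
_PRODUCED_BY = {
    "rri.csv": "simulate",
    "drivers.csv": "simulate",
    "events.csv": "simulate",
    "annotations.csv": "simulate",
    "cohort.csv": "simulate",
    "vas.csv": "simulate",
    "hrv.csv": "hrv",
    "daily.csv": "risk",
    "results.json": "associate",
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Serializable configuration for one pipeline run."""

    outdir: str = "run"
    seed: int = 0
    cohort: synthetic.CohortSpec = field(default_factory=synthetic.CohortSpec)
    spectral: hrv.SpectralConfig = field(default_factory=hrv.SpectralConfig)
    qc: hrv.QCPolicy = field(default_factory=hrv.QCPolicy)
    classifier: str = "cart"  # "cart" | "rules"
    norms_path: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.classifier not in ("cart", "rules"):
            raise ValueError("classifier must be 'cart' or 'rules'")
        # the root seed drives the cohort unless the spec pins its own
        self.cohort = dataclasses.replace(self.cohort, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, typ in (
            ("cohort", synthetic.CohortSpec),
            ("spectral", hrv.SpectralConfig),
            ("qc", hrv.QCPolicy),
        ):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                for f_ in ("age_range", "rri_base_range"):
                    if f_ in sub and isinstance(sub[f_], list):
                        sub[f_] = tuple(sub[f_])
                d[key] = typ(**sub)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths and logging excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        d.pop("log_level", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _require(outdir: Path, stage: str) -> None:
    for fname in _REQUIRES[stage]:
        if not (outdir / fname).exists():
            raise PipelineError(
                f"stage '{stage}' needs {fname}; run stage "
                f"'{_PRODUCED_BY[fname]}' first"
            )


def _norms(config: PipelineConfig) -> hrv.NormTable:
    if config.norms_path:
        return hrv.NormTable.from_csv(config.norms_path)
    return hrv.default_norm_table()


def _stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    data = synthetic.generate_cohort(config.cohort, norms=_norms(config))
    io.write_table(data.drivers, outdir / "drivers.csv", "drivers")
    io.write_table(data.daily, outdir / "cohort.csv", "cohort")
    io.write_table(data.vas, outdir / "vas.csv", "vas")
    io.write_table(data.rri, outdir / "rri.csv", "rri")
    if data.events is not None:
        io.write_table(data.events, outdir / "events.csv", "events")
        io.write_table(data.annotations, outdir / "annotations.csv", "annotations")
        io.write_table(data.truth_events, outdir / "truth_events.csv", "truth_events")
    io.write_table(
        data.truth_recordings, outdir / "truth_recordings.csv", "truth_recordings"
    )
    io.write_table(data.truth_days, outdir / "truth_days.csv", "truth_days")
    log.info("simulate: %d drivers, %d driver-days", len(data.drivers), len(data.daily))


def _stage_hrv(config: PipelineConfig, outdir: Path) -> None:
    _require(outdir, "hrv")
    rri = io.read_table(outdir / "rri.csv", "rri")
    drivers = io.read_table(outdir / "drivers.csv", "drivers")
    ages = dict(zip(drivers["driver_id"], drivers["age"].astype(float)))
    norms = _norms(config)
    rows = []
    for (drv, date, cond), grp in rri.groupby(
        ["driver_id", "date", "condition"], sort=True
    ):
        series = hrv.RRISeries(
            grp.sort_values("beat_index")["rri_ms"].to_numpy(),
            driver_id=drv,
            condition=cond,
            date=date,
        )
        report, summary = hrv.analyze_series(
            series, ages[drv], norms, config.spectral, config.qc
        )
        rows.append(
            {
                "driver_id": drv,
                "date": date,
                "condition": cond,
                "n_beats": report.n_beats,
                "accepted": report.accepted,
                "lf_power": summary.lf_power if summary else np.nan,
                "hf_power": summary.hf_power if summary else np.nan,
                "lf_hf": summary.lf_hf if summary else np.nan,
                "rri_average": summary.rri_average if summary else np.nan,
                "lf_score": summary.lf_score if summary else np.nan,
            }
        )
    io.write_table(pd.DataFrame(rows), outdir / "hrv.csv", "hrv")
    log.info("hrv: %d recordings analysed", len(rows))


def _stage_risk(config: PipelineConfig, outdir: Path) -> None:
    _require(outdir, "risk")
    events = io.read_table(outdir / "events.csv", "events")
    ann = io.read_table(outdir / "annotations.csv", "annotations")
    cohort = io.read_table(outdir / "cohort.csv", "cohort")

    feats, keys = [], []
    for (drv, date, eid), grp in events.groupby(
        ["driver_id", "date", "event_id"], sort=True
    ):
        grp = grp.sort_values("sample_index")
        ev = risk.WarningEvent(
            speed_samples=grp["speed_kmh"].to_numpy(),
            duration_s=float(len(grp)),
            driver_id=drv,
            date=date,
            start_time=str(grp["start_time"].iloc[0]),
        )
        feats.append(risk.extract_features(ev))
        keys.append((drv, date, eid))
    fdf = pd.DataFrame([f.as_array() for f in feats], columns=risk.FEATURE_NAMES)
    kdf = pd.DataFrame(keys, columns=["driver_id", "date", "event_id"])
    io.write_table(pd.concat([kdf, fdf], axis=1), outdir / "features.csv", "features")

    labels = kdf.merge(ann, on=["driver_id", "date", "event_id"], how="left")["label"]
    if config.classifier == "cart":
        model = risk.CartRiskClassifier(random_state=config.seed).fit(
            fdf, labels.to_numpy(dtype=int)
        )
        (outdir / "model.json").write_text(json.dumps(model.to_dict(), indent=2))
    else:
        model = risk.RuleRiskClassifier().fit()
    preds = model.predict(fdf)
    io.write_table(
        kdf.assign(prediction=preds), outdir / "predictions.csv", "predictions"
    )

    pred_per_day = (
        kdf.assign(prediction=preds)
        .groupby(["driver_id", "date"])["prediction"]
        .sum()
        .rename("R")
        .reset_index()
    )
    daily = cohort[["driver_id", "date", "wt_hours", "n_events"]].merge(
        pred_per_day, on=["driver_id", "date"], how="left"
    )
    daily["R"] = daily["R"].fillna(0).astype(int)
    daily["included"] = daily["wt_hours"] >= 3.0
    daily["r_1hr"] = np.where(
        daily["included"], daily["R"] / daily["wt_hours"], np.nan
    )
    io.write_table(daily, outdir / "daily.csv", "daily")
    log.info("risk: %d events classified over %d driver-days", len(kdf), len(daily))


def _stage_associate(config: PipelineConfig, outdir: Path) -> None:
    _require(outdir, "associate")
    hrv_table = io.read_table(outdir / "hrv.csv", "hrv")
    daily = io.read_table(outdir / "daily.csv", "daily")
    vas = io.read_table(outdir / "vas.csv", "vas")
    records = association.build_records(hrv_table, daily, vas)
    records.to_csv(outdir / "analysis_records.csv", index=False)
    results = association.run_association(records)
    results["schema_version"] = io.SCHEMA_VERSION
    results["seed"] = config.seed
    results["config_hash"] = config.config_hash()
    (outdir / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True))
    log.info("associate: %d analysis records, %d tests",
             results["n_records"], results["n_tests"])


def _stage_report(config: PipelineConfig, outdir: Path) -> None:
    _require(outdir, "report")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    records = pd.read_csv(outdir / "analysis_records.csv")
    ok = records[records["analysis_ok"]]
    panels = [
        ("vas_pre", "VAS (pre-shift)"),
        ("vas_post", "VAS (post-shift)"),
        ("lf_score_pre", "LF score (pre-shift)"),
        ("lf_score_post_prev", "LF score (post-shift, previous day)"),
    ]
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    for ax, (col, title) in zip(axes.ravel(), panels):
        if col in ok.columns:
            ax.scatter(ok[col], ok["r_1hr"], s=8, alpha=0.5)
        ax.set_xlabel(title)
        ax.set_ylabel("R_1hr [events/h]")
    fig.tight_layout()
    fig.savefig(outdir / "correlations.png", dpi=120)
    plt.close(fig)

    if "lf_score_post_prev" in ok.columns and ok["r_1hr"].notna().any():
        thr = ok["r_1hr"].median()
        hi = ok.loc[ok["r_1hr"] > thr, "lf_score_post_prev"].dropna()
        lo = ok.loc[ok["r_1hr"] <= thr, "lf_score_post_prev"].dropna()
        fig, ax = plt.subplots(figsize=(4, 5))
        ax.boxplot([lo, hi], tick_labels=["low risk", "high risk"])
        ax.set_ylabel("LF score (post-shift, previous day)")
        fig.tight_layout()
        fig.savefig(outdir / "group_comparison.png", dpi=120)
        plt.close(fig)
    log.info("report: figures written to %s", outdir)


_RUNNERS = {
    "simulate": _stage_simulate,
    "hrv": _stage_hrv,
    "risk": _stage_risk,
    "associate": _stage_associate,
    "report": _stage_report,
}


def _manifest(config: PipelineConfig, outdir: Path) -> None:
    arts = {}
    for p in sorted(outdir.iterdir()):
        if p.name == "manifest.json" or p.is_dir():
            continue
        arts[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "schema_version": io.SCHEMA_VERSION,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "artifacts": arts,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )


def run_pipeline(
    config: PipelineConfig, stages: Sequence[str] = STAGES
) -> Dict[str, List[str]]:
    """Run the requested stages in dependency order; returns artifact names."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stage(s): {unknown}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ordered = [s for s in STAGES if s in stages]
    for stage in ordered:
        log.info("running stage %s", stage)
        _RUNNERS[stage](config, outdir)
    _manifest(config, outdir)
    return {"stages": ordered, "artifacts": sorted(p.name for p in outdir.iterdir())}
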