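"""End-to-end orchestration: generate -> score -> summarize -> model.

A :class:`RunConfig` describes one run (cohort parameters, stage toggles,
permutation settings, seed, output directory); :func:`run_pipeline`
executes the enabled stages in dependency order, writes plain CSV/TSV
outputs, and returns a :class:`RunManifest` recording hashes of every
artifact so a re-run with the same config and seed can be verified
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import kinematics as kin
from . import questionnaires as quest
from .inference import ADJUSTMENT_SETS, paired_t
from .synthetic import CohortSpec, TaskGeometry, generate_cohort
from .tract_stats import AlongTractGLM, entire_tract_regression

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    outdir: str = "cmipipe_run"
    seed: int = 0
    cohort: CohortSpec | None = None
    geometry: TaskGeometry | None = None
    stages: dict = field(
        default_factory=lambda: {
            "simulate": True,
            "kinematics": True,
            "questionnaires": True,
            "rsfc": True,
            "tract": True,
            "inference": True,
        }
    )
    n_perm: int = 1000
    alpha: float = 0.05
    tract_outcome: str = "rpq3"
    timeseries_T: int = 300
    tract_length: int = 60

    def __post_init__(self) -> None:
        if self.cohort is None:
            self.cohort = CohortSpec(seed=self.seed)
        if self.geometry is None:
            self.geometry = TaskGeometry()

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            doc = yaml.safe_load(text)
        else:
            doc = json.loads(text)
        cohort = doc.pop("cohort", None)
        geometry = doc.pop("geometry", None)
        cfg = cls(**doc)
        if cohort:
            cfg.cohort = CohortSpec.from_dict(cohort)
        if geometry:
            cfg.geometry = TaskGeometry(**geometry)
        return cfg


@dataclass
class RunManifest:
    seed: int
    config: dict
    stages_run: list = field(default_factory=list)
    stages_skipped: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)  # path -> sha256
    timings_s: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _register(manifest: RunManifest, path: Path) -> None:
    manifest.outputs[str(path)] = _sha256(path)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in dependency order.

    Stage outputs are plain CSV/TSV under ``config.outdir``.  Partial
    failures leave completed-stage outputs intact; a disabled upstream
    stage whose outputs a later stage needs raises a dependency error
    naming the stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed, config={
        "cohort": config.cohort.to_dict(),
        "geometry": asdict(config.geometry),
        "n_perm": config.n_perm,
        "alpha": config.alpha,
        "stages": config.stages,
    })
    cohort = None

    def tick(stage):
        manifest.stages_run.append(stage)
        return time.perf_counter()

    if config.stages.get("simulate", True):
        t0 = tick("simulate")
        cohort = generate_cohort(
            config.cohort, config.geometry,
            timeseries_T=config.timeseries_T, tract_length=config.tract_length,
            with_timeseries=config.stages.get("rsfc", True),
            with_tracts=config.stages.get("tract", True),
        )
        cohort.write_trials_tsv(out / "trials.tsv")
        cohort.write_questionnaires_csv(out / "questionnaire_items.csv")
        cohort.write_covariates_csv(out / "covariates.csv")
        if cohort.tract_profiles:
            cohort.write_profiles_tsv(out / "tract_profiles.tsv")
        for f in ("trials.tsv", "questionnaire_items.csv", "covariates.csv"):
            _register(manifest, out / f)
        manifest.timings_s["simulate"] = round(time.perf_counter() - t0, 3)
    else:
        manifest.stages_skipped.append("simulate")

    def need_cohort(stage):
        if cohort is None:
            raise RuntimeError(
                f"stage {stage!r} requires the simulate stage (or loaded inputs)"
            )

    session_df = None
    if config.stages.get("kinematics", True):
        t0 = tick("kinematics")
        need_cohort("kinematics")
        trial_df, session_df = kin.score_cohort(cohort.trials, config.geometry)
        comp = kin.compute_composites(session_df)
        session_df = session_df.merge(comp, on=["participant", "condition"])
        trial_df.to_csv(out / "trial_outcomes.csv", index=False, float_format="%.6f")
        session_df.to_csv(out / "session_summaries.csv", index=False, float_format="%.6f")
        _register(manifest, out / "trial_outcomes.csv")
        _register(manifest, out / "session_summaries.csv")
        manifest.timings_s["kinematics"] = round(time.perf_counter() - t0, 3)
    else:
        manifest.stages_skipped.append("kinematics")

    scores = None
    if config.stages.get("questionnaires", True):
        t0 = tick("questionnaires")
        need_cohort("questionnaires")
        items = pd.concat([cohort.rpq_items, cohort.dhi_items], ignore_index=True)
        scores = quest.score_questionnaire_table(items)
        scores.to_csv(out / "questionnaire_scores.csv", index=False)
        quest.summarize_cohort(items, "RPQ").to_csv(
            out / "rpq_endorsement.tsv", sep="\t", index=False
        )
        _register(manifest, out / "questionnaire_scores.csv")
        _register(manifest, out / "rpq_endorsement.tsv")
        manifest.timings_s["questionnaires"] = round(time.perf_counter() - t0, 3)
    else:
        manifest.stages_skipped.append("questionnaires")

    rsfc_df = None
    if config.stages.get("rsfc", True):
        t0 = tick("rsfc")
        need_cohort("rsfc")
        rsfc_df = conn.within_network_table(
            cohort.parcel_timeseries, cohort.network_labels
        )
        rsfc_df.to_csv(out / "rsfc_within_network.csv", index=False, float_format="%.6f")
        _register(manifest, out / "rsfc_within_network.csv")
        manifest.timings_s["rsfc"] = round(time.perf_counter() - t0, 3)
    else:
        manifest.stages_skipped.append("rsfc")

    if config.stages.get("tract", True):
        t0 = tick("tract")
        need_cohort("tract")
        if scores is None:
            raise RuntimeError("stage 'tract' requires the questionnaires stage")
        data = cohort.covariates.merge(scores, on="participant")
        covs = [c for c in ADJUSTMENT_SETS["symptom"] if c in data.columns]
        cluster_rows, entire_rows = [], []
        for key, prof in cohort.tract_profiles.items():
            model = AlongTractGLM.from_dataframe(
                prof, data, config.tract_outcome, covs
            )
            res = model.fit(
                n_perm=config.n_perm, alpha=config.alpha, seed=config.seed
            )
            cluster_rows.extend(c.to_dict() for c in res.clusters)
            entire_rows.append(
                entire_tract_regression(
                    prof, data, config.tract_outcome, covs
                ).to_frame()
            )
        pd.DataFrame(cluster_rows).to_csv(
            out / "tract_clusters.tsv", sep="\t", index=False, float_format="%.6f"
        )
        pd.concat(entire_rows, ignore_index=True).to_csv(
            out / "entire_tract_models.csv", index=False, float_format="%.6f"
        )
        _register(manifest, out / "tract_clusters.tsv")
        _register(manifest, out / "entire_tract_models.csv")
        manifest.timings_s["tract"] = round(time.perf_counter() - t0, 3)
    else:
        manifest.stages_skipped.append("tract")

    if config.stages.get("inference", True) and session_df is not None:
        t0 = tick("inference")
        rows = []
        wide = session_df.pivot(
            index="participant", columns="condition",
            values=["timing_score", "trajectory_score", "RT", "PLf", "pct_DR"],
        )
        for measure in ("timing_score", "trajectory_score", "RT", "PLf", "pct_DR"):
            res = paired_t(
                wide[(measure, "pc_fr")].to_numpy(),
                wide[(measure, "standard")].to_numpy(),
            )
            rows.append(
                {"measure": measure, "t": res.t, "df": res.df, "p": res.p,
                 "mean_diff_pcfr_minus_standard": res.mean_diff}
            )
        pd.DataFrame(rows).to_csv(
            out / "condition_contrasts.csv", index=False, float_format="%.6f"
        )
        _register(manifest, out / "condition_contrasts.csv")
        manifest.timings_s["inference"] = round(time.perf_counter() - t0, 3)
    elif not config.stages.get("inference", True):
        manifest.stages_skipped.append("inference")

    manifest.write(out / "manifest.json")
    return manifest


# ---- input validation ----------------------------------------------------

SCHEMAS = {
    "trials": {
        "sep": "\t",
        "columns": ["participant", "condition", "trial", "target", "t_ms", "x_mm", "y_mm"],
        "checks": [("condition", lambda s: s.isin(["standard", "pc_fr"]))],
    },
    "questionnaires": {
        "sep": ",",
        "columns": ["participant", "instrument", "item", "rating"],
        "checks": [
            ("rating", lambda s: s.between(0, 4)),
        ],
    },
    "covariates": {
        "sep": ",",
        "columns": ["participant", "age", "sex"],
        "checks": [("age", lambda s: s.between(0, 120))],
    },
    "profiles": {
        "sep": "\t",
        "columns": ["participant", "tract", "hemisphere", "point_index", "value"],
        "checks": [
            ("hemisphere", lambda s: s.isin(["left", "right", "commissural"])),
        ],
    },
}


def validate_inputs(paths: dict[str, str | Path]) -> pd.DataFrame:
    """Schema-conformance report for user-supplied input files.

    ``paths`` maps a schema name (trials, questionnaires, covariates,
    profiles) to a file.  Each file is checked for required columns and
    value ranges; violations are reported per row.  Raises on any hard
    failure after writing the full report.
    """
    reports = []
    for kind, path in paths.items():
        schema = SCHEMAS[kind]
        path = Path(path)
        if not path.exists():
            reports.append({"file": str(path), "kind": kind, "status": "missing",
                            "detail": "file not found"})
            continue
        try:
            df = pd.read_csv(path, sep=schema["sep"])
        except Exception as e:  # malformed file
            reports.append({"file": str(path), "kind": kind, "status": "unreadable",
                            "detail": str(e)})
            continue
        if df.empty:
            reports.append({"file": str(path), "kind": kind, "status": "fail",
                            "detail": "empty file"})
            continue
        missing = [c for c in schema["columns"] if c not in df.columns]
        if missing:
            reports.append({"file": str(path), "kind": kind, "status": "fail",
                            "detail": f"missing columns: {missing}"})
            continue
        ok = True
        for col, check in schema["checks"]:
            bad = df.index[~check(df[col])].tolist()
            if bad:
                ok = False
                reports.append(
                    {"file": str(path), "kind": kind, "status": "fail",
                     "detail": f"column {col!r} violates range at rows {bad[:10]}"}
                )
        if ok:
            reports.append({"file": str(path), "kind": kind, "status": "pass",
                            "detail": ""})
    report = pd.DataFrame(reports)
    if (report["status"] != "pass").any():
        raise ValueError(
            "input validation failed:\n" + report.to_string(index=False)
        )
    return report
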