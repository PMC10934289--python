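"""End-to-end orchestration: ingest or synthesize -> features -> statistics ->
clustering -> reports, with seeded reproducibility and a run manifest.

Input modes
-----------
synthetic
    Draw an 84-participant cohort from the packaged three-group recipe (or a
    user YAML) and analyse it.
features
    Read an existing participant feature table (delimited text).
traces
    Read per-test IMU trace files listed in a JSON manifest, extract the
    seven parameters per participant, then join participant metadata.

Outputs (all delimited text / JSON, 2 dp in report tables, full precision in
JSON): the feature table, faller and frailty comparison tables, contingency
chi-square tables, the cluster model, a performance-level report, and a
manifest recording config, seed and package version.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import cluster_cohort, apply_equation
from .features import (
    FEATURE_COLUMNS,
    TestRecording,
    extract_features,
)
from .stats import ContingencyTable, compare_many, k_proportions_chi2
from .synthetic import (
    GroupSpec,
    default_cohort_spec,
    generate_cohort,
    read_cohort,
    read_trace,
    write_cohort,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "validate_cohort"]

log = logging.getLogger("imuperf")

_PHENOTYPES = ("robust", "pre-frail", "frail")
_FALLER_VALUES = ("yes", "no")


@dataclass
class RunConfig:
    """Configuration for one pipeline run (exactly one input mode)."""

    mode: str = "synthetic"  # synthetic | features | traces
    out_dir: str = "imuperf_out"
    seed: int = 0
    cohort_path: str | None = None  # features mode
    manifest_path: str | None = None  # traces mode
    cohort_spec_path: str | None = None  # synthetic mode override
    k_min: int = 2
    k_max: int = 8
    n_restarts: int = 50
    standardize: bool = False
    alpha: float = 0.05

    def validate(self) -> None:
        if self.mode not in ("synthetic", "features", "traces"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "features" and not self.cohort_path:
            raise ValueError("features mode requires cohort_path")
        if self.mode == "traces" and not self.manifest_path:
            raise ValueError("traces mode requires manifest_path")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)


@dataclass
class RunReport:
    """Paths and headline numbers from one run."""

    out_dir: str
    n_participants: int
    k_selected: int
    silhouette_by_k: dict
    level_counts: dict
    chi2_tables: dict
    artifacts: dict = field(default_factory=dict)


def validate_cohort(table: pd.DataFrame) -> list:
    """Range, vocabulary, and duplicate checks on a cohort table; returns issues."""
    issues = []
    if "participant_id" in table.columns:
        dup = table["participant_id"][table["participant_id"].duplicated()]
        for pid in dup.unique():
            issues.append(f"duplicate participant_id {pid!r}")
    if "faller" in table.columns:
        bad = set(table["faller"].dropna().unique()) - set(_FALLER_VALUES)
        for v in sorted(bad):
            issues.append(f"faller value {v!r} not in {_FALLER_VALUES}")
    if "frailty" in table.columns:
        bad = set(table["frailty"].dropna().unique()) - set(_PHENOTYPES)
        for v in sorted(bad):
            issues.append(f"frailty value {v!r} not in {_PHENOTYPES}")
    for col, lo, hi in [
        ("age", 18.0, 120.0),
        ("height_cm", 100.0, 230.0),
        ("body_mass_kg", 25.0, 250.0),
    ]:
        if col in table.columns:
            bad = table.loc[(table[col] < lo) | (table[col] > hi), col]
            for i, v in bad.items():
                issues.append(f"{col} out of range at row {i}: {v}")
    if {"height_cm", "body_mass_kg"} <= set(table.columns):
        bmi = table["body_mass_kg"] / (table["height_cm"] / 100.0) ** 2
        for i, v in bmi[(bmi < 10) | (bmi > 70)].items():
            issues.append(f"implausible BMI at row {i}: {v:.1f}")
    for col in FEATURE_COLUMNS:
        if col in table.columns:
            strict = col != "sts_count"
            bad = table.loc[table[col] < 0, col] if not strict else \
                table.loc[table[col] <= 0, col]
            for i, v in bad.items():
                issues.append(f"non-physiologic {col} at row {i}: {v}")
    return issues


def _load_traces_cohort(manifest_path: str) -> pd.DataFrame:
    """Extract features for every participant listed in a trace manifest.

    Manifest JSON: {"participants": [{"id": ..., "meta": {...}, "recordings":
    {"STS30": {"trace": path}, "6MWT": {"trace": path, "shuttle_marks": [...],
    "n_full_shuttles": int, "partial_m": float}, "TUG_COMFORT": {...},
    "TUG_FAST": {...}}}]}.  Paths are relative to the manifest.
    """
    mpath = Path(manifest_path)
    with open(mpath) as fh:
        manifest = json.load(fh)
    rows = []
    for part in manifest["participants"]:
        recs = {}
        for proto, entry in part["recordings"].items():
            tpath = mpath.parent / entry["trace"]
            try:
                trace = read_trace(tpath)
            except Exception as e:
                raise ValueError(f"malformed trace file {tpath}: {e}") from e
            recs[proto] = TestRecording(
                protocol=proto,
                trace=trace,
                shuttle_marks=tuple(entry.get("shuttle_marks", ())),
                n_full_shuttles=int(entry.get("n_full_shuttles", 0)),
                partial_m=float(entry.get("partial_m", 0.0)),
            )
        fv = extract_features(recs)
        rows.append({"participant_id": part["id"], **part.get("meta", {}), **fv.as_dict()})
    return pd.DataFrame(rows)


def _proportion_chi2_rows(cohort: pd.DataFrame, grouping: str) -> dict:
    """Chi-square homogeneity tests of faller and phenotype proportions."""
    labels = sorted(cohort[grouping].unique())
    totals = [int((cohort[grouping] == lab).sum()) for lab in labels]
    out = {}

    def add(name, successes):
        tab = ContingencyTable(tuple(labels), tuple(successes), tuple(totals))
        chi2, df, p = k_proportions_chi2(tab)
        out[name] = {
            "groups": labels, "successes": list(successes), "totals": totals,
            "chi2": chi2, "df": df, "p": p,
        }

    if "faller" in cohort.columns:
        add("faller", [int(((cohort[grouping] == lab) & (cohort["faller"] == "yes")).sum())
                       for lab in labels])
    if "frailty" in cohort.columns:
        for pheno in _PHENOTYPES:
            add(pheno, [int(((cohort[grouping] == lab) & (cohort["frailty"] == pheno)).sum())
                        for lab in labels])
    return out


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis and write all artifacts under config.out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run start: mode=%s seed=%d out=%s", config.mode, config.seed, out)

    if config.mode == "synthetic":
        if config.cohort_spec_path:
            with open(config.cohort_spec_path) as fh:
                cfg = yaml.safe_load(fh)
            groups = [GroupSpec(label=g["label"], n=int(g["n"]),
                                feature_means=g["feature_means"],
                                feature_sds=g["feature_sds"],
                                faller_prob=float(g["faller_prob"]),
                                frailty_probs=tuple(g["frailty_probs"]))
                      for g in cfg["groups"]]
        else:
            groups = default_cohort_spec()
        cohort = generate_cohort(groups, seed=config.seed)
    elif config.mode == "features":
        cohort = read_cohort(config.cohort_path)
    else:
        cohort = _load_traces_cohort(config.manifest_path)
    log.info("cohort: %d participants", len(cohort))

    issues = validate_cohort(cohort)
    for msg in issues:
        log.warning("cohort issue: %s", msg)

    artifacts = {}
    write_cohort(out / "features.csv", cohort)
    artifacts["features"] = str(out / "features.csv")

    # between-group statistics on observed labels
    chi2_tables = {}
    if "faller" in cohort.columns and cohort["faller"].nunique() > 1:
        tab = compare_many(cohort, FEATURE_COLUMNS, "faller", alpha=config.alpha)
        tab.to_csv(out / "comparison_fallers.csv", index=False, float_format="%.4g")
        artifacts["comparison_fallers"] = str(out / "comparison_fallers.csv")
    if "frailty" in cohort.columns and cohort["frailty"].nunique() > 1:
        tab = compare_many(cohort, FEATURE_COLUMNS, "frailty", alpha=config.alpha)
        tab.to_csv(out / "comparison_frailty.csv", index=False, float_format="%.4g")
        artifacts["comparison_frailty"] = str(out / "comparison_frailty.csv")
        chi2_tables["faller_by_frailty"] = _proportion_chi2_rows(cohort, "frailty")

    # clustering into performance levels
    X = cohort[FEATURE_COLUMNS].to_numpy(float)
    model = cluster_cohort(
        X, seed=config.seed, k_min=config.k_min, k_max=config.k_max,
        n_restarts=config.n_restarts, standardize=config.standardize,
    )
    log.info("selected k=%d (silhouettes: %s)", model.k,
             {k: round(v, 3) for k, v in model.silhouette_by_k.items()})
    cohort = cohort.copy()
    cohort["performance_level"] = model.levels()
    cohort["performance_score"] = [
        apply_equation(model.equation, dict(zip(FEATURE_COLUMNS, row)))
        for row in X
    ]
    write_cohort(out / "features_with_levels.csv", cohort)
    artifacts["features_with_levels"] = str(out / "features_with_levels.csv")
    (out / "cluster_model.json").write_text(model.to_json())
    artifacts["cluster_model"] = str(out / "cluster_model.json")

    # performance-level report (composition + proportions)
    level_order = [model.level_map[c] for c in sorted(model.level_map)]
    levels_sorted = sorted(
        cohort["performance_level"].unique(),
        key=lambda lv: level_order.index(lv) if lv in level_order else 99,
    )
    rows = []
    for lv in levels_sorted:
        sub = cohort[cohort["performance_level"] == lv]
        row = {"level": lv, "n": len(sub)}
        if "sex" in sub.columns:
            row["females_pct"] = round(100.0 * (sub["sex"] == "F").mean(), 2)
        for col in ("age", "height_cm", "body_mass_kg"):
            if col in sub.columns:
                row[col] = f"{sub[col].mean():.2f} ± {sub[col].std(ddof=1):.2f}"
        if "faller" in sub.columns:
            row["fallers_pct"] = round(100.0 * (sub["faller"] == "yes").mean(), 2)
        if "frailty" in sub.columns:
            for pheno in _PHENOTYPES:
                row[f"{pheno}_pct"] = round(100.0 * (sub["frailty"] == pheno).mean(), 2)
        row["score_mean"] = round(float(sub["performance_score"].mean()), 3)
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "cluster_report.csv", index=False)
    artifacts["cluster_report"] = str(out / "cluster_report.csv")

    if model.k >= 2 and cohort["performance_level"].nunique() > 1:
        tab = compare_many(cohort, FEATURE_COLUMNS, "performance_level", alpha=config.alpha)
        tab.to_csv(out / "comparison_performance.csv", index=False, float_format="%.4g")
        artifacts["comparison_performance"] = str(out / "comparison_performance.csv")
        chi2_tables["by_performance"] = _proportion_chi2_rows(cohort, "performance_level")

    with open(out / "chi2_tables.json", "w") as fh:
        json.dump(chi2_tables, fh, indent=1)
    artifacts["chi2_tables"] = str(out / "chi2_tables.json")

    manifest = {
        "package": "imuperf",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "n_participants": int(len(cohort)),
        "k_selected": int(model.k),
        "validation_issues": issues,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    artifacts["manifest"] = str(out / "manifest.json")

    level_counts = cohort["performance_level"].value_counts().to_dict()
    log.info("run complete: levels %s", level_counts)
    return RunReport(
        out_dir=str(out),
        n_participants=int(len(cohort)),
        k_selected=int(model.k),
        silhouette_by_k=model.silhouette_by_k,
        level_counts={str(k): int(v) for k, v in level_counts.items()},
        chi2_tables=chi2_tables,
        artifacts=artifacts,
    )
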