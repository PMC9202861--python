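"""End-to-end orchestration: structures + alignment -> fingerprints -> stats.

A run is described by a YAML config (paths, window, reference roles, stats
settings). Fingerprinting failures of individual targets are recorded and do
not abort the cohort run; the machine-readable run log lists inputs, seeds
and failures.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .geometry import (
    GeometryError,
    TightTurnDefinition,
    fingerprint,
    fingerprints_to_frame,
)
from .helix_mapping import (
    DEFAULT_TRIAD_POSITIONS,
    MappingError,
    map_reference_window,
    read_alignment,
    triad_check,
)
from .stats import (
    FEATURE_COLUMNS,
    StatsError,
    fit_threshold,
    lasso_fit,
    predict,
    summarize_groups,
    welch_t_test,
)
from .structure_io import StructureError, extract_backbone, read_pdb

__all__ = [
    "RunConfig",
    "TargetSpec",
    "ConfigError",
    "validate_config",
    "run_pipeline",
    "fingerprint_cohort",
]

log = logging.getLogger("helixprime")


class ConfigError(ValueError):
    """Raised for malformed or unresolvable run configs."""


VALID_PREDICTORS = {"AF2", "RF", "crystal", "synthetic", "unknown"}


@dataclass(frozen=True)
class TargetSpec:
    id: str
    path: Path
    predictor: str = "unknown"
    chain: str | None = None
    model: int = 1
    start_number: int = 1  # residue number of the first non-gap character


@dataclass
class RunConfig:
    targets: list[TargetSpec]
    references: dict[str, TargetSpec]  # role (1EMA/2AWJ/1H4U) -> spec
    alignment_path: Path
    reference_id: str  # alignment record anchoring the window numbering
    reference_start: int = 1
    window: tuple[int, int] = (60, 74)
    tight_turn: TightTurnDefinition = field(default_factory=TightTurnDefinition)
    triad_positions: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TRIAD_POSITIONS)
    )
    labels_path: Path | None = None
    #: CA-CA continuity check on target windows; off for cohorts with
    #: injected coordinate noise.
    check_continuity: bool = True
    folds: int = 5
    seed: int = 0
    lambda_grid: list[float] | None = None
    output_dir: Path = Path("helixprime_out")

    @property
    def window_positions(self) -> tuple[int, ...]:
        return tuple(range(self.window[0], self.window[1] + 1))


def _target_spec(entry: dict[str, Any], base: Path, role: str | None = None) -> TargetSpec:
    if "path" not in entry:
        raise ConfigError(f"structure entry lacks 'path': {entry}")
    path = (base / entry["path"]).resolve() if not Path(entry["path"]).is_absolute() else Path(entry["path"])
    if not path.exists():
        raise ConfigError(f"structure path does not exist: {path}")
    predictor = entry.get("predictor", "crystal" if role else "unknown")
    if predictor not in VALID_PREDICTORS:
        raise ConfigError(
            f"unknown predictor label {predictor!r} (expected one of {sorted(VALID_PREDICTORS)})"
        )
    return TargetSpec(
        id=entry.get("id", path.stem),
        path=path,
        predictor=predictor,
        chain=entry.get("chain"),
        model=int(entry.get("model", 1)),
        start_number=int(entry.get("start_number", 1)),
    )


def validate_config(path: str | Path) -> RunConfig:
    """Parse and fully resolve a YAML run config, filling defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = path.parent

    window = tuple(raw.get("window", (60, 74)))
    if len(window) != 2 or window[1] < window[0]:
        raise ConfigError(f"window must be [start, end] with start <= end, got {window}")
    if window[1] - window[0] + 1 > 15:
        raise ConfigError(
            f"window {window[0]}..{window[1]} exceeds 15 residues"
        )

    if "alignment" not in raw or "path" not in raw["alignment"]:
        raise ConfigError("config needs alignment: {path, reference_id}")
    aln_path = base / raw["alignment"]["path"]
    if not aln_path.exists():
        raise ConfigError(f"alignment path does not exist: {aln_path}")

    targets = [_target_spec(e, base) for e in raw.get("targets", [])]
    if not targets:
        raise ConfigError("config lists no targets")
    references = {
        role: _target_spec(entry, base, role)
        for role, entry in raw.get("references", {}).items()
    }
    for role in ("1EMA", "2AWJ", "1H4U"):
        if role not in references:
            raise ConfigError(f"missing reference role {role!r} in config")

    tt = raw.get("tight_turn", {})
    tight_turn = TightTurnDefinition(
        donor_position=int(tt.get("donor_position", 67)),
        donor_atom=tt.get("donor_atom", "N"),
        acceptor_position=int(tt.get("acceptor_position", 65)),
        acceptor_atom=tt.get("acceptor_atom", "C"),
    )
    triad = {**DEFAULT_TRIAD_POSITIONS, **raw.get("triad", {})}

    labels_path = None
    if raw.get("labels"):
        labels_path = base / raw["labels"]
        if not labels_path.exists():
            raise ConfigError(f"labels path does not exist: {labels_path}")

    stats_cfg = raw.get("stats", {})
    config = RunConfig(
        targets=targets,
        references=references,
        alignment_path=aln_path,
        reference_id=raw["alignment"].get("reference_id", "1EMA"),
        reference_start=int(raw["alignment"].get("reference_start", 1)),
        window=(int(window[0]), int(window[1])),
        tight_turn=tight_turn,
        triad_positions=triad,
        labels_path=labels_path,
        check_continuity=bool(raw.get("check_continuity", True)),
        folds=int(stats_cfg.get("folds", 5)),
        seed=int(stats_cfg.get("seed", 0)),
        lambda_grid=stats_cfg.get("lambda_grid"),
        output_dir=base / raw.get("output_dir", "helixprime_out"),
    )
    return config


def fingerprint_cohort(cohort) -> pd.DataFrame:
    """Fingerprint a synthetic cohort in memory (no files involved).

    Runs the same mapping -> extraction -> measurement route as the file
    pipeline: the cohort's identity alignment supplies the residue maps.
    The continuity check is skipped for members because they carry injected
    coordinate noise.
    """
    start = cohort.spec.window_start
    window = tuple(range(start, start + cohort.spec.n_residues))
    reference_segments = {}
    for role, ref in cohort.references.items():
        rmap = map_reference_window(
            cohort.alignment, ref.id, reference_start=start, target_start=start,
            window=window,
        )
        reference_segments[role] = extract_backbone(
            ref, rmap.target_numbers, reference_positions=rmap.reference_positions
        )
    fingerprints = []
    for tid, st in cohort.structures.items():
        rmap = map_reference_window(
            cohort.alignment, tid, reference_start=start, target_start=start,
            window=window,
        )
        fingerprints.append(
            fingerprint(
                st, rmap, reference_segments, predictor="synthetic",
                label=cohort.labels[tid], check_continuity=False,
            )
        )
    return fingerprints_to_frame(fingerprints)


def _config_provenance(config: RunConfig) -> dict[str, Any]:
    def enc(obj: Any) -> Any:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj

    return enc(config)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the full analysis and write the fixed-schema outputs.

    Writes fingerprints.csv always; when labels are provided, additionally
    summaries.csv, welch.csv (per feature), threshold.json,
    lasso_coefficients.csv, lasso_path.csv and predictions.csv. Returns the
    run report (also written as run_log.json): inputs, versions, seeds,
    per-target failures and headline statistics.
    """
    t0 = time.time()
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    alignment = read_alignment(config.alignment_path, config.reference_id)

    # reference helix windows
    reference_segments = {}
    for role, spec in config.references.items():
        st = read_pdb(spec.path, model_number=spec.model, chain_id=spec.chain,
                      structure_id=spec.id)
        rmap = map_reference_window(
            alignment, spec.id, reference_start=config.reference_start,
            target_start=spec.start_number, window=config.window_positions,
        )
        reference_segments[role] = extract_backbone(
            st, rmap.target_numbers, chain_id=spec.chain,
            reference_positions=rmap.reference_positions,
        )

    labels: dict[str, str] = {}
    if config.labels_path is not None:
        truth = pd.read_csv(config.labels_path)
        labels = dict(zip(truth["target_id"], truth["label"]))

    fingerprints = []
    triads = []
    failures: list[dict[str, str]] = []
    for spec in config.targets:
        try:
            st = read_pdb(spec.path, model_number=spec.model, chain_id=spec.chain,
                          structure_id=spec.id)
            rmap = map_reference_window(
                alignment, spec.id, reference_start=config.reference_start,
                target_start=spec.start_number, window=config.window_positions,
            )
            fingerprints.append(
                fingerprint(
                    st, rmap, reference_segments,
                    predictor=spec.predictor,
                    label=labels.get(spec.id, "unknown"),
                    tight_turn_def=config.tight_turn,
                    chain_id=spec.chain,
                    check_continuity=config.check_continuity,
                )
            )
            triads.append(
                triad_check(alignment, spec.id, reference_start=config.reference_start,
                            positions=config.triad_positions)
            )
        except (StructureError, MappingError, GeometryError) as exc:
            log.warning("target %s failed: %s", spec.id, exc)
            failures.append({"target_id": spec.id, "error": str(exc)})
    if not fingerprints:
        raise ConfigError("zero targets were successfully fingerprinted")

    table = fingerprints_to_frame(fingerprints)
    table.to_csv(out / "fingerprints.csv", index=False, float_format="%.3f")
    pd.DataFrame(
        [
            {
                "target_id": t.target_id,
                "gly_at_triad_gly": t.gly_at_triad_gly,
                "aromatic_at_66": t.aromatic_at_66,
                "arg_at_96": t.arg_at_96,
                "verdict": t.verdict,
            }
            for t in triads
        ]
    ).to_csv(out / "triad_report.csv", index=False)

    report: dict[str, Any] = {
        "package_version": __version__,
        "config": _config_provenance(config),
        "n_targets": len(config.targets),
        "n_fingerprinted": len(fingerprints),
        "failures": failures,
        "n_warnings": len(failures),
    }

    labeled = table[table["label"].isin(["can_form", "cannot_form"])]
    if len(labeled) >= 4 and labeled["label"].nunique() == 2:
        stats_report = _run_stats(labeled, config, out)
        report.update(stats_report)

    report["runtime_s"] = round(time.time() - t0, 3)
    with open(out / "run_log.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    # echo resolved config for provenance
    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(_config_provenance(config), fh)
    return report


def _run_stats(labeled: pd.DataFrame, config: RunConfig, out: Path) -> dict[str, Any]:
    values = labeled["rmsd_vs_1EMA"].to_numpy()
    labs = labeled["label"].to_numpy()

    summaries = summarize_groups(values, labs)
    pd.DataFrame([dataclasses.asdict(s) for s in summaries.values()]).to_csv(
        out / "summaries.csv", index=False
    )

    welch_rows = []
    for feat in FEATURE_COLUMNS:
        if feat not in labeled.columns:
            continue
        x = labeled.loc[labeled["label"] == "cannot_form", feat].to_numpy()
        y = labeled.loc[labeled["label"] == "can_form", feat].to_numpy()
        try:
            res = welch_t_test(x, y)
            welch_rows.append(
                {"feature": feat, "t": res.t, "df": res.df, "p": res.p}
            )
        except StatsError as exc:
            welch_rows.append({"feature": feat, "t": float("nan"),
                               "df": float("nan"), "p": float("nan"),
                               "note": str(exc)})
    pd.DataFrame(welch_rows).to_csv(out / "welch.csv", index=False)

    rule = fit_threshold(values, labs)
    with open(out / "threshold.json", "w") as fh:
        json.dump(dataclasses.asdict(rule), fh, indent=2)
    threshold_pred = predict(rule, labeled)
    threshold_acc = float((threshold_pred.to_numpy() == labs).mean())

    features = labeled[[c for c in FEATURE_COLUMNS if c in labeled.columns]]
    model = lasso_fit(
        features, labs, lambda_grid=config.lambda_grid,
        folds=config.folds, seed=config.seed,
    )
    model.coefficient_table().to_csv(out / "lasso_coefficients.csv", index=False)
    if model.lambda_path is not None:
        model.lambda_path.to_csv(out / "lasso_path.csv", index=False)
    prob = predict(model, features)
    predictions = pd.DataFrame(
        {
            "target_id": labeled["target_id"].to_numpy(),
            "label": labs,
            "threshold_class": threshold_pred.to_numpy(),
            "lasso_p_can_form": prob.to_numpy(),
            "lasso_class": (prob.to_numpy() >= 0.5),
        }
    )
    predictions["lasso_class"] = predictions["lasso_class"].map(
        {True: "can_form", False: "cannot_form"}
    )
    predictions.to_csv(out / "predictions.csv", index=False)
    lasso_acc = float((predictions["lasso_class"] == predictions["label"]).mean())

    welch_rmsd = next(r for r in welch_rows if r["feature"] == "rmsd_vs_1EMA")
    return {
        "group_means_rmsd_vs_1EMA": {
            g: s.mean for g, s in summaries.items()
        },
        "welch_rmsd_vs_1EMA": {k: welch_rmsd[k] for k in ("t", "df", "p")},
        "threshold_cutoff": rule.cutoff,
        "threshold_training_accuracy": threshold_acc,
        "lasso_selected_features": model.selected_features,
        "lasso_training_accuracy": lasso_acc,
    }
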