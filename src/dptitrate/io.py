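"""File formats, run configuration and the end-to-end pipeline.

All tabular artifacts are comma-separated, dot-decimal, UTF-8 CSV with a
required header; units are embedded in column names (``volume_ml``,
``pmean_cmh2o``, ``il6_pgml`` ...) so values never travel without them.
Reports are written deterministically (stable column order, floats at 4
significant digits) in CSV, JSON or Markdown, and everything the package
writes can be read back into an equal in-memory value.

``run_pipeline`` chains the full workflow: simulate a two-arm cohort,
titrate every animal's inflation maneuver, apply the arm's driving-pressure
policy (standard: fixed 14 cmH2O; individualized: the recommended DP),
compare all outcomes across arms, and record every artifact in a manifest.
A single global seed drives everything through per-stage substreams, so a
(config, seed) pair fully determines the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .mechanics import (
    ARM_INDIVIDUALIZED,
    ARM_STANDARD,
    AnimalRecord,
    ArmSpec,
    CohortConfig,
    LungParamRanges,
    OutcomeSpec,
    PVManeuver,
    default_outcome_specs,
    simulate_cohort,
)
from .outcomes import ALI_ITEMS, AliRatings, BloodGas, ali_aggregate, classify_berlin, pf_ratio
from .stats import study_report
from .titration import (
    ElasticPoint,
    VentSettings,
    detect_elastic_point,
    recommend_dp,
    recommend_peep,
)

__all__ = [
    "MANEUVER_COLUMNS",
    "RunConfig",
    "RunManifest",
    "read_maneuver_csv",
    "read_maneuvers_csv",
    "write_maneuvers_csv",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_ali_csv",
    "read_ali_csv",
    "write_report",
    "read_report",
    "write_elastic_points",
    "elastic_point_to_dict",
    "load_config",
    "config_to_dict",
    "run_pipeline",
    "log_setup",
    "STANDARD_DP_CMH2O",
]

logger = logging.getLogger("dptitrate")

MANEUVER_COLUMNS = ["subject_id", "limb", "step_index", "volume_ml", "pmean_cmh2o"]
REPORT_FORMATS = ("csv", "json", "md")
STANDARD_DP_CMH2O = 14.0  # the conventional protective DP of the standard arm


# ---------------------------------------------------------------------------
# float formatting: 4 significant digits everywhere a report is serialized


def _fmt(x) -> str:
    if isinstance(x, float):
        if x != x:
            return "nan"
        return format(x, ".4g")
    return str(x)


def _round4(x):
    if isinstance(x, float) and np.isfinite(x):
        return float(format(x, ".4g"))
    return x


# ---------------------------------------------------------------------------
# maneuver CSV


def write_maneuvers_csv(maneuvers: Sequence[PVManeuver], path) -> int:
    """Write one or more maneuvers to the maneuver CSV schema; returns rows."""
    rows = []
    for m in maneuvers:
        for i, (v, p) in enumerate(m.points):
            rows.append(
                {
                    "subject_id": m.subject_id,
                    "limb": m.limb,
                    "step_index": i,
                    "volume_ml": v,
                    "pmean_cmh2o": p,
                }
            )
    df = pd.DataFrame(rows, columns=MANEUVER_COLUMNS)
    # %.17g keeps float64 round-trips lossless
    df.to_csv(path, index=False, encoding="utf-8", float_format="%.17g", lineterminator="\n")
    return len(df)


def _maneuver_from_frame(df: pd.DataFrame, path) -> PVManeuver:
    sid = df["subject_id"].iloc[0]
    limb = df["limb"].iloc[0]
    vols = df["volume_ml"].to_numpy(dtype=float)
    dupes = df[df["volume_ml"].duplicated(keep=False)]
    if len(dupes):
        rows = ", ".join(str(i) for i in dupes.index.tolist())
        raise ValueError(f"{path}: duplicate volume_ml values at rows {rows}")
    order = np.argsort(vols)
    vols = vols[order]
    press = df["pmean_cmh2o"].to_numpy(dtype=float)[order]
    steps = np.diff(vols)
    step = float(np.median(steps)) if len(steps) else 1.0
    return PVManeuver(subject_id=str(sid), limb=str(limb), v=vols, p=press, step=step)


def _read_maneuver_frame(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    missing = [c for c in MANEUVER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("volume_ml", "pmean_cmh2o"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        if bad or coerced.isna().any():
            bad = bad or df.index[coerced.isna()].tolist()
            raise ValueError(f"{path}: non-numeric value in column {col!r} at rows {bad}")
        df[col] = coerced
    return df


def read_maneuver_csv(path) -> PVManeuver:
    """Read a single-maneuver CSV (one subject, one limb); rows may be in
    any order and are re-sorted by volume."""
    df = _read_maneuver_frame(path)
    keys = df[["subject_id", "limb"]].drop_duplicates()
    if len(keys) != 1:
        raise ValueError(
            f"{path}: expected exactly one (subject_id, limb) pair, found {len(keys)}"
        )
    return _maneuver_from_frame(df, path)


def read_maneuvers_csv(path) -> dict[tuple[str, str], PVManeuver]:
    """Read a multi-maneuver CSV keyed by (subject_id, limb)."""
    df = _read_maneuver_frame(path)
    out: dict[tuple[str, str], PVManeuver] = {}
    for (sid, limb), grp in df.groupby(["subject_id", "limb"], sort=False):
        out[(str(sid), str(limb))] = _maneuver_from_frame(grp.reset_index(drop=True), path)
    return out


# ---------------------------------------------------------------------------
# cohort and ALI CSV


def write_cohort_csv(df: pd.DataFrame, path) -> int:
    df.to_csv(path, index=False, encoding="utf-8", float_format="%.17g", lineterminator="\n")
    return len(df)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    for col in ("subject_id", "arm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


def write_ali_csv(records: Sequence[AnimalRecord], path) -> int:
    """Long-form ALI ratings: subject_id, rater, item, score."""
    rows = [
        {"subject_id": r.subject_id, "rater": rater, "item": item, "score": score}
        for r in records
        for rater, items in r.ali_ratings.items()
        for item, score in items.items()
    ]
    df = pd.DataFrame(rows, columns=["subject_id", "rater", "item", "score"])
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
    return len(df)


def read_ali_csv(path) -> dict[str, AliRatings]:
    df = pd.read_csv(path, encoding="utf-8")
    required = ["subject_id", "rater", "item", "score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out: dict[str, AliRatings] = {}
    for sid, grp in df.groupby("subject_id", sort=False):
        ratings: dict[str, dict[str, int]] = {}
        for _, row in grp.iterrows():
            ratings.setdefault(str(row["rater"]), {})[str(row["item"])] = int(row["score"])
        out[str(sid)] = AliRatings(subject_id=str(sid), ratings=ratings)
    return out


# ---------------------------------------------------------------------------
# elastic points and reports


def elastic_point_to_dict(ep: ElasticPoint) -> dict:
    d = dataclasses.asdict(ep)
    return {k: _round4(v) if isinstance(v, float) else v for k, v in d.items()}


def write_elastic_points(points: Mapping[str, ElasticPoint], path) -> int:
    payload = {sid: elastic_point_to_dict(ep) for sid, ep in sorted(points.items())}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    return len(payload)


def write_report(report: pd.DataFrame, path, format: str = "csv") -> dict:
    """Serialize a report deterministically; returns a manifest entry.

    Column/key order is the frame's order; floats carry 4 significant
    digits; writing the same report twice gives byte-identical files.
    """
    path = Path(path)
    if format == "csv":
        report.to_csv(path, index=False, encoding="utf-8", float_format="%.4g",
                      lineterminator="\n")
    elif format == "json":
        payload = {
            "rows": [
                {k: _round4(v) for k, v in row.items()} for row in report.to_dict("records")
            ],
            "footer": report.attrs.get("footer", ""),
        }
        path.write_text(json.dumps(payload, indent=2, allow_nan=True) + "\n", encoding="utf-8")
    elif format == "md":
        cols = list(report.columns)
        lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
        for _, row in report.iterrows():
            lines.append("| " + " | ".join(_fmt(row[c]) for c in cols) + " |")
        footer = report.attrs.get("footer", "")
        if footer:
            lines += ["", footer]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown format {format!r}; supported: {', '.join(REPORT_FORMATS)}")
    return {"path": str(path), "rows": int(len(report)), "format": format}


def read_report(path, format: Optional[str] = None) -> pd.DataFrame:
    """Read back a report written by :func:`write_report`."""
    path = Path(path)
    format = format or path.suffix.lstrip(".")
    if format == "csv":
        return pd.read_csv(path, encoding="utf-8")
    if format == "json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        df = pd.DataFrame(payload["rows"])
        df.attrs["footer"] = payload.get("footer", "")
        return df
    if format == "md":
        lines = [l for l in path.read_text(encoding="utf-8").splitlines() if l.startswith("|")]
        header = [c.strip() for c in lines[0].strip("|").split("|")]
        rows = []
        for line in lines[2:]:
            cells = [c.strip() for c in line.strip("|").split("|")]
            row = {}
            for col, cell in zip(header, cells):
                try:
                    row[col] = float(cell)
                except ValueError:
                    row[col] = cell
            rows.append(row)
        return pd.DataFrame(rows, columns=header)
    raise ValueError(f"unknown format {format!r}; supported: {', '.join(REPORT_FORMATS)}")


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration of an end-to-end run."""

    seed: int = 0
    output_dir: str = "results/run"
    log_level: str = "info"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    titration_method: str = "piecewise"
    report_formats: tuple[str, ...] = ("csv", "json", "md")
    holm: bool = False

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        if self.titration_method not in ("piecewise", "max_acceleration"):
            raise ValueError(f"unknown titration method {self.titration_method!r}")
        for f in self.report_formats:
            if f not in REPORT_FORMATS:
                raise ValueError(f"unknown report format {f!r}")


@dataclass
class RunManifest:
    seed: int
    config_hash: str
    version: str
    created: str
    artifacts: dict[str, dict] = field(default_factory=dict)


def _outcome_spec_to_dict(spec: OutcomeSpec) -> dict:
    return {
        "name": spec.name,
        "family": spec.family,
        "arms": {a: dataclasses.asdict(s) for a, s in spec.arms.items()},
    }


def config_to_dict(config: RunConfig) -> dict:
    c = config.cohort
    return {
        "seed": config.seed,
        "output_dir": config.output_dir,
        "log_level": config.log_level,
        "titration": {"method": config.titration_method},
        "analysis": {"holm": config.holm, "report_formats": list(config.report_formats)},
        "simulation": {
            "n_per_arm": c.n_per_arm,
            "v_max": c.v_max,
            "step": c.step,
            "weight_mean_g": c.weight_mean_g,
            "weight_sd_g": c.weight_sd_g,
            "fio2": c.fio2,
            "raters": list(c.raters),
            "rater_correlation": c.rater_correlation,
            "arms": {a: dataclasses.asdict(r) for a, r in c.arms.items()},
            "outcomes": [_outcome_spec_to_dict(s) for s in c.outcomes],
        },
    }


def _config_from_dict(d: Mapping) -> RunConfig:
    sim = d.get("simulation", {})
    arms_d = sim.get("arms")
    if arms_d:
        arms = {}
        for a, r in arms_d.items():
            r = dict(r)
            for key in ("dp_target", "v_el", "gamma", "hysteresis", "peep_choices", "peep_probs"):
                if key in r:
                    r[key] = tuple(r[key])
            arms[a] = LungParamRanges(**r)
    else:
        arms = {ARM_STANDARD: LungParamRanges(), ARM_INDIVIDUALIZED: LungParamRanges()}
    outcomes_d = sim.get("outcomes")
    if outcomes_d is not None:
        outcomes = [
            OutcomeSpec(
                name=o["name"],
                family=o["family"],
                arms={a: ArmSpec(**s) for a, s in o["arms"].items()},
            )
            for o in outcomes_d
        ]
    else:
        outcomes = default_outcome_specs()
    seed = int(d.get("seed", 0))
    cohort = CohortConfig(
        n_per_arm=int(sim.get("n_per_arm", 10)),
        seed=seed,
        arms=arms,
        outcomes=outcomes,
        raters=tuple(sim.get("raters", ("rater_1", "rater_2"))),
        rater_correlation=float(sim.get("rater_correlation", 0.8)),
        v_max=float(sim.get("v_max", 14.0)),
        step=float(sim.get("step", 1.0)),
        weight_mean_g=float(sim.get("weight_mean_g", 357.0)),
        weight_sd_g=float(sim.get("weight_sd_g", 21.0)),
        fio2=float(sim.get("fio2", 0.8)),
    )
    analysis = d.get("analysis", {})
    return RunConfig(
        seed=seed,
        output_dir=str(d.get("output_dir", "results/run")),
        log_level=str(d.get("log_level", "info")),
        cohort=cohort,
        titration_method=str(d.get("titration", {}).get("method", "piecewise")),
        report_formats=tuple(analysis.get("report_formats", ("csv", "json", "md"))),
        holm=bool(analysis.get("holm", False)),
    )


def load_config(path, seed: Optional[int] = None, output_dir: Optional[str] = None) -> RunConfig:
    """Load a JSON or YAML run configuration (by file extension).

    ``seed`` and ``output_dir`` override the file's values when given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        d = json.loads(text)
    elif path.suffix.lower() in (".yaml", ".yml"):
        d = yaml.safe_load(text)
    else:
        raise ValueError(f"config must be .json or .yaml, got {path.suffix!r}")
    d = dict(d or {})
    if seed is not None:
        d["seed"] = seed
    if output_dir is not None:
        d["output_dir"] = output_dir
    return _config_from_dict(d)


def config_hash(config: RunConfig) -> str:
    canon = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()


# ---------------------------------------------------------------------------
# logging


_LEVELS = {"debug": logging.DEBUG, "info": logging.INFO, "warning": logging.WARNING,
           "error": logging.ERROR}


def log_setup(level: str = "info") -> logging.Logger:
    """Configure structured logging to stderr; results never go to the log."""
    if level not in _LEVELS:
        raise ValueError(f"unknown log level {level!r}; use one of {sorted(_LEVELS)}")
    logger.handlers.clear()
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(_LEVELS[level])
    logger.propagate = False
    return logger


# ---------------------------------------------------------------------------
# end-to-end pipeline


def titrate_cohort(
    records: Sequence[AnimalRecord], method: str = "piecewise"
) -> tuple[dict[str, ElasticPoint], pd.DataFrame]:
    """Titrate every animal: elastic point, DP policy and PEEP recommendation.

    Returns the per-subject elastic points and a per-subject frame with the
    achieved DP (standard arm: fixed 14 cmH2O; individualized arm: the
    rounded recommendation, falling back to 14 when no plastic transition
    was detectable), the recommended expiratory PEEP, and derived outcomes
    (P/F ratio, Berlin class, ALI scores).
    """
    points: dict[str, ElasticPoint] = {}
    rows = []
    for rec in records:
        ep = detect_elastic_point(rec.inflation, method=method)
        points[rec.subject_id] = ep
        peep_rec = recommend_peep(rec.deflation)

        note = ""
        if rec.arm == ARM_STANDARD:
            dp_achieved = STANDARD_DP_CMH2O
        elif ep.ok:
            settings = VentSettings(peep=rec.params.peep, weight_g=rec.weight_g)
            dp_achieved = recommend_dp(ep, settings).dp
        else:
            dp_achieved = STANDARD_DP_CMH2O
            note = "no plastic transition; standard DP applied"
            logger.warning("subject %s: %s", rec.subject_id, note)

        row = {
            "subject_id": rec.subject_id,
            "arm": rec.arm,
            "weight_g": rec.weight_g,
            "dp_achieved_cmh2o": dp_achieved,
            "peep_set_cmh2o": rec.params.peep,
            "peep_recommended_cmh2o": peep_rec.peep,
            "note": note,
        }

        if "pao2_mmhg" in rec.outcomes:
            gas = BloodGas(
                pao2=rec.outcomes["pao2_mmhg"],
                fio2=0.8,
                peep_at_measurement=rec.params.peep,
            )
            pf = pf_ratio(gas)
            row["pf_ratio_mmhg"] = pf
            row["berlin"] = classify_berlin(pf, rec.params.peep)

        row.update(rec.outcomes)

        if rec.ali_ratings and all(
            set(items) == set(ALI_ITEMS) for items in rec.ali_ratings.values()
        ):
            score = ali_aggregate(
                AliRatings(subject_id=rec.subject_id, ratings=rec.ali_ratings)
            )
            for item, mean in score.item_means.items():
                row[f"ali_{item}"] = mean
            row["ali_global"] = score.global_score
        rows.append(row)
    return points, pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Simulate, titrate, analyze and persist a full study run.

    Outputs under ``config.output_dir``: ``maneuvers.csv``, ``cohort.csv``,
    ``ali.csv``, ``elastic_points.json``, ``report.{csv,json,md}`` and
    ``manifest.json``.  Identical (config, seed) pairs reproduce the report
    files byte for byte; only manifest timestamps differ between runs.
    """
    log = log_setup(config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        seed=config.seed,
        config_hash=config_hash(config),
        version=__version__,
        created=datetime.now(timezone.utc).isoformat(),
    )

    stage = "simulate"
    try:
        log.info("stage %s: start (n_per_arm=%d, seed=%d)",
                 stage, config.cohort.n_per_arm, config.seed)
        records = simulate_cohort(config.cohort)
        log.info("stage %s: done (%d animals)", stage, len(records))

        stage = "titrate"
        log.info("stage %s: start (method=%s)", stage, config.titration_method)
        points, cohort_df = titrate_cohort(records, method=config.titration_method)
        log.info("stage %s: done", stage)

        stage = "analyze"
        log.info("stage %s: start", stage)
        qualitative = None
        if "berlin" in cohort_df.columns:
            qualitative = {"berlin_severe": cohort_df["berlin"] == "severe"}
        report = study_report(
            cohort_df.drop(columns=["weight_g"], errors="ignore"),
            qualitative=qualitative,
            holm=config.holm,
        )
        log.info("stage %s: done (%d comparisons)", stage, len(report))

        stage = "write"
        maneuvers = [m for r in records for m in (r.inflation, r.deflation)]
        n = write_maneuvers_csv(maneuvers, outdir / "maneuvers.csv")
        manifest.artifacts["maneuvers"] = {"path": str(outdir / "maneuvers.csv"), "rows": n}
        n = write_cohort_csv(cohort_df, outdir / "cohort.csv")
        manifest.artifacts["cohort"] = {"path": str(outdir / "cohort.csv"), "rows": n}
        n = write_ali_csv(records, outdir / "ali.csv")
        manifest.artifacts["ali"] = {"path": str(outdir / "ali.csv"), "rows": n}
        n = write_elastic_points(points, outdir / "elastic_points.json")
        manifest.artifacts["elastic_points"] = {
            "path": str(outdir / "elastic_points.json"), "rows": n
        }
        for fmt in config.report_formats:
            entry = write_report(report, outdir / f"report.{fmt}", fmt)
            manifest.artifacts[f"report_{fmt}"] = entry
        log.info("stage %s: done (%d artifacts)", stage, len(manifest.artifacts))
    except Exception as exc:
        manifest.artifacts["error"] = {"stage": stage, "message": str(exc)}
        _write_manifest(manifest, outdir / "manifest.json")
        log.error("stage %s failed: %s", stage, exc)
        raise

    _write_manifest(manifest, outdir / "manifest.json")
    return manifest


def _write_manifest(manifest: RunManifest, path) -> None:
    Path(path).write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2) + "\n", encoding="utf-8"
    )
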