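"""Pipeline orchestration: simulate -> score -> metrics -> design -> fit -> report.

Each stage reads the previous stage's CSVs from a working directory and
writes its own, so every stage is runnable standalone; :func:`run_pipeline`
chains them and writes a run manifest (seed, config hash, row counts,
exclusion summary, output paths). Identical (config, seed, inputs) produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .affect_metrics import ALL_ITEMS, profile_table
from .errors import AffectVarError, ConfigError, ValidationError
from .growth_design import CODE_COLUMNS, ChangeDesign, attach_design
from .growth_models import (
    COVARIATES,
    GrowthFit,
    ModelSpec,
    hypothesis_report,
    model_sequence,
    simple_slopes,
)
from .performance_scoring import (
    exclusion_screen,
    score_effort_table,
    score_trial_table,
    vge_composite,
)
from .synthetic_data import SimConfig, generate_study, write_csv_bundle

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "STAGES"]

log = logging.getLogger("affectvar")

STAGES = ("simulate", "score", "metrics", "design", "fit", "report")


@dataclass
class RunConfig:
    """A pipeline run: either a simulation block or input CSV paths, never both."""

    outdir: str
    seed: int = 0
    simulation: dict | None = None
    inputs: dict | None = None  # paths: persons, affect_long, trials, outcomes_long
    design: dict = field(default_factory=dict)  # n_sessions, change_after
    metrics: dict = field(default_factory=dict)  # spin_variant, ddof
    flatline_threshold: int = 2
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.simulation is None) == (self.inputs is None):
            raise ConfigError(
                "config must have exactly one of a 'simulation' block or an 'inputs' block"
            )
        if self.inputs is not None:
            missing = {"persons", "affect_long", "trials"} - set(self.inputs)
            if missing:
                raise ConfigError(f"inputs block missing paths for {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None,
                  outdir: str | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if seed is not None:
            raw["seed"] = seed
        if outdir is not None:
            raw["outdir"] = outdir
        if "outdir" not in raw:
            raise ConfigError("config must set outdir (or pass --out)")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def change_design(self) -> ChangeDesign:
        return ChangeDesign(
            n_sessions=int(self.design.get("n_sessions", 14)),
            change_after=int(self.design.get("change_after", 7)),
        )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _violation(table, row, column, message):
    return {"table": table, "row": row, "column": column, "message": message}


def validate_inputs(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Schema, range and referential checks across the input bundle.

    Returns a report table (possibly empty) listing every violation with its
    table/row/column coordinates; it never raises on data problems.
    """
    out: list[dict] = []
    persons = tables.get("persons")
    known_pids = set(persons["participant_id"]) if persons is not None else None

    affect = tables.get("affect_long")
    if affect is not None:
        rating_cols = [c for c in affect.columns if c in ALL_ITEMS or c in ("PA", "PD", "NA", "ND")]
        for c in rating_cols:
            bad = ~affect[c].between(1, 9)
            out += [
                _violation("affect_long", int(i), c, f"rating {affect.at[i, c]} outside [1, 9]")
                for i in affect.index[bad]
            ]
        if "session_index" in affect.columns:
            dup = affect.duplicated(subset=["participant_id", "session_index"])
            out += [
                _violation("affect_long", int(i), "session_index", "duplicate participant-session")
                for i in affect.index[dup]
            ]

    trials = tables.get("trials")
    if trials is not None:
        for c in ("kills", "deaths"):
            if c in trials.columns:
                bad = trials[c] < 0
                out += [
                    _violation("trials", int(i), c, "negative count")
                    for i in trials.index[bad]
                ]

    for name in ("affect_long", "trials", "outcomes_long"):
        t = tables.get(name)
        if t is not None and known_pids is not None and "participant_id" in t.columns:
            orphan = ~t["participant_id"].isin(known_pids)
            for i in t.index[orphan]:
                out.append(
                    _violation(
                        name, int(i), "participant_id",
                        f"participant {t.at[i, 'participant_id']} absent from persons",
                    )
                )

    eff = tables.get("outcomes_long")
    if eff is not None and "effort" in eff.columns:
        bad = ~eff["effort"].between(-10, 30)  # generated effort is unbounded; flag absurd values
        out += [
            _violation("outcomes_long", int(i), "effort", "implausible effort value")
            for i in eff.index[bad]
        ]
    return pd.DataFrame(out, columns=["table", "row", "column", "message"])


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False)
    return path


def stage_simulate(cfg: RunConfig, outdir: Path) -> dict[str, str]:
    sim_kwargs = dict(cfg.simulation or {})
    sim_kwargs.setdefault("seed", cfg.seed)
    study = generate_study(SimConfig(**sim_kwargs))
    log.info("simulated %d participants x %d sessions",
             study.persons.shape[0], int(study.outcomes_long["session_index"].max()))
    return write_csv_bundle(study, outdir)


def stage_score(cfg: RunConfig, outdir: Path) -> dict[str, str]:
    trials = pd.read_csv(outdir / "trials.csv")
    sessions = score_trial_table(trials)
    design = cfg.change_design()
    excl = exclusion_screen(sessions, design.n_sessions, cfg.flatline_threshold)
    out_long = outdir / "outcomes_long.csv"
    if out_long.exists():
        eff = score_effort_table(pd.read_csv(out_long))
        sessions = sessions.merge(eff, on=["participant_id", "session_index"], how="left")
    persons_path = outdir / "persons.csv"
    if persons_path.exists():
        persons = pd.read_csv(persons_path)
        if "vge" not in persons.columns and "vge_freq_any" in persons.columns:
            persons["vge"] = vge_composite(persons)
            _write(persons, persons_path)
    n_drop = int((~excl["keep"]).sum())
    log.info("scored %d session rows; excluded %d participants", len(sessions), n_drop)
    return {
        "sessions": str(_write(sessions, outdir / "sessions.csv")),
        "exclusions": str(_write(excl, outdir / "exclusions.csv")),
    }


def stage_metrics(cfg: RunConfig, outdir: Path) -> dict[str, str]:
    affect = pd.read_csv(outdir / "affect_long.csv")
    profiles = profile_table(
        affect,
        spin_variant=cfg.metrics.get("spin_variant", "circular_sd"),
        ddof=int(cfg.metrics.get("ddof", 1)),
    )
    log.info("computed variability profiles for %d participants", len(profiles))
    return {"profiles": str(_write(profiles, outdir / "profiles.csv"))}


def stage_design(cfg: RunConfig, outdir: Path) -> dict[str, str]:
    sessions = pd.read_csv(outdir / "sessions.csv")
    profiles = pd.read_csv(outdir / "profiles.csv")
    persons = pd.read_csv(outdir / "persons.csv")
    excl = pd.read_csv(outdir / "exclusions.csv")
    keep = set(excl.loc[excl["keep"], "participant_id"])
    sessions = sessions[sessions["participant_id"].isin(keep)]
    prof_cols = [
        "participant_id", "spin", "pulse", "valence_variability", "activation_variability",
    ]
    person_cols = ["participant_id"] + [c for c in COVARIATES if c in persons.columns]
    long = (
        sessions.merge(profiles[prof_cols], on="participant_id", how="left")
        .merge(persons[person_cols], on="participant_id", how="left")
    )
    long = attach_design(long, cfg.change_design())
    log.info("analysis table: %d rows, %d participants",
             len(long), long["participant_id"].nunique())
    return {"analysis_long": str(_write(long, outdir / "analysis_long.csv"))}


def _fit_outputs(fits: list[GrowthFit], comparison: pd.DataFrame,
                 outcome: str, outdir: Path) -> dict[str, str]:
    paths = {}
    for f in fits:
        tab = f.table.copy()
        tab["model"] = f.spec.name
        tab["outcome"] = f.spec.outcome
        tab["loglik"] = f.loglik
        tab["tau2"] = f.tau2
        tab["sigma2"] = f.sigma2
        tab["n_obs"] = f.n_obs
        tab["n_participants"] = f.n_participants
        paths[f"coef_{f.spec.name}"] = str(_write(tab, outdir / f"coef_{f.spec.name}.csv"))
    paths[f"loglik_{outcome}"] = str(
        _write(comparison, outdir / f"loglik_comparison_{outcome}.csv")
    )
    return paths


def stage_fit(cfg: RunConfig, outdir: Path) -> dict[str, str]:
    long = pd.read_csv(outdir / "analysis_long.csv")
    paths = {}
    for outcome in ("effort", "performance"):
        fits, comparison = model_sequence(long, outcome)
        paths.update(_fit_outputs(fits, comparison, outcome, outdir))
        log.info("%s ladder: %d models, final LL %.2f",
                 outcome, len(fits), fits[-1].loglik)
    return paths


def _fits_from_csvs(outdir: Path, outcome: str) -> list[GrowthFit]:
    """Rebuild lightweight GrowthFit objects from a fit stage's coefficient CSVs."""
    fits = []
    for path in sorted(outdir.glob(f"coef_{outcome}_m*.csv")):
        tab = pd.read_csv(path).fillna({"class": ""})
        meta = tab.iloc[0]
        spec = ModelSpec(
            outcome=meta["outcome"],
            terms=tuple(t for t in tab["term"] if t != "Intercept"),
            name=meta["model"],
        )
        fits.append(
            GrowthFit(
                spec=spec,
                table=tab[["term", "class", "B", "SE", "t", "df", "p", "p_one_tailed"]],
                tau2=float(meta["tau2"]),
                sigma2=float(meta["sigma2"]),
                loglik=float(meta["loglik"]),
                n_obs=int(meta["n_obs"]),
                n_participants=int(meta["n_participants"]),
                converged=True,
            )
        )
    return fits


def stage_report(cfg: RunConfig, outdir: Path) -> dict[str, str]:
    effort_fits = _fits_from_csvs(outdir, "effort")
    perf_fits = _fits_from_csvs(outdir, "performance")
    if not effort_fits or not perf_fits:
        raise ValidationError("report stage needs the fit stage's coefficient CSVs")
    long = pd.read_csv(outdir / "analysis_long.csv")
    paths = {}
    report = hypothesis_report(effort_fits, perf_fits)
    paths["hypothesis_report"] = str(_write(report, outdir / "hypothesis_report.csv"))
    slopes = []
    for moderator in ("spin", "pulse"):
        for fit in (effort_fits[-1], perf_fits[-1]):
            s = simple_slopes(fit, long, moderator, cfg.change_design())
            s["model"] = fit.spec.name
            slopes.append(s)
    paths["simple_slopes"] = str(
        _write(pd.concat(slopes, ignore_index=True), outdir / "simple_slopes.csv")
    )
    log.info("report written: %d hypothesis rows", len(report))
    return paths


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "score": stage_score,
    "metrics": stage_metrics,
    "design": stage_design,
    "fit": stage_fit,
    "report": stage_report,
}


def _load_inputs(cfg: RunConfig, outdir: Path) -> None:
    """Copy user-supplied CSVs into the working directory under canonical names."""
    for name, path in (cfg.inputs or {}).items():
        src = Path(path)
        if not src.exists():
            raise ValidationError(f"input file for {name!r} not found: {src}")
        pd.read_csv(src).to_csv(outdir / f"{name}.csv", index=False)


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] | None = None) -> dict:
    """Execute the staged pipeline and write outputs plus manifest.json.

    On a stage failure the run halts with a stage-named diagnostic and any
    files that stage had begun writing are renamed with a ``.partial``
    suffix. Returns the manifest dict.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(cfg, outdir)

    if stages is None:
        stages = STAGES if cfg.simulation is not None else STAGES[1:]
    outputs: dict[str, str] = {}
    if cfg.inputs is not None:
        _load_inputs(cfg, outdir)

    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ConfigError(f"unknown stage {stage!r}; expected one of {STAGES}")
        before = set(outdir.glob("*"))
        try:
            outputs.update(_STAGE_FUNCS[stage](cfg, outdir))
        except Exception as err:
            for p in set(outdir.glob("*")) - before:
                if p.is_file():
                    p.rename(p.with_suffix(p.suffix + ".partial"))
            raise AffectVarError(f"stage {stage!r} failed: {err}") from err

    # validation report over whatever tables exist
    tables = {
        name: pd.read_csv(outdir / f"{name}.csv")
        for name in ("persons", "affect_long", "trials", "outcomes_long")
        if (outdir / f"{name}.csv").exists()
    }
    vreport = validate_inputs(tables)
    _write(vreport, outdir / "validation_report.csv")

    excl_path = outdir / "exclusions.csv"
    exclusion_summary = {}
    if excl_path.exists():
        excl = pd.read_csv(excl_path).fillna({"reason": ""})
        exclusion_summary = (
            excl.loc[~excl["keep"], "reason"].value_counts().to_dict()
        )
    manifest = {
        "package_version": _version,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": list(stages),
        "row_counts": {name: int(len(t)) for name, t in tables.items()},
        "n_validation_violations": int(len(vreport)),
        "exclusion_summary": {k: int(v) for k, v in exclusion_summary.items()},
        "outputs": dict(sorted(outputs.items())),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("pipeline complete; manifest at %s", outdir / "manifest.json")
    return manifest


def _setup_logging(cfg: RunConfig, outdir: Path) -> None:
    log.setLevel(getattr(logging, cfg.log_level.upper(), logging.INFO))
    log.handlers = [
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(outdir / "run.log"),
    ]
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in log.handlers:
        h.setFormatter(fmt)
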