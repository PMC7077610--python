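"""Synthetic-study generator: persons, circumplex affect series, trials, outcomes.

Emulates a repeated-measures skill-acquisition study: a cohort (default 214
participants) plays 14 sessions of two trials each on a complex video-game
task, with an unannounced increase in task difficulty after session 7.
After each session participants report affect on a 16-item circumplex
checklist and six effort items. The generator produces every table the
analysis pipeline consumes, with all generating parameters retained so
recovery tests can compare estimates against ground truth.

Generating model, per participant *i*:

* affect direction ``theta_t ~ wrapped normal(mu_theta_i, sigma_theta_i)``
  (the wrapped normal's circular SD equals ``sigma_theta`` exactly, making
  spin-recovery targets analytic; a von Mises option is available);
* affect intensity ``d_t ~ Normal(mu_d_i, sigma_d_i)`` truncated at 0;
* ``valence_t = d_t cos(theta_t)``, ``activation_t = d_t sin(theta_t)``;
  subscales are back-solved around scale-midpoint baselines and clipped to
  [1, 9] (clipping flagged per row);
* outcomes follow the discontinuous growth model
  ``Y_ij = gamma' x_ij + u_i + e_ij`` with participant random intercept
  ``u_i ~ N(0, tau^2)`` and residual ``e_ij ~ N(0, sigma^2)``; session
  effort is generated first and may enter the performance predictor;
* trial kill/death/place counts are drawn to invert the trial-score formula
  so collapsed session scores approximate the generated performance.

Person-level spin/pulse targets are drawn from truncated normals anchored
at the cohort descriptives (spin 0.83 +/- 0.51, pulse 2.49 +/- 0.94).
A single seed expands into per-participant substreams, so any participant
subset is reproducible on its own.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .affect_metrics import AffectPoint, pulse as _pulse, spin as _spin, uni_dimensional_variability
from .errors import ValidationError
from .growth_design import ChangeDesign, attach_design
from .growth_models import COVARIATES, build_exog
from .performance_scoring import rank_term, vge_composite

__all__ = [
    "SimConfig",
    "SimulatedStudy",
    "DEFAULT_GAMMA_EFFORT",
    "DEFAULT_GAMMA_PERFORMANCE",
    "simulate_affect_series",
    "backfill_subscales",
    "simulate_person_covariates",
    "simulate_outcomes",
    "simulate_trials",
    "generate_study",
    "write_csv_bundle",
]

# Default generating coefficients for the two outcomes. Time-code and
# covariate effects reproduce the magnitudes typical of this task paradigm
# (strong pre-change performance growth, a marked post-change drop, slower
# reacquisition; effort rising at the change then decaying); trait and
# product terms default to the full cross-level structure.
DEFAULT_GAMMA_EFFORT: dict[str, float] = {
    "Intercept": 7.90,
    "SA": -0.04,
    "TA": 0.98,
    "RA": -0.76,
    "SA2": -0.04,
    "RA2": 0.08,
    "gender": -0.24,
    "act": -0.02,
    "vge": 0.19,
    "openness": -0.06,
    "conscientiousness": 0.25,
    "extraversion": 0.20,
    "agreeableness": 0.04,
    "emotional_stability": 0.14,
    "valence_variability": 0.30,
    "activation_variability": -0.25,
    "spin": -0.11,
    "pulse": 0.09,
    "SA:spin": -0.01,
    "SA:pulse": -0.06,
    "TA:spin": -0.54,
    "TA:pulse": -0.07,
    "RA:spin": 0.02,
    "RA:pulse": 0.04,
}

DEFAULT_GAMMA_PERFORMANCE: dict[str, float] = {
    "Intercept": 34.75,
    "SA": 5.47,
    "TA": -18.88,
    "RA": -4.66,
    "SA2": -0.57,
    "RA2": 0.0,
    "gender": -17.00,
    "act": 0.85,
    "vge": 5.02,
    "openness": 0.18,
    "conscientiousness": 1.30,
    "extraversion": -1.29,
    "agreeableness": -0.96,
    "emotional_stability": 0.43,
    "valence_variability": -1.14,
    "activation_variability": 1.03,
    "spin": -2.83,
    "pulse": -4.23,
    "effort": -0.14,
    "spin:effort": 0.23,
    "pulse:effort": 0.07,
    "SA:spin": -0.30,
    "SA:pulse": 0.36,
    "SA:effort": 0.18,
    "TA:spin": 1.16,
    "TA:pulse": -0.59,
    "TA:effort": -0.28,
    "RA:spin": -0.04,
    "RA:pulse": -0.56,
    "RA:effort": -0.05,
    "SA:spin:effort": 0.15,
    "SA:pulse:effort": 0.01,
    "TA:spin:effort": -2.20,
    "TA:pulse:effort": -0.43,
    "RA:spin:effort": 0.23,
    "RA:pulse:effort": 0.06,
}

# Cohort distributions for person-level covariates: (mean, SD), values on
# their native scales (ACT-like ability score; Big Five on a 1-9 metric).
_COVARIATE_DISTS: dict[str, tuple[float, float]] = {
    "act": (26.79, 4.09),
    "openness": (6.43, 0.88),
    "conscientiousness": (6.25, 0.98),
    "extraversion": (5.60, 1.16),
    "agreeableness": (6.86, 0.94),
    "emotional_stability": (5.26, 1.06),
}

_VGE_ITEM_DISTS: dict[str, tuple[float, float, float, float]] = {
    # (mean, sd, lower, upper)
    "vge_freq_any": (2.92, 1.42, 1.0, 5.0),
    "vge_freq_fps": (2.35, 1.33, 1.0, 5.0),
    "vge_hours_any": (4.61, 6.59, 0.0, 60.0),
    "vge_hours_fps": (2.03, 4.03, 0.0, 60.0),
}


@dataclass(frozen=True)
class SimConfig:
    """All generator knobs; defaults are the study conditions."""

    seed: int
    n_participants: int = 214
    n_sessions: int = 14
    trials_per_session: int = 2
    change_after: int = 7
    # person-level affect parameter draws
    spin_anchor_mean: float = 0.83
    spin_anchor_sd: float = 0.51
    sigma_theta_min: float = 0.05
    pulse_anchor_mean: float = 2.49
    pulse_anchor_sd: float = 0.94
    sigma_d_min: float = 0.2
    mu_theta_mean: float = 0.5
    mu_theta_sd: float = 0.6
    mu_d_mean: float = 8.0
    mu_d_sd: float = 2.5
    mu_d_min: float = 1.0
    angle_dist: str = "wrapped_normal"  # or "von_mises"
    subscale_baseline_pa_nd: float = 5.0
    subscale_baseline_pd_na: float = 5.0
    # outcome model
    gamma_effort: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GAMMA_EFFORT))
    gamma_performance: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GAMMA_PERFORMANCE)
    )
    tau_effort: float = 1.55
    sigma_effort: float = 1.10
    tau_performance: float = 8.0
    sigma_performance: float = 9.0
    effort_in_performance: bool = True
    # cohort composition
    p_female: float = 0.416
    # trial-level inversion
    n_competitors_pre: int = 3
    n_competitors_post: int = 10
    engagements_mean: float = 14.0
    # exclusion-screen exercise
    n_flatline_participants: int = 0
    flatline_sessions: int = 2

    def __post_init__(self):
        if not (1 <= self.change_after < self.n_sessions):
            raise ValidationError("change_after must lie in [1, n_sessions-1]")
        for name in ("spin_anchor_sd", "pulse_anchor_sd", "mu_theta_sd", "mu_d_sd",
                     "tau_effort", "sigma_effort", "tau_performance", "sigma_performance"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.angle_dist not in ("wrapped_normal", "von_mises"):
            raise ValidationError(f"unknown angle_dist {self.angle_dist!r}")


@dataclass
class SimulatedStudy:
    """The generated bundle plus everything needed to re-simulate it."""

    persons: pd.DataFrame
    affect_long: pd.DataFrame
    trials: pd.DataFrame
    outcomes_long: pd.DataFrame
    ground_truth: dict


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lower: float, upper: float = np.inf, size: int | None = None):
    if sd == 0:
        return np.full(size, mean) if size else mean
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _vonmises_kappa_for_circular_sd(sigma_theta: float) -> float:
    """kappa such that the von Mises circular SD equals sigma_theta."""
    target_r = float(np.exp(-(sigma_theta**2) / 2.0))
    if target_r >= 1.0 - 1e-12:
        return 1e8
    # exponentially scaled Bessel functions: i1e/i0e == i1/i0 without overflow
    f = lambda k: special.i1e(k) / special.i0e(k) - target_r
    return float(optimize.brentq(f, 1e-8, 1e8))


def simulate_affect_series(
    mu_theta: float,
    sigma_theta: float,
    mu_d: float,
    sigma_d: float,
    n_sessions: int,
    rng: np.random.Generator,
    angle_dist: str = "wrapped_normal",
) -> list[AffectPoint]:
    """One person's circumplex series: direction x intensity per session."""
    if sigma_theta < 0 or mu_d <= 0:
        raise ValidationError("need sigma_theta >= 0 and mu_d > 0")
    if angle_dist == "wrapped_normal":
        theta = mu_theta + sigma_theta * rng.standard_normal(n_sessions)
        theta = np.mod(theta + np.pi, 2 * np.pi) - np.pi
    elif angle_dist == "von_mises":
        kappa = _vonmises_kappa_for_circular_sd(sigma_theta)
        theta = rng.vonmises(mu_theta, kappa, size=n_sessions)
    else:
        raise ValidationError(f"unknown angle_dist {angle_dist!r}")
    d = _truncnorm(rng, mu_d, sigma_d, 0.0, size=n_sessions)
    return [
        AffectPoint(valence=float(di * np.cos(ti)), activation=float(di * np.sin(ti)))
        for di, ti in zip(d, theta)
    ]


def backfill_subscales(
    points: list[AffectPoint],
    baseline_pa_nd: float = 5.0,
    baseline_pd_na: float = 5.0,
) -> pd.DataFrame:
    """Back-solve PA/PD/NA/ND from composites around midpoint baselines.

    The inversion ``PA = m + (v+a)/4``, ``ND = m - (v+a)/4``,
    ``PD = m' + (v-a)/4``, ``NA = m' - (v-a)/4`` reproduces the composites
    exactly when no value leaves the 1–9 response range; out-of-range values
    are clipped and the row is flagged ``clipped`` so round-trip consumers
    can condition on clean rows.
    """
    v = np.array([p.valence for p in points])
    a = np.array([p.activation for p in points])
    raw = {
        "PA": baseline_pa_nd + (v + a) / 4.0,
        "ND": baseline_pa_nd - (v + a) / 4.0,
        "PD": baseline_pd_na + (v - a) / 4.0,
        "NA": baseline_pd_na - (v - a) / 4.0,
    }
    out = pd.DataFrame({k: np.clip(x, 1.0, 9.0) for k, x in raw.items()})
    out["clipped"] = np.stack(
        [(x < 1.0) | (x > 9.0) for x in raw.values()], axis=1
    ).any(axis=1)
    out["valence"] = v
    out["activation"] = a
    return out[["PA", "PD", "NA", "ND", "valence", "activation", "clipped"]]


def simulate_person_covariates(
    n: int, cfg: SimConfig, streams: list[np.random.Generator]
) -> pd.DataFrame:
    """Draw the person table: demographics, traits, VGE items, affect params.

    ``streams`` must hold one independent generator per participant so that
    any subset of participants is reproducible on its own.
    """
    if n < 2:
        raise ValidationError("need n >= 2 participants")
    rows = []
    for i in range(n):
        rng = streams[i]
        row: dict[str, object] = {"participant_id": f"P{i + 1:04d}"}
        row["gender"] = int(rng.random() < cfg.p_female)  # 1 = female
        for name, (m, s) in _COVARIATE_DISTS.items():
            lo, hi = (1.0, 9.0) if name != "act" else (1.0, 36.0)
            row[name] = float(_truncnorm(rng, m, s, lo, hi))
        for name, (m, s, lo, hi) in _VGE_ITEM_DISTS.items():
            row[name] = float(_truncnorm(rng, m, s, lo, hi))
        # person affect parameters: targets drawn around the cohort anchors
        row["sigma_theta"] = float(
            _truncnorm(rng, cfg.spin_anchor_mean, cfg.spin_anchor_sd, cfg.sigma_theta_min)
        )
        row["sigma_d"] = float(
            _truncnorm(rng, cfg.pulse_anchor_mean, cfg.pulse_anchor_sd, cfg.sigma_d_min)
        )
        row["mu_theta"] = float(cfg.mu_theta_mean + cfg.mu_theta_sd * rng.standard_normal())
        row["mu_d"] = float(_truncnorm(rng, cfg.mu_d_mean, cfg.mu_d_sd, cfg.mu_d_min))
        rows.append(row)
    persons = pd.DataFrame(rows)
    persons["vge"] = vge_composite(persons)
    return persons


def simulate_outcomes(
    long: pd.DataFrame,
    gamma: dict[str, float],
    tau: float,
    sigma: float,
    streams: dict[object, np.random.Generator],
) -> np.ndarray:
    """Draw Y = gamma'x + u_i + e_ij for each row of an assembled long table.

    ``long`` must already carry every column the gamma terms reference
    (time codes, covariates, realized spin/pulse, effort when present).
    ``streams`` maps participant_id -> generator (per-person noise stream).
    """
    terms = tuple(t for t in gamma if t != "Intercept")
    bad = [t for t in terms if not np.isfinite(gamma[t])]
    if bad:
        raise ValidationError(f"non-finite generating coefficient for terms {bad}")
    X = build_exog(long, terms)
    beta = np.array([gamma.get("Intercept", 0.0)] + [gamma[t] for t in terms])
    linpred = X.to_numpy() @ beta
    y = np.empty(len(long))
    for pid, idx in long.groupby("participant_id", sort=False).indices.items():
        rng = streams[pid]
        u = tau * rng.standard_normal() if tau > 0 else 0.0
        eps = sigma * rng.standard_normal(len(idx)) if sigma > 0 else np.zeros(len(idx))
        y[idx] = linpred[idx] + u + eps
    return y


def simulate_trials(
    session_perf: pd.DataFrame,
    cfg: SimConfig,
    streams: dict[object, np.random.Generator],
) -> pd.DataFrame:
    """Invert the trial-score formula: draw kills/deaths/place per trial.

    For each session's target score S (on the x100 metric), each of its
    trials gets a rank term r drawn uniformly over the feasible band, a
    kill ratio q = S/100 - r, and integer kills/deaths at a Poisson-drawn
    engagement count; collapsed session scores then approximate S within
    the rounding granularity of integer counts. Flatline participants
    (all-zero trials in the configured number of sessions) can be injected
    to exercise the exclusion screen.
    """
    rows = []
    flat_pids = set(
        session_perf["participant_id"].drop_duplicates().iloc[: cfg.n_flatline_participants]
    )
    for r in session_perf.itertuples():
        pid, s = r.participant_id, int(r.session_index)
        rng = streams[pid]
        post = s > cfg.change_after
        n_comp = cfg.n_competitors_post if post else cfg.n_competitors_pre
        target = min(max(float(r.performance), 0.0), 200.0) / 100.0
        for j in range(cfg.trials_per_session):
            trial_index = (s - 1) * cfg.trials_per_session + j + 1
            if pid in flat_pids and s <= cfg.flatline_sessions:
                rows.append(
                    {
                        "participant_id": pid,
                        "trial_index": trial_index,
                        "kills": 0,
                        "deaths": 0,
                        "place": n_comp,
                        "n_competitors": n_comp,
                    }
                )
                continue
            # rank grid {0, 1/(n-1), ..., 1}: prefer a grid point for which
            # the kill ratio q = target - r stays in [0, 1], so integer
            # rounding of kills is the only inversion error
            grid = [(p, rank_term(p, n_comp)) for p in range(1, n_comp + 1)]
            feasible = [pr for pr in grid if target - 1.0 <= pr[1] <= target]
            lo, hi = max(0.0, target - 1.0), min(1.0, target)
            r_draw = rng.uniform(lo, hi) if hi > lo else lo
            pool = feasible if feasible else grid
            place, r_actual = min(pool, key=lambda pr: abs(pr[1] - r_draw))
            q = min(max(target - r_actual, 0.0), 1.0)
            m = max(2, int(rng.poisson(cfg.engagements_mean)))
            kills = int(np.clip(np.rint(q * m), 0, m))
            rows.append(
                {
                    "participant_id": pid,
                    "trial_index": trial_index,
                    "kills": kills,
                    "deaths": m - kills,
                    "place": place,
                    "n_competitors": n_comp,
                }
            )
    return pd.DataFrame(rows)


def generate_study(cfg: SimConfig) -> SimulatedStudy:
    """Run the full generator and return all linked tables plus ground truth."""
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_participants + 1)
    person_streams = [np.random.default_rng(c) for c in children[1:]]

    persons = simulate_person_covariates(cfg.n_participants, cfg, person_streams)
    pid_stream = dict(zip(persons["participant_id"], person_streams))

    # affect series + realized variability metrics per person
    affect_rows, realized = [], []
    clip_count = 0
    for r in persons.itertuples():
        rng = pid_stream[r.participant_id]
        points = simulate_affect_series(
            r.mu_theta, r.sigma_theta, r.mu_d, r.sigma_d,
            cfg.n_sessions, rng, angle_dist=cfg.angle_dist,
        )
        sub = backfill_subscales(
            points, cfg.subscale_baseline_pa_nd, cfg.subscale_baseline_pd_na
        )
        sub.insert(0, "participant_id", r.participant_id)
        sub.insert(1, "session_index", np.arange(1, cfg.n_sessions + 1))
        clip_count += int(sub["clipped"].sum())
        affect_rows.append(sub)
        vv, av = uni_dimensional_variability(points)
        realized.append(
            {
                "participant_id": r.participant_id,
                "spin": _spin(points),
                "pulse": _pulse(points),
                "valence_variability": vv,
                "activation_variability": av,
            }
        )
    affect_long = pd.concat(affect_rows, ignore_index=True)
    realized = pd.DataFrame(realized)

    # assemble the long table with design codes and person columns
    design = ChangeDesign(n_sessions=cfg.n_sessions, change_after=cfg.change_after)
    long = pd.DataFrame(
        {
            "participant_id": np.repeat(persons["participant_id"].to_numpy(), cfg.n_sessions),
            "session_index": np.tile(np.arange(1, cfg.n_sessions + 1), cfg.n_participants),
        }
    )
    long = attach_design(long, design)
    person_cols = [c for c in COVARIATES if c in persons.columns]
    long = long.merge(persons[["participant_id", *person_cols]], on="participant_id", how="left")
    long = long.merge(realized, on="participant_id", how="left")

    long["effort"] = simulate_outcomes(
        long, cfg.gamma_effort, cfg.tau_effort, cfg.sigma_effort, pid_stream
    )
    perf_gamma = dict(cfg.gamma_performance)
    if not cfg.effort_in_performance:
        perf_gamma = {t: g for t, g in perf_gamma.items() if "effort" not in t.split(":")}
    long["performance"] = simulate_outcomes(
        long, perf_gamma, cfg.tau_performance, cfg.sigma_performance, pid_stream
    )

    outcome_cols = [
        "participant_id", "session_index", "SA", "TA", "RA", "SA2", "RA2",
        *COVARIATES, "spin", "pulse", "effort", "performance",
    ]
    # realized valence/activation variability already among COVARIATES
    outcomes_long = long[[c for c in outcome_cols if c in long.columns]].copy()

    trials = simulate_trials(
        outcomes_long[["participant_id", "session_index", "performance"]],
        cfg, pid_stream,
    )

    ground_truth = {
        "config": {
            k: (v if not isinstance(v, dict) else dict(v))
            for k, v in asdict(cfg).items()
        },
        "n_clipped_subscale_rows": clip_count,
        "person_params": persons[
            ["participant_id", "sigma_theta", "sigma_d", "mu_theta", "mu_d"]
        ].to_dict(orient="list"),
        "realized": realized.to_dict(orient="list"),
    }
    return SimulatedStudy(
        persons=persons,
        affect_long=affect_long,
        trials=trials,
        outcomes_long=outcomes_long,
        ground_truth=ground_truth,
    )


def write_csv_bundle(study: SimulatedStudy, outdir: str | Path) -> dict[str, str]:
    """Write persons/affect_long/trials/outcomes_long CSVs + ground_truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("persons", "affect_long", "trials", "outcomes_long"):
        p = outdir / f"{name}.csv"
        getattr(study, name).to_csv(p, index=False)
        paths[name] = str(p)
    gt = outdir / "ground_truth.json"
    gt.write_text(json.dumps(study.ground_truth, indent=2, default=float))
    paths["ground_truth"] = str(gt)
    return paths
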