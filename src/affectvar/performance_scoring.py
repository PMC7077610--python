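"""Trial and session performance scoring, exclusion screens, auxiliary composites.

A trial on the first-person-shooter task yields a kill count, a death count
and a finishing rank relative to the computer-controlled opponents. The
trial score is::

    100 * ( kills / (kills + deaths) + rank_term )

where ``rank_term`` is the normalized standing ``(n_competitors - place) /
(n_competitors - 1)`` in [0, 1] (1 = first place). Pairs of consecutive
trials are averaged into session scores (28 trials -> 14 sessions), which
stabilizes the estimates. A trial with ``kills + deaths == 0`` carries no
information and is flagged as a *flatline*; participants who flatline
repeatedly, or who are missing sessions, are excluded with a reason code,
mirroring the participant-level screens used with this task.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import StructuralError, ValidationError

__all__ = [
    "TrialResult",
    "SessionScore",
    "rank_term",
    "trial_score",
    "collapse_sessions",
    "score_trial_table",
    "exclusion_screen",
    "score_effort",
    "score_effort_table",
    "vge_composite",
]

EFFORT_MIN, EFFORT_MAX = 0.0, 10.0
N_EFFORT_ITEMS = 6


@dataclass(frozen=True)
class TrialResult:
    participant_id: object
    trial_index: int
    kills: int
    deaths: int
    rank_term: float

    def __post_init__(self):
        if self.kills < 0 or self.deaths < 0:
            raise ValidationError(
                f"negative kills/deaths for participant {self.participant_id} "
                f"trial {self.trial_index}"
            )
        if not (0.0 <= self.rank_term <= 1.0):
            raise ValidationError(f"rank_term {self.rank_term} outside [0, 1]")

    @property
    def is_flatline(self) -> bool:
        return self.kills == 0 and self.deaths == 0


@dataclass(frozen=True)
class SessionScore:
    participant_id: object
    session_index: int
    performance: float  # NaN when the session contains a flatlined trial
    flatline: bool = False


def rank_term(place: int, n_competitors: int) -> float:
    """Normalized standing: 1 for first place, 0 for last.

    The rank component of the published score formula is cited to prior work
    without a numeric definition; this normalized form keeps it on the same
    [0, 1] scale as the kill ratio.
    """
    if n_competitors < 2 or not (1 <= place <= n_competitors):
        raise ValidationError(
            f"invalid place {place} of {n_competitors} competitors"
        )
    return (n_competitors - place) / (n_competitors - 1)


def trial_score(t: TrialResult) -> float:
    """Score one trial on the x100 metric; NaN (flatline) when kills+deaths=0."""
    if t.is_flatline:
        return math.nan
    return 100.0 * (t.kills / (t.kills + t.deaths) + t.rank_term)


def collapse_sessions(trials: list[TrialResult]) -> list[SessionScore]:
    """Average consecutive trial pairs into session scores.

    Trials must be supplied in trial order for one participant; an odd count
    is a structural error. A session containing a flatlined trial is marked
    ``flatline`` and its performance is NaN (surfaced to the exclusion
    screen, never silently imputed).
    """
    if len(trials) % 2 != 0:
        raise StructuralError(
            f"odd trial count ({len(trials)}) for participant "
            f"{trials[0].participant_id if trials else '?'}"
        )
    out = []
    for s, i in enumerate(range(0, len(trials), 2), start=1):
        pair = trials[i : i + 2]
        flat = any(t.is_flatline for t in pair)
        perf = math.nan if flat else float(np.mean([trial_score(t) for t in pair]))
        out.append(SessionScore(pair[0].participant_id, s, perf, flatline=flat))
    return out


def score_trial_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Collapse a trial-level table into a session-level performance table.

    Expects columns ``participant_id, trial_index, kills, deaths, place,
    n_competitors`` (or a precomputed ``rank_term`` column). Returns one row
    per participant-session with ``performance`` and ``flatline`` columns.
    """
    required = {"participant_id", "trial_index", "kills", "deaths"}
    if not required.issubset(trials.columns):
        raise StructuralError(f"trial table must have columns {sorted(required)}")
    rows = []
    for pid, grp in trials.groupby("participant_id", sort=True):
        grp = grp.sort_values("trial_index")
        tr = []
        for r in grp.itertuples():
            rt = (
                float(r.rank_term)
                if "rank_term" in grp.columns
                else rank_term(int(r.place), int(r.n_competitors))
            )
            tr.append(TrialResult(pid, int(r.trial_index), int(r.kills), int(r.deaths), rt))
        for s in collapse_sessions(tr):
            rows.append(
                {
                    "participant_id": pid,
                    "session_index": s.session_index,
                    "performance": s.performance,
                    "flatline": s.flatline,
                }
            )
    return pd.DataFrame(rows)


def exclusion_screen(
    sessions: pd.DataFrame,
    n_sessions_expected: int,
    flatline_threshold: int = 2,
) -> pd.DataFrame:
    """Decide keep/drop per participant, with a reason code.

    Drops participants with any missing session (``incomplete``) or with at
    least ``flatline_threshold`` flatlined sessions (``flatline``).
    Deterministic and order-independent: decisions depend only on each
    participant's own rows. Returns one row per participant with columns
    ``participant_id, keep, reason``.
    """
    out = []
    for pid, grp in sessions.groupby("participant_id", sort=True):
        present = set(grp["session_index"])
        expected = set(range(1, n_sessions_expected + 1))
        n_flat = int(grp["flatline"].sum()) if "flatline" in grp.columns else int(
            grp["performance"].isna().sum()
        )
        if present != expected:
            keep, reason = False, "incomplete"
        elif n_flat >= flatline_threshold:
            keep, reason = False, "flatline"
        else:
            keep, reason = True, ""
        out.append({"participant_id": pid, "keep": keep, "reason": reason})
    return pd.DataFrame(out)


def score_effort(items) -> float:
    """Mean of the six 0–10 task-effort items."""
    items = [float(x) for x in items]
    if len(items) != N_EFFORT_ITEMS:
        raise ValidationError(f"expected {N_EFFORT_ITEMS} effort items, got {len(items)}")
    for x in items:
        if not (EFFORT_MIN <= x <= EFFORT_MAX):
            raise ValidationError(f"effort item {x} outside [0, 10]")
    return float(np.mean(items))


def score_effort_table(df: pd.DataFrame) -> pd.DataFrame:
    """Score an effort-item table (effort_1..effort_6, or a ready effort column)."""
    if "effort" in df.columns:
        return df[["participant_id", "session_index", "effort"]].copy()
    item_cols = [f"effort_{i}" for i in range(1, N_EFFORT_ITEMS + 1)]
    missing = [c for c in item_cols if c not in df.columns]
    if missing:
        raise StructuralError(f"effort table missing columns {missing}")
    out = df[["participant_id", "session_index"]].copy()
    out["effort"] = [score_effort(row) for row in df[item_cols].to_numpy()]
    return out


def vge_composite(persons: pd.DataFrame) -> pd.Series:
    """Standardized video-game-experience composite, one value per participant.

    The four inputs — two frequency items (``vge_freq_any``, ``vge_freq_fps``)
    and two weekly-hours items (``vge_hours_any``, ``vge_hours_fps``) — are
    z-scored within cohort; each frequency/hours pair is averaged, and the two
    pair means are averaged into the composite. Its cohort mean is 0 by
    construction.
    """
    pairs = [("vge_freq_any", "vge_freq_fps"), ("vge_hours_any", "vge_hours_fps")]
    if len(persons) < 2:
        raise ValidationError("vge_composite needs >=2 participants")
    zs = {}
    for pair in pairs:
        for col in pair:
            if col not in persons.columns:
                raise StructuralError(f"persons table missing column {col}")
            x = persons[col].astype(float)
            sd = x.std(ddof=1)
            if sd == 0:
                raise ValidationError(f"zero variance in item {col}")
            zs[col] = (x - x.mean()) / sd
    pair_means = [sum(zs[c] for c in pair) / len(pair) for pair in pairs]
    comp = sum(pair_means) / len(pairs)
    comp.name = "vge"
    return comp
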