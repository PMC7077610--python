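"""Circumplex affect scoring and within-person variability metrics.

Repeated affect reports are scored into two bipolar composites — valence
(pleasant vs. unpleasant) and activation (aroused vs. deactivated) — from a
16-item adjective checklist with four subscales:

* PA, positive-activating  (enthusiastic, excited, happy)
* PD, positive-deactivating (at ease, calm, relaxed)
* NA, negative-activating  (angry, anxious, frustrated, irritated, tense, uneasy)
* ND, negative-deactivating (bored, disappointed, discouraged, fatigued)

Each session's report becomes a point in the affect circumplex::

    valence_t    = (PA + PD) - (NA + ND)
    activation_t = (PA + NA) - (PD + ND)

Between-person traits are then defined on each person's point series:

* **spin** — circular standard deviation of the angular positions,
  ``sqrt(-2 ln ||R||/n)`` where ``||R||/n`` is the mean resultant length of
  the per-session unit vectors;
* **pulse** — standard deviation of the vector lengths (affect intensity);
* **valence/activation variability** — plain SDs of the two composites.

Subscales are scored as item *means* so every subscale shares the 1–9
response metric and composites lie in ``[-16, 16]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, SchemaError, ValidationError

__all__ = [
    "ITEM_MAP",
    "SessionAffect",
    "AffectPoint",
    "AffectVariabilityProfile",
    "EffortReport",
    "score_subscales",
    "compute_composites",
    "resultant_length_ratio",
    "spin",
    "pulse",
    "uni_dimensional_variability",
    "profile",
    "score_affect_table",
    "profile_table",
]

#: Canonical mapping from subscale to adjective item names (CSV column names).
ITEM_MAP: dict[str, tuple[str, ...]] = {
    "PA": ("enthusiastic", "excited", "happy"),
    "PD": ("at_ease", "calm", "relaxed"),
    "NA": ("angry", "anxious", "frustrated", "irritated", "tense", "uneasy"),
    "ND": ("bored", "disappointed", "discouraged", "fatigued"),
}

ALL_ITEMS: tuple[str, ...] = tuple(i for items in ITEM_MAP.values() for i in items)

RATING_MIN, RATING_MAX = 1.0, 9.0


@dataclass(frozen=True)
class SessionAffect:
    """Four subscale scores for one participant-session.

    Under the default item-mean scoring every subscale lies on the 1–9
    response metric; ``scoring="sum"`` widens the bounds to each subscale's
    item-total range.
    """

    participant_id: object
    session_index: int
    PA: float
    PD: float
    NA: float
    ND: float
    scoring: str = "mean"

    def __post_init__(self):
        for name in ("PA", "PD", "NA", "ND"):
            v = getattr(self, name)
            n_items = len(ITEM_MAP[name]) if self.scoring == "sum" else 1
            lo, hi = n_items * RATING_MIN, n_items * RATING_MAX
            if not (lo <= v <= hi):
                raise ValidationError(
                    f"{name}={v} outside [{lo}, {hi}] "
                    f"(participant {self.participant_id}, session {self.session_index})"
                )


@dataclass(frozen=True)
class AffectPoint:
    """One session's position in the circumplex (valence, activation)."""

    valence: float
    activation: float

    @property
    def distance(self) -> float:
        """Euclidean distance from the neutral origin (affect intensity)."""
        return math.hypot(self.valence, self.activation)

    @property
    def is_degenerate(self) -> bool:
        """True when the point sits exactly at the origin (no direction)."""
        return self.valence == 0.0 and self.activation == 0.0


@dataclass(frozen=True)
class AffectVariabilityProfile:
    """Per-person summary of mean affect and its within-person variability."""

    participant_id: object
    n_sessions_used: int
    n_degenerate_dropped: int
    mean_valence: float
    mean_activation: float
    valence_variability: float
    activation_variability: float
    resultant_length_ratio: float
    spin: float
    pulse: float


@dataclass(frozen=True)
class EffortReport:
    """Session effort: the mean of six 0–10 task-effort items."""

    participant_id: object
    session_index: int
    item_scores: tuple[float, ...]
    effort: float


def score_subscales(
    item_ratings: Mapping[str, float],
    participant_id: object = None,
    session_index: int = 0,
    aggregate: str = "mean",
) -> SessionAffect:
    """Score 16 named adjective ratings into the four subscales.

    Parameters
    ----------
    item_ratings
        Mapping from item name (see :data:`ITEM_MAP`) to rating in [1, 9].
        All 16 expected names must be present, with no extras.
    aggregate
        ``"mean"`` (default, keeps the 1–9 metric) or ``"sum"``.
    """
    expected = set(ALL_ITEMS)
    got = set(item_ratings)
    if got != expected:
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        raise SchemaError(f"item name mismatch: missing={missing}, extra={extra}")
    for name, v in item_ratings.items():
        if not (RATING_MIN <= float(v) <= RATING_MAX):
            raise ValidationError(f"rating {name}={v} outside [1, 9]")
    if aggregate not in ("mean", "sum"):
        raise ValidationError(f"unknown aggregate {aggregate!r}")
    agg = np.mean if aggregate == "mean" else np.sum
    scores = {
        sub: float(agg([float(item_ratings[i]) for i in items]))
        for sub, items in ITEM_MAP.items()
    }
    return SessionAffect(participant_id, session_index, scoring=aggregate, **scores)


def compute_composites(s: SessionAffect) -> AffectPoint:
    """Valence = (PA + PD) − (NA + ND); activation = (PA + NA) − (PD + ND)."""
    return AffectPoint(
        valence=(s.PA + s.PD) - (s.NA + s.ND),
        activation=(s.PA + s.NA) - (s.PD + s.ND),
    )


def _usable(points: Sequence[AffectPoint]) -> tuple[list[AffectPoint], int]:
    """Split a series into direction-carrying points and a degenerate count."""
    usable = [p for p in points if not p.is_degenerate]
    return usable, len(points) - len(usable)


def resultant_length_ratio(points: Sequence[AffectPoint]) -> float:
    """Mean resultant length ``||R||/n`` of the per-session unit vectors.

    Each non-degenerate point is normalized to its unit vector; the ratio is
    the Euclidean length of the vector sum divided by the number of
    contributing points. 1 means every report shares one direction; values
    near 0 mean the directions cancel. Origin points carry no direction and
    are excluded (the count is reported via :func:`profile`).
    """
    usable, dropped = _usable(points)
    if len(usable) < 2:
        raise InsufficientDataError(
            f"need >=2 non-degenerate points, got {len(usable)} "
            f"({dropped} degenerate dropped)",
            n_usable=len(usable),
            n_dropped=dropped,
        )
    v = np.array([p.valence for p in usable])
    a = np.array([p.activation for p in usable])
    d = np.hypot(v, a)
    rx = float(np.sum(v / d))
    ry = float(np.sum(a / d))
    ratio = math.hypot(rx, ry) / len(usable)
    # guard fp overshoot so the [0, 1] invariant holds exactly
    return min(max(ratio, 0.0), 1.0)


def spin(points: Sequence[AffectPoint], variant: str = "circular_sd") -> float:
    """Angular dispersion of a person's affect directions.

    ``variant="circular_sd"`` (default) returns the circular standard
    deviation ``sqrt(-2 ln ||R||/n)``. ``variant="neg2log"`` returns
    ``-2 ln(||R||/n)`` (the same quantity without the square root, i.e. the
    circular variance on the log scale). Both are 0 when every report points
    the same way and +inf when the directions cancel exactly.
    """
    if variant not in ("circular_sd", "neg2log"):
        raise ValidationError(f"unknown spin variant {variant!r}")
    ratio = resultant_length_ratio(points)
    if ratio == 0.0:
        return math.inf
    neg2log = max(0.0, -2.0 * math.log(ratio))
    return math.sqrt(neg2log) if variant == "circular_sd" else neg2log


def pulse(points: Sequence[AffectPoint], ddof: int = 1) -> float:
    """Within-person SD of the affect-vector lengths (intensity variability).

    Distances are measured from the neutral origin, so degenerate points
    contribute a distance of 0 (they are *not* dropped here).
    """
    if len(points) < 2:
        raise InsufficientDataError(
            f"need >=2 points for pulse, got {len(points)}", n_usable=len(points)
        )
    d = np.array([p.distance for p in points])
    return float(np.std(d, ddof=ddof))


def uni_dimensional_variability(
    points: Sequence[AffectPoint], ddof: int = 1
) -> tuple[float, float]:
    """Within-person SDs of the valence and activation series separately."""
    if len(points) < 2:
        raise InsufficientDataError(
            f"need >=2 points, got {len(points)}", n_usable=len(points)
        )
    v = np.array([p.valence for p in points])
    a = np.array([p.activation for p in points])
    return float(np.std(v, ddof=ddof)), float(np.std(a, ddof=ddof))


def profile(
    sessions: Sequence[SessionAffect],
    spin_variant: str = "circular_sd",
    ddof: int = 1,
) -> AffectVariabilityProfile:
    """Score one participant's full session set into a variability profile."""
    if not sessions:
        raise InsufficientDataError("no sessions supplied")
    pid = sessions[0].participant_id
    idx = [s.session_index for s in sessions]
    if len(set(idx)) != len(idx):
        raise ValidationError(f"duplicate session_index for participant {pid}: {idx}")
    points = [compute_composites(s) for s in sessions]
    usable, dropped = _usable(points)
    try:
        ratio = resultant_length_ratio(points)
        spin_val = spin(points, variant=spin_variant)
    except InsufficientDataError as err:
        raise InsufficientDataError(
            f"participant {pid}: {err}", n_usable=err.n_usable, n_dropped=err.n_dropped
        ) from err
    vv, av = uni_dimensional_variability(points, ddof=ddof)
    return AffectVariabilityProfile(
        participant_id=pid,
        n_sessions_used=len(points),
        n_degenerate_dropped=dropped,
        mean_valence=float(np.mean([p.valence for p in points])),
        mean_activation=float(np.mean([p.activation for p in points])),
        valence_variability=vv,
        activation_variability=av,
        resultant_length_ratio=ratio,
        spin=spin_val,
        pulse=pulse(points, ddof=ddof),
    )


# ---------------------------------------------------------------------------
# Table-level interface (long CSV in, per-person profile table out)
# ---------------------------------------------------------------------------

_SUBSCALE_COLS = ("PA", "PD", "NA", "ND")


def score_affect_table(df: pd.DataFrame) -> pd.DataFrame:
    """Score a long affect table to one PA/PD/NA/ND row per participant-session.

    The input must carry ``participant_id`` and ``session_index`` plus either
    the 16 item columns of :data:`ITEM_MAP` or pre-scored ``PA/PD/NA/ND``
    columns (auto-detected from the header).
    """
    required = {"participant_id", "session_index"}
    if not required.issubset(df.columns):
        raise SchemaError(f"affect table must have columns {sorted(required)}")
    if set(_SUBSCALE_COLS).issubset(df.columns):
        out = df[["participant_id", "session_index", *_SUBSCALE_COLS]].copy()
        for c in _SUBSCALE_COLS:
            bad = ~out[c].between(RATING_MIN, RATING_MAX)
            if bad.any():
                raise ValidationError(
                    f"{c} outside [1, 9] in rows {list(out.index[bad][:5])}"
                )
        return out
    missing = [c for c in ALL_ITEMS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"affect table has neither PA/PD/NA/ND nor all 16 item columns; "
            f"missing items: {missing}"
        )
    rows = []
    for _, r in df.iterrows():
        s = score_subscales(
            {c: r[c] for c in ALL_ITEMS},
            participant_id=r["participant_id"],
            session_index=int(r["session_index"]),
        )
        rows.append(
            {
                "participant_id": s.participant_id,
                "session_index": s.session_index,
                "PA": s.PA,
                "PD": s.PD,
                "NA": s.NA,
                "ND": s.ND,
            }
        )
    return pd.DataFrame(rows)


def profile_table(
    df: pd.DataFrame, spin_variant: str = "circular_sd", ddof: int = 1
) -> pd.DataFrame:
    """Compute one :func:`profile` row per participant from a long affect table."""
    scored = score_affect_table(df)
    out = []
    for pid, grp in scored.groupby("participant_id", sort=True):
        sessions = [
            SessionAffect(pid, int(r.session_index), r.PA, r.PD, r.NA, r.ND)
            for r in grp.itertuples()
        ]
        p = profile(sessions, spin_variant=spin_variant, ddof=ddof)
        out.append(
            {
                "participant_id": p.participant_id,
                "n_sessions_used": p.n_sessions_used,
                "n_degenerate_dropped": p.n_degenerate_dropped,
                "mean_valence": p.mean_valence,
                "mean_activation": p.mean_activation,
                "valence_variability": p.valence_variability,
                "activation_variability": p.activation_variability,
                "resultant_length_ratio": p.resultant_length_ratio,
                "spin": p.spin,
                "pulse": p.pulse,
            }
        )
    return pd.DataFrame(out)
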