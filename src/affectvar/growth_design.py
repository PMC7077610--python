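"""Time codes for discontinuous growth models with one task-change point.

Sessions are indexed 1..S at the interface; the linear code SA is 0-based.
For a change after session ``c`` the five codes for session ``s`` are::

    SA  = s - 1                      linear trend across all sessions
    TA  = 1 if s > c else 0          post-change level shift (dummy)
    RA  = max(0, s - c - 1)          post-change slope, relative to SA
    SA2 = min(s - 1, c - 1) ** 2     quadratic acquisition, capped after change
    RA2 = RA ** 2                    quadratic reacquisition

TA is interpreted relative to the value SA predicts immediately after the
change; RA is the post-change change in slope relative to the pre-change
slope. SA2 freezes at its last pre-change value ((c-1)^2) so curvature in
the post-change period is carried entirely by RA2 (the Bliese-style
convention; for the 14-session / change-after-7 study design the cap is 36).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

__all__ = ["ChangeDesign", "DesignRow", "build_design", "design_frame", "attach_design", "CODE_COLUMNS"]

CODE_COLUMNS = ("SA", "TA", "RA", "SA2", "RA2")


@dataclass(frozen=True)
class ChangeDesign:
    """A sessions-and-change-point layout; study default is 14 sessions, change after 7."""

    n_sessions: int = 14
    change_after: int = 7

    def __post_init__(self):
        if self.n_sessions < 2:
            raise ValidationError(f"n_sessions must be >=2, got {self.n_sessions}")
        if not (1 <= self.change_after <= self.n_sessions - 1):
            raise ValidationError(
                f"change_after must lie in [1, {self.n_sessions - 1}], "
                f"got {self.change_after}"
            )


@dataclass(frozen=True)
class DesignRow:
    session_index: int
    SA: int
    TA: int
    RA: int
    SA2: int
    RA2: int


def build_design(d: ChangeDesign) -> list[DesignRow]:
    """Enumerate the code rows for sessions 1..n_sessions."""
    c = d.change_after
    rows = []
    for s in range(1, d.n_sessions + 1):
        sa = s - 1
        ra = max(0, s - c - 1)
        rows.append(
            DesignRow(
                session_index=s,
                SA=sa,
                TA=1 if s > c else 0,
                RA=ra,
                SA2=min(sa, c - 1) ** 2,
                RA2=ra**2,
            )
        )
    return rows


def design_frame(d: ChangeDesign) -> pd.DataFrame:
    """The design as a DataFrame keyed by session_index."""
    return pd.DataFrame([vars(r) for r in build_design(d)])


def attach_design(long: pd.DataFrame, d: ChangeDesign) -> pd.DataFrame:
    """Append the five code columns to a long table keyed by ``session_index``.

    Row count and order are preserved; re-attachment is idempotent (existing
    code columns are replaced).
    """
    if "session_index" not in long.columns:
        raise ValidationError("long table must have a session_index column")
    bad = ~long["session_index"].between(1, d.n_sessions)
    if bad.any():
        raise ValidationError(
            f"session_index outside design range in rows {list(long.index[bad][:10])}"
        )
    out = long.drop(columns=[c for c in CODE_COLUMNS if c in long.columns]).copy()
    codes = design_frame(d)
    merged = out.merge(codes, on="session_index", how="left", sort=False)
    merged.index = out.index
    return merged
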