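"""Discontinuous mixed-effects growth models: fitting sequence and reports.

The outcome (session effort or session performance) is modelled as a
two-level linear mixed model with a participant random intercept, fitted by
maximum likelihood::

    Y_ij = gamma' x_ij + u_i + e_ij,   u_i ~ N(0, tau2),  e_ij ~ N(0, sigma2)

where ``x_ij`` contains the discontinuous-growth time codes (SA, TA, RA,
SA2, RA2), person-level covariates, the affect-variability traits (spin,
pulse), and configured cross-level products. Models are built as an ordered
ladder of nested fixed-effect sets, each refitted from scratch by ML so
log-likelihoods are comparable across steps (higher = better fit).

Degrees of freedom follow the two-level counting convention: a term that
involves a time code is a *level-1* (within-person) term with
``df = n_obs - n_participants - (number of level-1 terms)``; every other
term — including session-level effort and its products with person traits —
is a *between-person* term with ``df = n_participants - (number of between
terms) - 1``. ML estimation is delegated to statsmodels MixedLM; the
degenerate ``tau2 = 0`` fit is computed in closed form.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, FitError, ValidationError
from .growth_design import CODE_COLUMNS, ChangeDesign, design_frame

__all__ = [
    "TIME_CODES",
    "COVARIATES",
    "ModelSpec",
    "GrowthFit",
    "effort_ladder",
    "performance_ladder",
    "classify_term",
    "assign_df",
    "fit_growth_model",
    "model_sequence",
    "hypothesis_report",
    "substitute_covariate",
    "simple_slopes",
]

TIME_CODES = frozenset(CODE_COLUMNS)

#: Person-level control variables, in the order they enter the ladders.
COVARIATES = (
    "gender",
    "act",
    "vge",
    "openness",
    "conscientiousness",
    "extraversion",
    "agreeableness",
    "emotional_stability",
    "valence_variability",
    "activation_variability",
)

TRAITS = ("spin", "pulse")


@dataclass(frozen=True)
class ModelSpec:
    """One step of a model ladder: an outcome and an ordered fixed-effect set.

    Terms are column names or colon-joined products (e.g. ``"SA:spin"``,
    ``"TA:spin:effort"``); the intercept is implicit. Estimation is always
    maximum likelihood with a participant random intercept (``tau2=0.0`` may
    be forced via ``fix_tau2`` for the degenerate no-clustering limit).
    """

    outcome: str
    terms: tuple[str, ...]
    name: str = "model"
    fix_tau2: float | None = None

    def __post_init__(self):
        if len(set(self.terms)) != len(self.terms):
            raise ConfigError(f"duplicate terms in spec {self.name}: {self.terms}")


@dataclass(frozen=True)
class GrowthFit:
    """Fitted fixed effects with SE/t/df/p plus variance components and LL."""

    spec: ModelSpec
    table: pd.DataFrame = field(repr=False)  # term, class, B, SE, t, df, p, p_one_tailed
    tau2: float
    sigma2: float
    loglik: float
    n_obs: int
    n_participants: int
    converged: bool

    def coef(self, term: str) -> pd.Series:
        hit = self.table[self.table["term"] == term]
        if hit.empty:
            raise KeyError(f"term {term!r} not in model {self.spec.name}")
        return hit.iloc[0]


def classify_term(term: str) -> str:
    """``"level1"`` if the term involves any time code, else ``"between"``.

    Session-level effort (and trait-by-effort products without a time code)
    are counted as between-person terms under this bookkeeping convention.
    """
    return "level1" if any(f in TIME_CODES for f in term.split(":")) else "between"


def assign_df(term_class: str, n_obs: int, n_participants: int,
              level1_count: int, between_count: int) -> int:
    """Denominator df under the two-level counting rule.

    level-1: ``n_obs - n_participants - level1_count``;
    between (and the intercept): ``n_participants - between_count - 1``.
    """
    if term_class == "level1":
        df = n_obs - n_participants - level1_count
    else:
        df = n_participants - between_count - 1
    if df <= 0:
        raise FitError(
            f"nonpositive df ({df}) — design too rich for "
            f"{n_obs} observations on {n_participants} participants"
        )
    return df


def _term_column(data: pd.DataFrame, term: str) -> np.ndarray:
    col = np.ones(len(data))
    for f in term.split(":"):
        if f not in data.columns:
            raise ConfigError(f"term {term!r} references missing column {f!r}")
        col = col * data[f].to_numpy(dtype=float)
    return col


def build_exog(data: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    """Design matrix with an Intercept column followed by the spec's terms."""
    X = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
    for t in terms:
        X[t] = _term_column(data, t)
    return X


def _check_finite(data: pd.DataFrame, terms: tuple[str, ...], outcome: str) -> None:
    cols = {outcome} | {f for t in terms for f in t.split(":")}
    for c in sorted(cols & set(data.columns)):
        vals = data[c].to_numpy(dtype=float)
        bad = ~np.isfinite(vals)
        if bad.any():
            pids = sorted(set(data.loc[bad, "participant_id"].astype(str)))[:10]
            raise FitError(
                f"non-finite values in {c!r} (e.g. an infinite spin sentinel) "
                f"for participants {pids}; resolve or exclude before fitting"
            )


def _closed_form_tau0(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, float]:
    """ML fit with the random-intercept variance pinned at 0.

    With tau2 = 0 the marginal covariance is sigma2*I, so the ML fixed
    effects solve the normal equations and sigma2 is the mean squared
    residual (ML, not OLS-unbiased); returns (beta, sigma2, loglik).
    """
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    sigma2 = float(resid @ resid) / n
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return beta, sigma2, loglik


def fit_growth_model(data: pd.DataFrame, spec: ModelSpec) -> GrowthFit:
    """Fit one ladder step by ML and assemble the coefficient table.

    ``data`` is a long table with one row per participant-session carrying
    the outcome, the time codes and every covariate the spec references.
    Raises :class:`FitError` on non-finite predictors (e.g. the infinite
    spin sentinel of a direction-less affect series) or non-convergence.
    """
    if "participant_id" not in data.columns:
        raise ValidationError("long data must carry participant_id")
    if spec.outcome not in data.columns:
        raise ConfigError(f"outcome column {spec.outcome!r} missing")
    _check_finite(data, spec.terms, spec.outcome)

    groups = data["participant_id"].to_numpy()
    n_obs = len(data)
    n_participants = len(pd.unique(groups))
    if n_participants < 2:
        raise FitError("need >=2 participants to fit a mixed model")

    X = build_exog(data, spec.terms)
    y = data[spec.outcome].to_numpy(dtype=float)

    if spec.fix_tau2 is not None:
        if spec.fix_tau2 != 0.0:
            raise ConfigError("only fix_tau2=0.0 is supported")
        beta, sigma2, loglik = _closed_form_tau0(y, X.to_numpy())
        # SEs from the sigma2*(X'X)^-1 information matrix
        xtx_inv = np.linalg.pinv(X.to_numpy().T @ X.to_numpy())
        se = np.sqrt(sigma2 * np.diag(xtx_inv))
        fe = pd.Series(beta, index=X.columns)
        se = pd.Series(se, index=X.columns)
        tau2, converged = 0.0, True
    else:
        from statsmodels.regression.mixed_linear_model import MixedLM

        model = MixedLM(y, X, groups=groups)
        res, last_err = None, None
        # lbfgs is fastest but its Hessian step can be singular on some
        # instances; fall back through sturdier optimizers before giving up
        for method in ("lbfgs", "bfgs", "cg", "powell"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    cand = model.fit(reml=False, method=[method], maxiter=500)
                except np.linalg.LinAlgError as err:
                    last_err = err
                    continue
            if getattr(cand, "converged", True):
                res = cand
                break
        if res is None:
            raise FitError(
                f"model {spec.name} failed to converge under all optimizers "
                f"(n_obs={n_obs}, n_participants={n_participants}, "
                f"terms={len(spec.terms)}; last error: {last_err})"
            )
        fe = pd.Series(np.asarray(res.fe_params, dtype=float), index=X.columns)
        se = pd.Series(np.asarray(res.bse_fe, dtype=float), index=X.columns)
        tau2 = float(np.asarray(res.cov_re)[0, 0])
        sigma2 = float(res.scale)
        loglik = float(res.llf)
        converged = True

    classes = {t: classify_term(t) for t in spec.terms}
    level1_count = sum(1 for c in classes.values() if c == "level1")
    between_count = sum(1 for c in classes.values() if c == "between")

    rows = []
    for name in X.columns:
        cls = "between" if name == "Intercept" else classes[name]
        df = assign_df(cls, n_obs, n_participants, level1_count, between_count)
        b, s = float(fe[name]), float(se[name])
        t = b / s if s > 0 else np.nan
        p_two = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else np.nan
        rows.append(
            {
                "term": name,
                "class": cls,
                "B": b,
                "SE": s,
                "t": t,
                "df": df,
                "p": p_two,
                "p_one_tailed": p_two / 2.0 if np.isfinite(t) else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    if sigma2 <= 0 or not np.isfinite(loglik):
        raise FitError(f"degenerate fit in model {spec.name}: sigma2={sigma2}")
    return GrowthFit(
        spec=spec,
        table=table,
        tau2=tau2,
        sigma2=sigma2,
        loglik=loglik,
        n_obs=n_obs,
        n_participants=n_participants,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Model ladders
# ---------------------------------------------------------------------------

def effort_ladder() -> list[ModelSpec]:
    """The five-step effort ladder: time codes, covariates, trait mains,
    trait x SA products, trait x TA/RA products."""
    time = tuple(CODE_COLUMNS)
    steps = [time]
    steps.append(steps[-1] + COVARIATES)
    steps.append(steps[-1] + TRAITS)
    steps.append(steps[-1] + ("SA:spin", "SA:pulse"))
    steps.append(steps[-1] + ("TA:spin", "TA:pulse", "RA:spin", "RA:pulse"))
    return [
        ModelSpec(outcome="effort", terms=t, name=f"effort_m{i}")
        for i, t in enumerate(steps, start=1)
    ]


def performance_ladder(include_ra2: bool = False) -> list[ModelSpec]:
    """The six-step performance ladder.

    Step 1 carries all five time codes; subsequent steps drop RA2 by default
    (the pruning rule for a quadratic term that is non-significant at step 1
    — see :func:`model_sequence`), then add covariates, trait mains, the
    effort main effect, all two-way products, and the three-way products.
    """
    time_full = tuple(CODE_COLUMNS)
    time_later = time_full if include_ra2 else tuple(c for c in CODE_COLUMNS if c != "RA2")
    steps = [time_full]
    steps.append(time_later + COVARIATES)
    steps.append(steps[-1] + TRAITS)
    steps.append(steps[-1] + ("effort",))
    steps.append(
        steps[-1]
        + (
            "spin:effort",
            "pulse:effort",
            "SA:spin",
            "SA:pulse",
            "SA:effort",
            "TA:spin",
            "TA:pulse",
            "TA:effort",
            "RA:spin",
            "RA:pulse",
            "RA:effort",
        )
    )
    steps.append(
        steps[-1]
        + (
            "SA:spin:effort",
            "SA:pulse:effort",
            "TA:spin:effort",
            "TA:pulse:effort",
            "RA:spin:effort",
            "RA:pulse:effort",
        )
    )
    return [
        ModelSpec(outcome="performance", terms=t, name=f"performance_m{i}")
        for i, t in enumerate(steps, start=1)
    ]


def model_sequence(
    data: pd.DataFrame,
    outcome: str,
    steps: list[ModelSpec] | None = None,
    prune_nonsig_quadratic: bool = True,
    alpha: float = 0.05,
) -> tuple[list[GrowthFit], pd.DataFrame]:
    """Fit a ladder of nested models by ML on identical rows.

    For the performance ladder the reacquisition quadratic (RA2) is kept in
    later steps only when it is significant at step 1 (two-tailed, at
    ``alpha``); otherwise it is dropped from models 2 onward. Returns the
    fits plus a log-likelihood comparison table (higher = better fit).
    """
    if steps is None:
        if outcome == "effort":
            steps = effort_ladder()
        elif outcome == "performance":
            steps = performance_ladder(include_ra2=True)  # resolved after step 1
        else:
            raise ConfigError(f"no default ladder for outcome {outcome!r}")
    for prev, nxt in zip(steps, steps[1:]):
        missing = [t for t in prev.terms if t not in nxt.terms and t != "RA2"]
        if missing:
            raise ConfigError(
                f"ladder step {nxt.name} drops terms {missing} from {prev.name}"
            )

    fits = [fit_growth_model(data, steps[0])]
    if (
        outcome == "performance"
        and prune_nonsig_quadratic
        and "RA2" in steps[0].terms
        and fits[0].coef("RA2")["p"] >= alpha
    ):
        steps = [steps[0]] + [
            replace(s, terms=tuple(t for t in s.terms if t != "RA2"))
            for s in steps[1:]
        ]
    for spec in steps[1:]:
        fits.append(fit_growth_model(data, spec))

    comparison = pd.DataFrame(
        {
            "model": [f.spec.name for f in fits],
            "n_terms": [len(f.spec.terms) for f in fits],
            "loglik": [f.loglik for f in fits],
        }
    )
    comparison["delta_loglik"] = comparison["loglik"].diff()
    return fits, comparison


# ---------------------------------------------------------------------------
# Hypothesis mapping, covariate substitution, simple slopes
# ---------------------------------------------------------------------------

# (hypothesis, sub) -> (ladder, model index from 1, terms, one_tailed)
_HYPOTHESIS_MAP = {
    ("H1", "a"): ("effort", 3, ("spin",), False),
    ("H1", "b"): ("effort", 3, ("pulse",), False),
    ("H2", "a"): ("effort", 4, ("SA:spin",), False),
    ("H2", "b"): ("effort", 4, ("SA:pulse",), False),
    ("H3", "a"): ("performance", 5, ("spin:effort",), False),
    ("H3", "b"): ("performance", 5, ("pulse:effort",), False),
    ("H4", "a"): ("effort", 5, ("TA:spin",), True),
    ("H4", "b"): ("effort", 5, ("TA:pulse",), True),
    ("H5", "a"): ("effort", 5, ("RA:spin",), True),
    ("H5", "b"): ("effort", 5, ("RA:pulse",), True),
    ("H6", "a"): ("performance", 6, ("TA:spin:effort", "RA:spin:effort"), False),
    ("H6", "b"): ("performance", 6, ("TA:pulse:effort", "RA:pulse:effort"), False),
}


def hypothesis_report(
    effort_fits: list[GrowthFit], performance_fits: list[GrowthFit]
) -> pd.DataFrame:
    """Map the six hypothesis families onto their ladder terms.

    H1: trait main effects on effort. H2: trait x SA on effort (sustained
    effort). H3: trait x effort on performance. H4/H5: trait x TA / x RA on
    effort (adaptation vs. acquisition). H6: trait x effort x TA/RA on
    performance. The ``one_tailed`` flag marks the directional tests that
    were evaluated one-tailed; a hypothesis whose term is absent from the
    fitted ladder is marked untestable rather than raising.
    """
    ladders = {"effort": effort_fits, "performance": performance_fits}
    rows = []
    for (hyp, sub), (ladder, step, terms, one_tailed) in _HYPOTHESIS_MAP.items():
        fits = ladders[ladder]
        fit = fits[step - 1] if len(fits) >= step else None
        for term in terms:
            row = {
                "hypothesis": hyp,
                "sub": sub,
                "ladder": ladder,
                "model": fit.spec.name if fit else f"{ladder}_m{step}",
                "term": term,
                "one_tailed": one_tailed,
            }
            if fit is None or term not in fit.spec.terms:
                row.update(
                    testable=False, B=np.nan, SE=np.nan, t=np.nan,
                    df=np.nan, p=np.nan, p_one_tailed=np.nan,
                )
            else:
                c = fit.coef(term)
                row.update(
                    testable=True, B=c["B"], SE=c["SE"], t=c["t"],
                    df=c["df"], p=c["p"], p_one_tailed=c["p_one_tailed"],
                )
            rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(["hypothesis", "sub", "term"]).reset_index(drop=True)


def substitute_covariate(
    spec: ModelSpec,
    drop: tuple[str, ...] = ("spin", "pulse"),
    add: str = "emotional_stability",
) -> ModelSpec:
    """Replace every spin/pulse term by its emotional-stability analogue.

    Each term containing a dropped trait has that factor replaced by ``add``;
    duplicates created by the 2-to-1 collapse (e.g. SA:spin and SA:pulse both
    mapping to SA:emotional_stability) are merged, and terms already present
    (the emotional-stability main effect among the covariates) are not
    repeated. Idempotent on specs without spin/pulse terms.
    """
    new_terms: list[str] = []
    for term in spec.terms:
        factors = term.split(":")
        if any(f in drop for f in factors):
            mapped = [add if f in drop else f for f in factors]
            # collapse repeated factors within the term (spin:pulse -> add)
            seen: list[str] = []
            for f in mapped:
                if f not in seen:
                    seen.append(f)
            term = ":".join(seen)
        if term not in new_terms:
            new_terms.append(term)
    return replace(spec, terms=tuple(new_terms), name=spec.name + "_es")


def simple_slopes(
    fit: GrowthFit,
    data: pd.DataFrame,
    moderator: str,
    design: ChangeDesign | None = None,
    sd_multiplier: float = 1.0,
) -> pd.DataFrame:
    """Predicted outcome trajectories at moderator = mean +/- 1 SD.

    All other predictors are held at their grand means while the time codes
    run across sessions; the fit must contain at least one product term
    involving the moderator. Returns one row per session per level.
    """
    if not any(
        moderator in t.split(":") and len(t.split(":")) > 1 for t in fit.spec.terms
    ):
        raise ConfigError(
            f"model {fit.spec.name} has no interaction involving {moderator!r}"
        )
    design = design or ChangeDesign()
    codes = design_frame(design).set_index("session_index")
    m_mean = float(data[moderator].mean())
    m_sd = float(data[moderator].std(ddof=1))
    means = {
        c: float(data[c].mean())
        for c in data.columns
        if c not in ("participant_id", "session_index") and np.issubdtype(data[c].dtype, np.number)
    }
    coefs = dict(zip(fit.table["term"], fit.table["B"]))
    rows = []
    for level, mult in (("low", -sd_multiplier), ("high", +sd_multiplier)):
        m_val = m_mean + mult * m_sd
        for s in codes.index:
            vals = dict(means)
            vals.update({c: float(codes.loc[s, c]) for c in CODE_COLUMNS})
            vals[moderator] = m_val
            pred = coefs["Intercept"]
            for term in fit.spec.terms:
                x = 1.0
                for f in term.split(":"):
                    x *= vals[f]
                pred += coefs[term] * x
            rows.append(
                {
                    "session_index": int(s),
                    "level": level,
                    "moderator": moderator,
                    "moderator_value": m_val,
                    "predicted": pred,
                }
            )
    return pd.DataFrame(rows)


def spec_hash(specs: list[ModelSpec]) -> str:
    """Stable short hash of a ladder definition (for run manifests)."""
    payload = "|".join(f"{s.name}~{s.outcome}~{','.join(s.terms)}" for s in specs)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
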