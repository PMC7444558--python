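"""Cause-specific transition models: dataset construction, fitting, selection.

Event histories are decomposed into *sojourn records* — one per stay in a
community or hospital state, with the sojourn clock reset to zero at entry
(semi-Markov) and covariates frozen at entry — and *ED records*, one per
same-day emergency-department visit.  For each parametric arc the
time-to-event model is fitted cause-specifically: exits to competing
destinations censor the sojourn at the exit time.  ED destinations are
modelled jointly by a multinomial logit over {community, COPD hospital,
other hospital, death}.

Family choice per arc follows an information-criterion rule: fit all six
families, take the minimum-AIC fit, but if a family with fewer parameters is
within 2 of the best on *both* AIC and BIC, prefer the most parsimonious
such family.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.tools import numdiff

from .covariates import (
    BASELINE_COLUMNS,
    COEFFICIENT_NAMES,
    COUNTER_COLUMNS,
    encode_frame,
)
from .families import DistributionFamily, DistributionParams, _log_pdf, _log_sf
from .states import (
    DX,
    ED_STATES,
    HOSPITAL_STATES,
    MO,
    StructureError,
    Trajectory,
    TransitionStructure,
)

__all__ = [
    "ParametricTransitionFit",
    "MultinomialFit",
    "InestimableError",
    "FitConvergenceError",
    "build_transition_dataset",
    "sojourn_records",
    "ed_records",
    "fit_survival",
    "fit_parametric",
    "select_family",
    "fit_multinomial",
    "predict_destination_probs",
    "write_parameter_tables",
    "read_parameter_tables",
    "PARSIMONY_THRESHOLD",
]

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

#: families within this distance of the best on both AIC and BIC are
#: considered indistinguishable; the fewest-parameter one then wins
PARSIMONY_THRESHOLD = 2.0


class InestimableError(ValueError):
    """No uncensored events — the transition model cannot be estimated."""


class FitConvergenceError(RuntimeError):
    """The likelihood optimizer failed; carries the optimizer diagnostics."""


# ---------------------------------------------------------------------------
# unconstrained parameter packing (estimation scale)
# ---------------------------------------------------------------------------

def _dist_param_names(family: DistributionFamily) -> Tuple[str, ...]:
    if family is DistributionFamily.EXPONENTIAL:
        return ("location",)
    if family is DistributionFamily.GAMMA:
        return ("location", "log_shape")
    if family is DistributionFamily.GENERALIZED_GAMMA:
        return ("location", "log_scale", "q")
    return ("location", "log_scale")


def _decode_dist(family: DistributionFamily, theta: np.ndarray) -> DistributionParams:
    if family is DistributionFamily.EXPONENTIAL:
        return DistributionParams(family, float(theta[0]))
    if family is DistributionFamily.GAMMA:
        return DistributionParams(family, float(theta[0]), shape=float(np.exp(theta[1])))
    if family is DistributionFamily.GENERALIZED_GAMMA:
        return DistributionParams(
            family, float(theta[0]), float(np.exp(theta[1])), shape=float(theta[2])
        )
    return DistributionParams(family, float(theta[0]), float(np.exp(theta[1])))


def _encode_dist(params: DistributionParams) -> np.ndarray:
    fam = params.family
    if fam is DistributionFamily.EXPONENTIAL:
        return np.array([params.location])
    if fam is DistributionFamily.GAMMA:
        return np.array([params.location, np.log(params.shape)])
    if fam is DistributionFamily.GENERALIZED_GAMMA:
        return np.array([params.location, np.log(params.scale), params.shape])
    return np.array([params.location, np.log(params.scale)])


@dataclass
class ParametricTransitionFit:
    """One cause-specific AFT fit: family, parameters, covariance, fit stats.

    ``theta`` holds the free parameters on the estimation scale
    (location, log-scale / log-shape / q, then the AFT coefficients);
    ``cov`` is the covariance of ``theta`` from the inverse observed
    information, used for multivariate-normal parameter draws in the
    probabilistic sensitivity analysis.
    """

    arc: Tuple[str, str]
    family: DistributionFamily
    theta: np.ndarray
    coef_names: Tuple[str, ...] = ()
    cov: Optional[np.ndarray] = None
    loglik: float = float("nan")
    n: int = 0
    n_events: int = 0
    comparison: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.family = DistributionFamily(self.family)
        self.theta = np.asarray(self.theta, dtype=float)
        expected = len(_dist_param_names(self.family)) + len(self.coef_names)
        if self.theta.size != expected:
            raise ValueError(
                f"theta has {self.theta.size} entries, expected {expected}"
            )
        if self.cov is not None:
            self.cov = np.asarray(self.cov, dtype=float)
            if self.cov.shape != (expected, expected):
                raise ValueError("covariance shape does not match theta")
        try:
            self._coef_idx = np.array(
                [COEFFICIENT_NAMES.index(nm) for nm in self.coef_names], dtype=int
            )
        except ValueError:
            self._coef_idx = None  # custom covariate set; use own ordering

    @property
    def n_dist_params(self) -> int:
        return len(_dist_param_names(self.family))

    @property
    def params(self) -> DistributionParams:
        """Baseline distribution (all covariates at reference/zero)."""
        return _decode_dist(self.family, self.theta[: self.n_dist_params])

    @property
    def betas(self) -> np.ndarray:
        return self.theta[self.n_dist_params:]

    @property
    def param_names(self) -> Tuple[str, ...]:
        return _dist_param_names(self.family) + tuple(self.coef_names)

    @property
    def k(self) -> int:
        return int(self.theta.size)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def bic(self) -> float:
        return self.k * np.log(self.n) - 2.0 * self.loglik

    def location_shift(self, x_full: np.ndarray) -> float:
        """Linear predictor for a full design vector (length 23)."""
        if len(self.coef_names) == 0:
            return 0.0
        if self._coef_idx is None:
            raise ValueError("fit uses a custom covariate set; pass matching x")
        return float(self.betas @ np.asarray(x_full, dtype=float)[self._coef_idx])

    def aft_params(self, x_full: np.ndarray) -> DistributionParams:
        """Covariate-adjusted distribution for one subject-sojourn."""
        return self.params.shifted(self.location_shift(x_full))

    def sample(self, rng: np.random.Generator) -> "ParametricTransitionFit":
        """Draw one parameter set from the fit's sampling distribution."""
        if self.cov is None:
            raise ValueError("fit carries no covariance; cannot sample")
        theta = rng.multivariate_normal(
            self.theta, self.cov, check_valid="raise", method="eigh"
        )
        return ParametricTransitionFit(
            self.arc, self.family, theta, self.coef_names,
            cov=None, loglik=self.loglik, n=self.n, n_events=self.n_events,
        )


# ---------------------------------------------------------------------------
# transition dataset construction
# ---------------------------------------------------------------------------

def build_transition_dataset(
    trajectories: Sequence[Trajectory],
    structure: TransitionStructure | None = None,
    cohort: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Decompose trajectories into sojourn and same-day ED records.

    One record per sojourn in a community/hospital state (competing exits
    encoded by ``to_state``; other destinations act as censoring in the
    cause-specific fits) and one record per ED visit with its same-day
    destination.  Time-dependent counters reflect events strictly before the
    record's entry; ``age_entry`` is the age at entry in years.

    If ``cohort`` is given (indexed or keyed by ``subject_id``), its baseline
    predictor columns are attached to every record.
    """
    structure = structure or TransitionStructure.default()
    instant = structure.instant_destinations
    base_by_id: Dict[int, Mapping] = {}
    if cohort is not None:
        base_by_id = {
            int(r["subject_id"]): r for r in cohort.to_dict("records")
        }

    rows: List[dict] = []
    for tr in trajectories:
        base = base_by_id.get(tr.subject_id, {})
        age0 = float(base.get("age", np.nan))
        counters = dict.fromkeys(COUNTER_COLUMNS, 0)
        entries = list(zip(tr.times, tr.states))
        for i, (t, s) in enumerate(entries):
            if s == MO:
                continue
            nxt = entries[i + 1] if i + 1 < len(entries) else None
            common = {
                "subject": tr.subject_id,
                "age_entry": age0 + t / DAYS_PER_YEAR if np.isfinite(age0) else np.nan,
                **counters,
            }
            for c in BASELINE_COLUMNS:
                if c != "age" and c in base:
                    common[c] = base[c]
            if s in ED_STATES:
                if nxt is None:
                    raise StructureError(
                        f"subject {tr.subject_id}: ED visit at day {t} never resolves"
                    )
                t2, dest = nxt
                if t2 != t:
                    raise StructureError(
                        f"subject {tr.subject_id}: ED state {s} must resolve same day"
                    )
                if dest not in instant.get(s, ()):
                    raise StructureError(f"arc {s}->{dest} not in structure")
                rows.append({
                    **common, "kind": "ed", "from_state": s, "to_state": dest,
                    "entry_day": t, "exit_day": t, "duration": 0.0, "event": True,
                })
                counters["n_copd_ed" if s == "EDC" else "n_other_ed"] += 1
            else:  # DX / HC / HO sojourn
                if nxt is not None:
                    t2, dest = nxt
                    if (s, dest) not in structure.parametric_arcs:
                        raise StructureError(f"arc {s}->{dest} not in structure")
                    rows.append({
                        **common, "kind": "sojourn", "from_state": s, "to_state": dest,
                        "entry_day": t, "exit_day": t2, "duration": t2 - t,
                        "event": True,
                    })
                else:
                    rows.append({
                        **common, "kind": "sojourn", "from_state": s, "to_state": None,
                        "entry_day": t, "exit_day": tr.horizon,
                        "duration": tr.horizon - t, "event": False,
                    })
                if s in HOSPITAL_STATES:
                    counters["n_copd_hosp" if s == "HC" else "n_other_hosp"] += 1
    df = pd.DataFrame(rows)
    order = [
        "kind", "subject", "from_state", "to_state", "entry_day", "exit_day",
        "duration", "event", "age_entry", *COUNTER_COLUMNS,
    ]
    extra = [c for c in df.columns if c not in order]
    return df[order + extra] if len(df) else df


def sojourn_records(records: pd.DataFrame, from_state: Optional[str] = None) -> pd.DataFrame:
    out = records[records["kind"] == "sojourn"]
    if from_state is not None:
        out = out[out["from_state"] == from_state]
    return out


def ed_records(records: pd.DataFrame, origin: Optional[str] = None) -> pd.DataFrame:
    out = records[records["kind"] == "ed"]
    if origin is not None:
        out = out[out["from_state"] == origin]
    return out


# ---------------------------------------------------------------------------
# parametric maximum likelihood
# ---------------------------------------------------------------------------

def _neg_loglik(
    theta: np.ndarray,
    family: DistributionFamily,
    t: np.ndarray,
    event: np.ndarray,
    X: Optional[np.ndarray],
    entry: Optional[np.ndarray],
) -> float:
    d = len(_dist_param_names(family))
    try:
        params = _decode_dist(family, theta[:d])
    except (ValueError, OverflowError):
        return 1e12
    loc = params.location
    if X is not None:
        loc = loc + X @ theta[d:]
    ll = 0.0
    ev, cen = event, ~event
    if ev.any():
        lp = _log_pdf(family, t[ev], loc[ev] if np.ndim(loc) else loc,
                      params.scale, params.shape)
        ll += lp.sum()
    if cen.any():
        tc = t[cen]
        locc = loc[cen] if np.ndim(loc) else loc
        pos = tc > 0
        if pos.any():
            ls = _log_sf(family, tc[pos],
                         locc[pos] if np.ndim(locc) else locc,
                         params.scale, params.shape)
            ll += ls.sum()
    if entry is not None:
        pos = entry > 0
        if pos.any():
            le = _log_sf(family, entry[pos],
                         loc[pos] if np.ndim(loc) else loc,
                         params.scale, params.shape)
            ll -= le.sum()
    if not np.isfinite(ll):
        return 1e12
    return -float(ll)


def _start_values(
    family: DistributionFamily, t: np.ndarray, event: np.ndarray, p: int
) -> np.ndarray:
    te = t[event]
    m = float(np.mean(np.log(te)))
    s = float(np.std(np.log(te), ddof=1)) if te.size > 1 else 0.8
    s = max(s, 0.2)
    if family is DistributionFamily.EXPONENTIAL:
        x0 = [np.log(t.sum() / event.sum())]
    elif family is DistributionFamily.GAMMA:
        x0 = [m, 0.0]
    elif family is DistributionFamily.GENERALIZED_GAMMA:
        x0 = [m, np.log(s), 0.2]
    else:
        x0 = [m, np.log(s)]
    return np.array(x0 + [0.0] * p)


def fit_survival(
    time: np.ndarray,
    event: np.ndarray,
    family: DistributionFamily | str,
    X: Optional[np.ndarray] = None,
    coef_names: Sequence[str] = (),
    arc: Tuple[str, str] = ("", ""),
    entry: Optional[np.ndarray] = None,
) -> ParametricTransitionFit:
    """Right-censored AFT maximum likelihood for one family.

    ``time`` are sojourn durations in days, ``event`` flags observed exits to
    the arc's destination (False = censored), ``X`` the design matrix for the
    AFT coefficients, ``entry`` optional left-truncation times (used by the
    non-default clock-forward mode).  The covariance comes from the inverse
    observed information at the optimum.
    """
    family = DistributionFamily(family)
    t = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if t.size == 0 or not event.any():
        raise InestimableError(f"arc {arc}: no uncensored events to fit")
    if np.any(t[event] <= 0):
        raise ValueError("event durations must be positive")
    if X is not None:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != t.size:
            raise ValueError("design matrix does not align with times")
        if X.shape[1] != len(coef_names):
            raise ValueError("coef_names must name every design column")
        if X.shape[1] == 0:
            X = None
    p = 0 if X is None else X.shape[1]
    x0 = _start_values(family, t, event, p)
    args = (family, t, event, X, entry)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        opts = {"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-9}
        res = optimize.minimize(
            _neg_loglik, x0, args=args, method="L-BFGS-B", options=opts,
        )
        if not res.success or not np.isfinite(res.fun):
            res2 = optimize.minimize(
                _neg_loglik, res.x if np.isfinite(res.fun) else x0, args=args,
                method="Nelder-Mead", options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
            )
            if res2.fun <= res.fun or not res.success:
                res = res2
        if not np.isfinite(res.fun) or res.fun >= 1e12:
            raise FitConvergenceError(
                f"arc {arc} family {family.value}: optimizer failed ({res.message})"
            )
        # polish + Hessian at the optimum
        res = optimize.minimize(
            _neg_loglik, res.x, args=args, method="L-BFGS-B", options=opts,
        )
        H = numdiff.approx_hess1(res.x, _neg_loglik, args=args)
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    # guard against numerically indefinite information matrices
    w, V = np.linalg.eigh(cov)
    cov = (V * np.clip(w, 0.0, None)) @ V.T
    return ParametricTransitionFit(
        arc=tuple(arc), family=family, theta=res.x,
        coef_names=tuple(coef_names), cov=cov,
        loglik=-float(res.fun), n=int(t.size), n_events=int(event.sum()),
    )


def fit_parametric(
    records: pd.DataFrame,
    arc: Tuple[str, str],
    family: DistributionFamily | str,
    covariates: Sequence[str] | None = COEFFICIENT_NAMES,
) -> ParametricTransitionFit:
    """Cause-specific fit of one arc from the sojourn-record table.

    Records must all share ``from_state == arc[0]``; exits to other
    destinations (and administrative censoring) censor the sojourn.
    """
    frm, to = arc
    rec = sojourn_records(records, frm)
    if len(rec) == 0:
        raise InestimableError(f"no sojourn records for state {frm}")
    t = rec["duration"].to_numpy(dtype=float)
    event = (rec["to_state"] == to).to_numpy(dtype=bool)
    # a zero-length censored sojourn carries no information but a zero-length
    # event is a same-day exit; nudge to half a day so log-time is defined
    t = np.where(t <= 0, 0.5, t)
    covariates = tuple(covariates or ())
    X = encode_frame(rec)[list(covariates)].to_numpy() if covariates else None
    return fit_survival(t, event, family, X, covariates, arc=arc)


def select_family(
    records: pd.DataFrame,
    arc: Tuple[str, str],
    covariates: Sequence[str] | None = COEFFICIENT_NAMES,
    threshold: float = PARSIMONY_THRESHOLD,
) -> ParametricTransitionFit:
    """Fit all six families to one arc and pick by AIC with a parsimony rule.

    The minimum-AIC family wins unless a family with fewer free parameters
    lies within ``threshold`` of the best on both AIC and BIC, in which case
    the fewest-parameter such family is preferred.  The six-row comparison
    table is attached to the returned fit as ``.comparison``.
    """
    fits: Dict[DistributionFamily, ParametricTransitionFit] = {}
    for fam in DistributionFamily:
        try:
            fits[fam] = fit_parametric(records, arc, fam, covariates)
        except (FitConvergenceError, InestimableError) as exc:
            if isinstance(exc, InestimableError):
                raise
            logger.warning("arc %s: %s family dropped (%s)", arc, fam.value, exc)
    if not fits:
        raise FitConvergenceError(f"arc {arc}: no family converged")
    table = pd.DataFrame(
        [
            {
                "family": f.family.value, "k": f.k, "loglik": f.loglik,
                "aic": f.aic, "bic": f.bic, "n": f.n, "n_events": f.n_events,
            }
            for f in fits.values()
        ]
    ).sort_values("aic", ignore_index=True)
    best = min(fits.values(), key=lambda f: f.aic)
    candidates = [
        f for f in fits.values()
        if f.aic - best.aic < threshold and f.bic - min(g.bic for g in fits.values()) < threshold
    ]
    winner = min(candidates, key=lambda f: (f.k, f.aic)) if candidates else best
    winner.comparison = table
    return winner


# ---------------------------------------------------------------------------
# multinomial same-day ED destination model
# ---------------------------------------------------------------------------

@dataclass
class MultinomialFit:
    """Multinomial-logit destination model for one ED state.

    ``coefs`` has one column per non-reference destination (rows: intercept
    then covariates); the reference destination (community, when present)
    has all-zero coefficients by the identifiability convention.
    """

    origin: str
    destinations: Tuple[str, ...]  # reference first
    coefs: pd.DataFrame
    cov: Optional[np.ndarray] = None
    loglik: float = float("nan")
    n: int = 0

    def __post_init__(self) -> None:
        if list(self.coefs.columns) != list(self.destinations[1:]):
            raise ValueError("coefficient columns must match non-reference destinations")

    @property
    def coef_names(self) -> Tuple[str, ...]:
        return tuple(self.coefs.index)

    def linear_predictors(self, x_full: np.ndarray) -> np.ndarray:
        names = [nm for nm in self.coefs.index if nm != "intercept"]
        idx = [COEFFICIENT_NAMES.index(nm) for nm in names]
        xv = np.concatenate([[1.0], np.asarray(x_full, dtype=float)[idx]])
        B = self.coefs.to_numpy()  # (p+1, m-1)
        return np.concatenate([[0.0], xv @ B])

    def sample(self, rng: np.random.Generator) -> "MultinomialFit":
        if self.cov is None:
            raise ValueError("fit carries no covariance; cannot sample")
        flat = self.coefs.to_numpy().ravel(order="F")
        draw = rng.multivariate_normal(
            flat, self.cov, check_valid="raise", method="eigh"
        )
        coefs = pd.DataFrame(
            draw.reshape(self.coefs.shape, order="F"),
            index=self.coefs.index, columns=self.coefs.columns,
        )
        return MultinomialFit(self.origin, self.destinations, coefs,
                              cov=None, loglik=self.loglik, n=self.n)


def fit_multinomial(
    records: pd.DataFrame,
    origin: str,
    covariates: Sequence[str] | None = COEFFICIENT_NAMES,
    structure: TransitionStructure | None = None,
) -> MultinomialFit:
    """Maximum-likelihood multinomial logit for same-day ED destinations.

    Reference destination is the community (DX) when observed; destinations
    with zero observations are dropped with a warning.  Convergence issues
    (e.g. separation) are surfaced as warnings from the optimizer.
    """
    import statsmodels.api as sm

    structure = structure or TransitionStructure.default()
    rec = ed_records(records, origin)
    if len(rec) == 0:
        raise InestimableError(f"no ED records for origin {origin}")
    allowed = structure.instant_destinations[origin]
    observed = [d for d in allowed if (rec["to_state"] == d).any()]
    dropped = set(allowed) - set(observed)
    if dropped:
        warnings.warn(
            f"{origin}: destinations {sorted(dropped)} have no observations; dropped",
            UserWarning, stacklevel=2,
        )
    if len(observed) < 2:
        raise InestimableError(f"{origin}: fewer than two observed destinations")
    dests = ([DX] if DX in observed else []) + [d for d in observed if d != DX]
    code = {d: i for i, d in enumerate(dests)}
    y = rec["to_state"].map(code).to_numpy()
    covariates = tuple(covariates or ())
    if covariates:
        Xc = encode_frame(rec)[list(covariates)].to_numpy()
        X = np.column_stack([np.ones(len(rec)), Xc])
    else:
        X = np.ones((len(rec), 1))
    names = ["intercept", *covariates]
    model = sm.MNLogit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            resm = model.fit(method="newton", maxiter=200, disp=False)
        except Exception:
            resm = model.fit(method="bfgs", maxiter=2000, disp=False)
    if not resm.mle_retvals.get("converged", True):
        warnings.warn(
            f"{origin}: multinomial fit did not fully converge "
            "(possible separation)", UserWarning, stacklevel=2,
        )
    coefs = pd.DataFrame(resm.params, index=names, columns=dests[1:])
    return MultinomialFit(
        origin=origin, destinations=tuple(dests), coefs=coefs,
        cov=np.asarray(resm.cov_params()), loglik=float(resm.llf), n=len(rec),
    )


def predict_destination_probs(fit: MultinomialFit, x_full: np.ndarray) -> Dict[str, float]:
    """Destination probabilities (softmax of the linear predictors); sum to 1."""
    lp = fit.linear_predictors(x_full)
    lp = lp - lp.max()
    p = np.exp(lp)
    p /= p.sum()
    return dict(zip(fit.destinations, p))


# ---------------------------------------------------------------------------
# parameter-table I/O (published-estimate format)
# ---------------------------------------------------------------------------

def write_parameter_tables(
    parametric: Mapping[Tuple[str, str], ParametricTransitionFit],
    multinomial: Mapping[str, MultinomialFit],
    out_dir,
) -> None:
    """Write fits as delimited text mirroring a published estimate table.

    Four TSV files: per-transition estimates and covariances for the
    multi-state models, and per-origin estimates and covariances for the
    ED multinomial models.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows, vrows = [], []
    for (frm, to), fit in sorted(parametric.items()):
        names = fit.param_names
        ses = (
            np.sqrt(np.clip(np.diag(fit.cov), 0, None))
            if fit.cov is not None else np.full(len(names), np.nan)
        )
        for nm, est, se in zip(names, fit.theta, ses):
            rows.append({
                "arc_from": frm, "arc_to": to, "family": fit.family.value,
                "parameter_name": nm, "estimate": est, "std_error": se,
            })
        if fit.cov is not None:
            for i, ni in enumerate(names):
                for j, nj in enumerate(names):
                    vrows.append({
                        "arc_from": frm, "arc_to": to,
                        "param_i": ni, "param_j": nj, "value": fit.cov[i, j],
                    })
    pd.DataFrame(rows).to_csv(out / "multistate_params.tsv", sep="\t", index=False)
    pd.DataFrame(vrows).to_csv(out / "multistate_vcov.tsv", sep="\t", index=False)

    mrows, mvrows = [], []
    for origin, fit in sorted(multinomial.items()):
        ses = (
            np.sqrt(np.clip(np.diag(fit.cov), 0, None)).reshape(
                fit.coefs.shape, order="F")
            if fit.cov is not None else np.full(fit.coefs.shape, np.nan)
        )
        for jd, dest in enumerate(fit.coefs.columns):
            for ip, nm in enumerate(fit.coefs.index):
                mrows.append({
                    "origin": origin, "destination": dest,
                    "reference": fit.destinations[0], "parameter_name": nm,
                    "estimate": fit.coefs.iloc[ip, jd], "std_error": ses[ip, jd],
                })
        if fit.cov is not None:
            names = [
                f"{dest}:{nm}" for dest in fit.coefs.columns for nm in fit.coefs.index
            ]
            for i, ni in enumerate(names):
                for j, nj in enumerate(names):
                    mvrows.append({
                        "origin": origin, "param_i": ni, "param_j": nj,
                        "value": fit.cov[i, j],
                    })
    pd.DataFrame(mrows).to_csv(out / "multinomial_params.tsv", sep="\t", index=False)
    pd.DataFrame(mvrows).to_csv(out / "multinomial_vcov.tsv", sep="\t", index=False)


def read_parameter_tables(in_dir):
    """Load parameter tables written by :func:`write_parameter_tables`.

    Returns ``(parametric, multinomial)`` dictionaries ready for simulation;
    log-likelihoods are not stored in the tables and read back as NaN.
    """
    from pathlib import Path

    inp = Path(in_dir)
    est = pd.read_csv(inp / "multistate_params.tsv", sep="\t")
    vcv_path = inp / "multistate_vcov.tsv"
    vcv = pd.read_csv(vcv_path, sep="\t") if vcv_path.exists() else pd.DataFrame()
    parametric: Dict[Tuple[str, str], ParametricTransitionFit] = {}
    for (frm, to), grp in est.groupby(["arc_from", "arc_to"], sort=True):
        family = DistributionFamily(grp["family"].iloc[0])
        dist_names = _dist_param_names(family)
        by_name = dict(zip(grp["parameter_name"], grp["estimate"]))
        coef_names = tuple(nm for nm in grp["parameter_name"] if nm not in dist_names)
        theta = np.array([by_name[nm] for nm in dist_names + coef_names])
        cov = None
        if len(vcv):
            sub = vcv[(vcv["arc_from"] == frm) & (vcv["arc_to"] == to)]
            if len(sub):
                names = dist_names + coef_names
                cov = (
                    sub.pivot(index="param_i", columns="param_j", values="value")
                    .loc[list(names), list(names)].to_numpy()
                )
        parametric[(frm, to)] = ParametricTransitionFit(
            (frm, to), family, theta, coef_names, cov=cov
        )

    mest = pd.read_csv(inp / "multinomial_params.tsv", sep="\t")
    mvcv_path = inp / "multinomial_vcov.tsv"
    mvcv = pd.read_csv(mvcv_path, sep="\t") if mvcv_path.exists() else pd.DataFrame()
    multinomial: Dict[str, MultinomialFit] = {}
    for origin, grp in mest.groupby("origin", sort=True):
        ref = grp["reference"].iloc[0]
        dest_order = list(dict.fromkeys(grp["destination"]))
        names = list(dict.fromkeys(grp["parameter_name"]))
        coefs = grp.pivot(index="parameter_name", columns="destination", values="estimate")
        coefs = coefs.loc[names, dest_order]
        cov = None
        if len(mvcv):
            sub = mvcv[mvcv["origin"] == origin]
            if len(sub):
                flat = [f"{d}:{nm}" for d in dest_order for nm in names]
                cov = (
                    sub.pivot(index="param_i", columns="param_j", values="value")
                    .loc[flat, flat].to_numpy()
                )
        multinomial[origin] = MultinomialFit(
            origin=origin, destinations=(ref, *dest_order), coefs=coefs, cov=cov
        )
    return parametric, multinomial
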