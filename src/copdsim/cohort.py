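"""Synthetic baseline cohorts and ground-truth event histories.

The published cohort is summarized only by its marginal table (age mean/SD,
and level frequencies for sex, smoking, rurality, deprivation and nine
comorbidities); the joint distribution of the real data is not available.
Baseline cohorts are therefore drawn from a Gaussian copula: a latent
multivariate normal with a configurable correlation matrix is thresholded
to the categorical marginals and transformed to the continuous age
marginal.  The copula spec is fully serializable (YAML), so any cohort is
reproducible from (spec, seed).

Age is drawn from a normal truncated to [35, 100] years whose parent
parameters are moment-matched so the *truncated* distribution has exactly
the published mean (63.9 y) and SD (13.8 y).

The module also provides a synthetic ground-truth model set
(:func:`default_true_model`) so estimation and simulation can be exercised
end-to-end with known parameters and no data access.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special, stats

from .covariates import (
    BASELINE_COLUMNS,
    COEFFICIENT_NAMES,
    COMORBIDITIES,
    DEPRIVATION_LEVELS,
    RURALITY_LEVELS,
    SMOKING_LEVELS,
    validate_cohort,
)
from .engine import DEFAULT_HORIZON_DAYS, ModelSet, simulate_cohort
from .families import DistributionFamily
from .states import DX, EDC, EDO, HC, HO, MO, Trajectory, TransitionStructure
from .transitions import MultinomialFit, ParametricTransitionFit, _dist_param_names

__all__ = [
    "CohortSpec",
    "default_cohort_spec",
    "generate_baseline",
    "generate_histories",
    "write_cohort",
    "read_cohort",
    "default_true_model",
]

# published cohort marginals (proportions; deprivation renormalised to sum 1)
_TABLE1 = {
    "age_mean": 63.9,
    "age_sd": 13.8,
    "female": 0.552,
    "smoking": {"current": 0.439, "former": 0.391, "never": 0.170},
    "rurality": {"urban": 0.463, "suburban": 0.393, "rural": 0.144},
    "deprivation": {1: 0.137, 2: 0.176, 3: 0.209, 4: 0.234, 5: 0.245},
    "comorbidities": {
        "chf": 0.110, "ihd": 0.175, "cancer": 0.136, "diabetes": 0.195,
        "asthma": 0.191, "dementia": 0.039, "depression": 0.047,
        "anxiety": 0.179, "hypertension": 0.526,
    },
}

_COPULA_VARS: Tuple[str, ...] = (
    "age", "female", "smoking", "rurality", "deprivation", *COMORBIDITIES
)

# modest positive latent correlations between age and the age-graded
# comorbidities; everything else independent by default
_DEFAULT_CORRELATIONS: Tuple[Tuple[str, str, float], ...] = (
    ("age", "chf", 0.15), ("age", "ihd", 0.15), ("age", "cancer", 0.10),
    ("age", "diabetes", 0.10), ("age", "dementia", 0.20),
    ("age", "hypertension", 0.20),
)


@dataclass
class CohortSpec:
    """Serializable recipe for a synthetic baseline cohort."""

    n: int = 10_000
    age_mean: float = _TABLE1["age_mean"]
    age_sd: float = _TABLE1["age_sd"]
    age_bounds: Tuple[float, float] = (35.0, 100.0)
    p_female: float = _TABLE1["female"]
    smoking: Dict[str, float] = field(default_factory=lambda: dict(_TABLE1["smoking"]))
    rurality: Dict[str, float] = field(default_factory=lambda: dict(_TABLE1["rurality"]))
    deprivation: Dict[int, float] = field(
        default_factory=lambda: dict(_TABLE1["deprivation"])
    )
    comorbidities: Dict[str, float] = field(
        default_factory=lambda: dict(_TABLE1["comorbidities"])
    )
    correlations: Tuple[Tuple[str, str, float], ...] = _DEFAULT_CORRELATIONS

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        for name, probs, levels in (
            ("smoking", self.smoking, SMOKING_LEVELS),
            ("rurality", self.rurality, RURALITY_LEVELS),
            ("deprivation", self.deprivation, DEPRIVATION_LEVELS),
        ):
            if set(probs) != set(levels):
                raise ValueError(f"{name} probabilities must cover levels {levels}")
            total = sum(probs.values())
            if abs(total - 1.0) > 0.02:
                raise ValueError(f"{name} probabilities sum to {total:.3f}, not 1")
            for k in probs:  # renormalise printed-precision tables
                probs[k] = probs[k] / total
        self.correlation_matrix()  # validates PSD

    def correlation_matrix(self) -> np.ndarray:
        p = len(_COPULA_VARS)
        idx = {v: i for i, v in enumerate(_COPULA_VARS)}
        R = np.eye(p)
        for a, b, rho in self.correlations:
            if a not in idx or b not in idx:
                raise ValueError(f"unknown predictor in correlation ({a}, {b})")
            if not -1.0 < rho < 1.0:
                raise ValueError(f"correlation ({a}, {b}) = {rho} outside (-1, 1)")
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = rho
        w = np.linalg.eigvalsh(R)
        if w.min() < -1e-10:
            raise ValueError(
                f"correlation matrix is not positive semi-definite "
                f"(min eigenvalue {w.min():.3g})"
            )
        return R

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["correlations"] = [list(c) for c in self.correlations]
        d["age_bounds"] = list(self.age_bounds)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        d = yaml.safe_load(Path(path).read_text())
        d["correlations"] = tuple(tuple(c) for c in d.get("correlations", ()))
        d["age_bounds"] = tuple(d.get("age_bounds", (35.0, 100.0)))
        d["deprivation"] = {int(k): v for k, v in d["deprivation"].items()}
        return cls(**d)


def default_cohort_spec(n: int = 10_000) -> CohortSpec:
    """The published-table-calibrated cohort recipe."""
    return CohortSpec(n=n)


@lru_cache(maxsize=32)
def _calibrated_truncnorm(
    mean: float, sd: float, lo: float, hi: float
) -> Tuple[float, float]:
    """Parent (mu, sigma) whose [lo, hi]-truncation has the target mean/SD."""

    def resid(p):
        mu, log_sigma = p
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.fsolve(resid, [mean, np.log(sd)], full_output=False)
    mu, sigma = float(sol[0]), float(np.exp(sol[1]))
    return mu, sigma


def generate_baseline(
    spec: CohortSpec | None = None, seed: int = 0, n: Optional[int] = None
) -> pd.DataFrame:
    """Draw a baseline cohort from the Gaussian copula; deterministic per seed.

    Returns one row per subject with the documented predictor columns;
    event counters are implicitly zero at diagnosis.
    """
    spec = spec or default_cohort_spec()
    size = spec.n if n is None else int(n)
    cols = ["subject_id", *BASELINE_COLUMNS]
    if size == 0:
        return pd.DataFrame(columns=cols)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    R = spec.correlation_matrix()
    L = np.linalg.cholesky(R + 1e-12 * np.eye(len(R)))
    Z = rng.standard_normal((size, len(_COPULA_VARS))) @ L.T
    U = special.ndtr(Z)
    col = {v: U[:, i] for i, v in enumerate(_COPULA_VARS)}

    mu, sigma = _calibrated_truncnorm(
        spec.age_mean, spec.age_sd, *spec.age_bounds
    )
    a, b = (spec.age_bounds[0] - mu) / sigma, (spec.age_bounds[1] - mu) / sigma
    age = stats.truncnorm.ppf(col["age"], a, b, loc=mu, scale=sigma)

    def categorical(u, probs: dict, levels: Sequence) -> np.ndarray:
        p = np.array([probs[lv] for lv in levels])
        edges = np.cumsum(p)[:-1]
        return np.asarray(levels, dtype=object)[np.searchsorted(edges, u)]

    df = pd.DataFrame({
        "subject_id": np.arange(size),
        "age": age,
        "smoking": categorical(col["smoking"], spec.smoking, SMOKING_LEVELS),
        "rurality": categorical(col["rurality"], spec.rurality, RURALITY_LEVELS),
        "deprivation": categorical(
            col["deprivation"], spec.deprivation, DEPRIVATION_LEVELS
        ).astype(int),
        # upper-tail threshold so positive latent correlation means the
        # indicator co-occurs with high values of its correlates
        "female": (col["female"] >= 1.0 - spec.p_female).astype(int),
    })
    for c in COMORBIDITIES:
        df[c] = (col[c] >= 1.0 - spec.comorbidities[c]).astype(int)
    df = df[cols]
    validate_cohort(df)
    return df


def generate_histories(
    cohort: pd.DataFrame,
    models: ModelSet,
    horizon: float = DEFAULT_HORIZON_DAYS,
    seed: int = 0,
    structure: TransitionStructure | None = None,
) -> List[Trajectory]:
    """Ground-truth event histories for a cohort: one engine run per subject."""
    return simulate_cohort(cohort, models, structure, horizon, seed=seed)


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort as delimited text (CSV, documented column names)."""
    df.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort table and validate its predictor domains."""
    df = pd.read_csv(path)
    validate_cohort(df)
    return df


# ---------------------------------------------------------------------------
# synthetic ground-truth model set
# ---------------------------------------------------------------------------

def _true_fit(
    arc: Tuple[str, str],
    family: DistributionFamily,
    location: float,
    scale: float | None = None,
    shape: float | None = None,
    betas: Optional[Dict[str, float]] = None,
) -> ParametricTransitionFit:
    dist_names = _dist_param_names(family)
    head = [location]
    if "log_scale" in dist_names:
        head.append(np.log(scale))
    if "log_shape" in dist_names:
        head.append(np.log(shape))
    if "q" in dist_names:
        head.append(shape)
    beta_vec = np.zeros(len(COEFFICIENT_NAMES))
    for nm, v in (betas or {}).items():
        beta_vec[COEFFICIENT_NAMES.index(nm)] = v
    theta = np.concatenate([head, beta_vec])
    ses = np.concatenate([
        np.full(len(head), 0.02), np.full(len(beta_vec), 0.005)
    ])
    return ParametricTransitionFit(
        arc, family, theta, tuple(COEFFICIENT_NAMES), cov=np.diag(ses ** 2)
    )


def _true_multinomial(
    origin: str,
    intercepts: Dict[str, float],
    betas: Dict[str, Dict[str, float]],
) -> MultinomialFit:
    dests = (DX, HC, HO, MO)
    names = ["intercept", "age", "smoking_current", "smoking_former"]
    coefs = pd.DataFrame(0.0, index=names, columns=list(dests[1:]))
    for d, v in intercepts.items():
        coefs.loc["intercept", d] = v
    for d, bd in betas.items():
        for nm, v in bd.items():
            coefs.loc[nm, d] = v
    k = coefs.size
    cov = np.diag(np.full(k, 0.01 ** 2))
    return MultinomialFit(origin, dests, coefs, cov=cov)


def default_true_model() -> ModelSet:
    """A synthetic ground-truth model set with known parameters.

    Entirely synthetic stand-in for a fitted parameter table: family
    assignments follow the per-transition families reported for this model
    class (log-logistic for the COPD-ED and hospital-exit arcs, Weibull for
    the non-COPD acute arcs, log-normal for COPD hospitalization and death
    from the community), with locations on realistic day scales (hospital
    sojourns of order 10 days, community sojourns of order years) and
    harmful smoking/age effects on the acute and mortality arcs.  Used for
    parameter-recovery tests, demos and scenario illustrations — the
    numbers are not estimates from any real cohort.
    """
    LL, WB, LN = (
        DistributionFamily.LOGLOGISTIC,
        DistributionFamily.WEIBULL,
        DistributionFamily.LOGNORMAL,
    )
    parametric = {
        (DX, EDC): _true_fit((DX, EDC), LL, np.log(5000.0), 0.9, betas={
            "age": -0.008, "smoking_current": -0.90, "smoking_former": -0.45,
            "asthma": -0.30, "n_copd_ed": -0.10,
        }),
        (DX, EDO): _true_fit((DX, EDO), WB, np.log(800.0), 1.1, betas={
            "age": -0.008, "chf": -0.30, "n_other_ed": -0.03,
        }),
        (DX, HC): _true_fit((DX, HC), LN, np.log(20000.0), 1.2, betas={
            "age": -0.012, "smoking_current": -0.70, "smoking_former": -0.35,
            "n_copd_ed": -0.10, "n_copd_hosp": -0.15,
        }),
        (DX, HO): _true_fit((DX, HO), WB, np.log(4500.0), 1.0, betas={
            "age": -0.018, "chf": -0.40, "cancer": -0.40, "n_other_hosp": -0.08,
        }),
        (DX, MO): _true_fit((DX, MO), LN, np.log(11000.0), 1.0, betas={
            "age": -0.040, "smoking_current": -0.50, "smoking_former": -0.25,
            "female": 0.15, "chf": -0.40, "cancer": -0.50, "dementia": -0.50,
            "n_copd_hosp": -0.10,
        }),
        (HC, DX): _true_fit((HC, DX), LL, np.log(10.0), 0.35, betas={
            "age": 0.005,
        }),
        (HC, MO): _true_fit((HC, MO), LL, np.log(60.0), 0.5, betas={
            "age": -0.015,
        }),
        (HO, DX): _true_fit((HO, DX), LL, np.log(7.0), 0.4, betas={
            "age": 0.005,
        }),
        (HO, MO): _true_fit((HO, MO), LL, np.log(90.0), 0.5, betas={
            "age": -0.015,
        }),
    }
    multinomial = {
        EDC: _true_multinomial(
            EDC,
            intercepts={HC: -1.47, HO: -3.66, MO: -5.50},
            betas={HC: {"age": 0.02, "smoking_current": 0.30},
                   MO: {"age": 0.03}},
        ),
        EDO: _true_multinomial(
            EDO,
            intercepts={HC: -4.38, HO: -1.55, MO: -5.50},
            betas={HO: {"age": 0.02}, MO: {"age": 0.03}},
        ),
    }
    return ModelSet(parametric=parametric, multinomial=multinomial)
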