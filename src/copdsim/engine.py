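"""Individual-level continuous-time microsimulation over the state structure.

Each subject is simulated with competing latent clocks: at entry to a
community or hospital state one sojourn time is drawn per parametric exit
arc from its covariate-adjusted distribution, the minimum wins, and times
are rounded up to whole days (ties between arcs on the same day broken by a
seeded uniform draw).  ED states resolve the same day through the
multinomial destination model.  Age advances with simulation time and the
four prior-event counters increment on each ED/hospital entry, so
time-dependent covariates affect every *subsequent* sojourn (covariates are
frozen at state entry, matching how the models are fitted).

Parameter-level uncertainty is propagated by a two-level nested scheme: an
outer loop draws one coefficient vector per model from its multivariate
normal sampling distribution, an inner loop re-simulates the whole cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .covariates import COUNTER_COLUMNS, encode_covariates
from .families import sample_time
from .states import (
    DX,
    ED_STATES,
    HOSPITAL_STATES,
    MO,
    StructureError,
    Trajectory,
    TransitionStructure,
)
from .transitions import (
    DAYS_PER_YEAR,
    MultinomialFit,
    ParametricTransitionFit,
    predict_destination_probs,
)

__all__ = [
    "ModelSet",
    "SubjectState",
    "simulate_subject",
    "simulate_cohort",
    "run_nested_uncertainty",
    "DEFAULT_HORIZON_DAYS",
]

#: 14 years of follow-up, the default simulation horizon
DEFAULT_HORIZON_DAYS = 5110.0


@dataclass
class ModelSet:
    """The complete model input of a simulation run.

    ``parametric`` maps each time-to-event arc to its fitted AFT model;
    ``multinomial`` maps each ED state to its same-day destination model.
    """

    parametric: Dict[Tuple[str, str], ParametricTransitionFit]
    multinomial: Dict[str, MultinomialFit]

    def validate(self, structure: TransitionStructure) -> None:
        """Fail fast if any reachable arc lacks a model."""
        missing = [a for a in structure.parametric_arcs if a not in self.parametric]
        if missing:
            raise StructureError(f"no parametric model for arcs: {sorted(missing)}")
        for origin in structure.instant_destinations:
            if origin not in self.multinomial:
                raise StructureError(f"no multinomial model for ED state {origin}")

    def has_covariances(self) -> bool:
        return all(f.cov is not None for f in self.parametric.values()) and all(
            f.cov is not None for f in self.multinomial.values()
        )

    def sample(self, rng: np.random.Generator) -> "ModelSet":
        """One outer-level draw of every model's coefficients."""
        return ModelSet(
            parametric={a: f.sample(rng) for a, f in self.parametric.items()},
            multinomial={o: f.sample(rng) for o, f in self.multinomial.items()},
        )


@dataclass
class SubjectState:
    """Mutable simulation state of one subject."""

    profile: Mapping
    state: str = DX
    entry_time: float = 0.0
    counters: Dict[str, int] = field(
        default_factory=lambda: dict.fromkeys(COUNTER_COLUMNS, 0)
    )

    def covariates(self) -> np.ndarray:
        age = float(self.profile["age"]) + self.entry_time / DAYS_PER_YEAR
        return encode_covariates(self.profile, age, self.counters)


def _subject_rng(seed: int, subject_id: int, *extra: int) -> np.random.Generator:
    """Deterministic per-subject stream, independent of batch composition."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), *map(int, extra), int(subject_id)])
    )


def _draw_destination(
    fit: MultinomialFit, x: np.ndarray, rng: np.random.Generator
) -> str:
    probs = predict_destination_probs(fit, x)
    u = rng.random()
    acc = 0.0
    for dest in fit.destinations:
        acc += probs[dest]
        if u < acc:
            return dest
    return fit.destinations[-1]


def simulate_subject(
    profile: Mapping,
    models: ModelSet,
    structure: TransitionStructure | None = None,
    horizon: float = DEFAULT_HORIZON_DAYS,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Simulate one subject from diagnosis (day 0, community) to death or horizon."""
    structure = structure or TransitionStructure.default()
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if rng is None:
        rng = np.random.default_rng()
    models.validate(structure)

    st = SubjectState(profile=profile)
    times: List[float] = [0.0]
    states: List[str] = [DX]

    while st.state != MO:
        x = st.covariates()
        if st.state in ED_STATES:
            # same-day resolution happens even when the visit falls on the
            # horizon day, so a trajectory never ends inside an ED state
            # covariates reflect events strictly before this visit;
            # then the visit itself increments its counter
            dest = _draw_destination(models.multinomial[st.state], x, rng)
            key = "n_copd_ed" if st.state == "EDC" else "n_other_ed"
            st.counters[key] += 1
            times.append(st.entry_time)
            states.append(dest)
            st.state = dest
            continue
        if st.entry_time >= horizon:
            break
        # community or hospital: competing latent sojourn clocks
        arcs = structure.parametric_exits(st.state)
        draws = []
        for arc in arcs:
            fit = models.parametric[arc]
            params = fit.aft_params(x)
            t_latent = sample_time(params, 0.0, rng)
            draws.append(math.ceil(t_latent) if math.isfinite(t_latent) else math.inf)
        best = min(draws)
        exit_time = st.entry_time + best
        if not math.isfinite(best) or exit_time > horizon:
            break  # censored at the horizon in the current state
        tied = [i for i, d in enumerate(draws) if d == best]
        pick = tied[0] if len(tied) == 1 else tied[int(rng.random() * len(tied))]
        dest = arcs[pick][1]
        if st.state in HOSPITAL_STATES:
            key = "n_copd_hosp" if st.state == "HC" else "n_other_hosp"
            st.counters[key] += 1
        times.append(exit_time)
        states.append(dest)
        st.state = dest
        st.entry_time = exit_time

    return Trajectory(
        subject_id=int(profile["subject_id"]),
        times=times, states=states, horizon=horizon,
    )


def simulate_cohort(
    cohort: pd.DataFrame,
    models: ModelSet,
    structure: TransitionStructure | None = None,
    horizon: float = DEFAULT_HORIZON_DAYS,
    seed: int = 0,
    stream_key: Sequence[int] = (),
) -> List[Trajectory]:
    """Simulate every subject with its own seeded substream.

    Substreams are keyed by ``(seed, *stream_key, subject_id)``, so a
    subject's trajectory is identical whether the cohort is simulated whole
    or in pieces — the common-random-numbers alignment used by paired
    counterfactual scenarios.
    """
    structure = structure or TransitionStructure.default()
    models.validate(structure)
    out = []
    for row in cohort.to_dict("records"):
        rng = _subject_rng(seed, row["subject_id"], *stream_key)
        out.append(simulate_subject(row, models, structure, horizon, rng))
    return out


def _nearest_psd(cov: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(0.5 * (cov + cov.T))
    return (V * np.clip(w, 0.0, None)) @ V.T


def _check_covariances(models: ModelSet, repair: bool) -> ModelSet:
    """Reject (or, behind the explicit flag, eigen-clip) non-PSD covariances."""
    import dataclasses

    tol = -1e-10

    def fix(fit, label):
        w = np.linalg.eigvalsh(0.5 * (fit.cov + fit.cov.T))
        if w.min() >= tol * max(1.0, abs(w.max())):
            return fit
        if not repair:
            raise ValueError(
                f"covariance for {label} is not positive semi-definite "
                f"(min eigenvalue {w.min():.3g}); pass repair_non_psd=True to "
                "project onto the nearest PSD matrix"
            )
        return dataclasses.replace(fit, cov=_nearest_psd(fit.cov))

    return ModelSet(
        parametric={a: fix(f, f"arc {a}") for a, f in models.parametric.items()},
        multinomial={o: fix(f, f"ED {o}") for o, f in models.multinomial.items()},
    )


def run_nested_uncertainty(
    cohort: pd.DataFrame,
    models: ModelSet,
    structure: TransitionStructure | None = None,
    horizon: float = DEFAULT_HORIZON_DAYS,
    n_outer: int = 200,
    seed: int = 0,
    inner_seed_mode: str = "vary",
    repair_non_psd: bool = False,
) -> List[List[Trajectory]]:
    """Two-level nested simulation propagating parameter uncertainty.

    Outer level: ``n_outer`` multivariate-normal draws of every model's
    coefficients (mean = estimates, covariance = fit covariance).  Inner
    level: one full-cohort simulation per draw.  Returns the per-replicate
    trajectory sets; deterministic given ``seed``.

    ``inner_seed_mode="vary"`` (default) gives each replicate fresh inner
    randomness; ``"common"`` reuses identical per-subject streams across
    replicates, so outer draws are the only source of between-replicate
    variation.
    """
    structure = structure or TransitionStructure.default()
    models.validate(structure)
    if not models.has_covariances():
        raise ValueError("every fit needs a covariance for the outer draws")
    if inner_seed_mode not in ("vary", "common"):
        raise ValueError("inner_seed_mode must be 'vary' or 'common'")
    models = _check_covariances(models, repair_non_psd)
    replicates = []
    for r in range(int(n_outer)):
        outer_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1, r]))
        drawn = models.sample(outer_rng)
        key = (2, r) if inner_seed_mode == "vary" else (2,)
        replicates.append(
            simulate_cohort(cohort, drawn, structure, horizon, seed=seed, stream_key=key)
        )
    return replicates
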