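"""Species Accumulation Index (SAI) evaluation of abiotic surrogates.

The evaluation mimics a planning situation where species data exist for only
q% of the planning plots. For each q and each repetition:

1. draw a uniform random subset of ⌈q% × n_plots⌉ plots;
2. run the greedy complementarity selection *within that subset* and assign
   its plots conservation importance scores in [0, 1];
3. fit a random-forest regression of those scores on the subset's surrogate
   covariates;
4. predict scores for *all* plots — out-of-bag predictions for the
   calibration plots themselves, so an uninformative surrogate cannot score
   better than random by memorizing its calibration data — and select the
   ``site_budget`` top-ranked;
5. count the unique target species S represented by that selection.

S is compared with O (species represented by the full-data greedy selection
at the same site budget) and R (mean species represented by ``n_random``
random plot subsets of the same size):

    SAI = (S − R) / (O − R)          (range-consistent, default: ≤ 1,
                                      1 iff S = O, 0 iff S = R)
    SAI = (S − R) / (O − S)          ("as printed" variant; +inf when S = O)

Values above the conventional 0.2 threshold mark a surrogate considered
good or reliable. Curves over q carry the per-repetition SAI values, their
mean, and a 95% percentile interval.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from ._rng import spawn_int, substream
from .io import CovariateTable, OccurrenceMatrix
from .selection import greedy_richness_selection, importance_scores

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationConfig",
    "SAICurve",
    "SurrogateComparison",
    "sai",
    "random_baseline",
    "evaluate_surrogate",
    "compare_surrogates",
    "RELIABILITY_THRESHOLD",
]

#: SAI above this value marks a surrogate conventionally considered reliable.
RELIABILITY_THRESHOLD = 0.2

DEFAULT_Q = tuple(range(5, 61, 5))


@dataclass(frozen=True)
class EvaluationConfig:
    """Parameters of one surrogacy evaluation.

    ``site_budget=None`` means "size of the full-data greedy selection" — the
    smallest plot set that represents every representable target species.
    """

    surrogate_variables: tuple[str, ...] = ()
    q_values: tuple[int, ...] = DEFAULT_Q
    n_models: int = 100
    n_random: int = 1000
    site_budget: int | None = None
    sai_variant: str = "range_consistent"  # or "as_printed"
    n_trees: int = 500
    seed: int = 0

    def validate(self, covariates: CovariateTable | pd.DataFrame | None = None) -> None:
        if not self.surrogate_variables:
            raise ValueError("surrogate_variables must be a nonempty covariate subset")
        if not all(0 < q < 100 for q in self.q_values):
            raise ValueError(f"q_values must lie in (0, 100): {self.q_values}")
        if self.n_models < 1 or self.n_random < 1:
            raise ValueError("n_models and n_random must be >= 1")
        if self.sai_variant not in ("range_consistent", "as_printed"):
            raise ValueError(f"unknown sai_variant {self.sai_variant!r}")
        if covariates is not None:
            cols = covariates.data.columns if isinstance(covariates, CovariateTable) else covariates.columns
            missing = [v for v in self.surrogate_variables if v not in cols]
            if missing:
                raise ValueError(f"surrogate variables not in covariate table: {missing}")


def sai(S: float, O: float, R: float, variant: str = "range_consistent") -> float:
    """Species Accumulation Index comparing surrogate (S), optimal (O) and random (R).

    The default range-consistent form (S−R)/(O−R) spans (−inf, 1] with 1 iff
    the surrogate matches the optimum and 0 iff it matches random selection.
    The ``as_printed`` form (S−R)/(O−S) returns +inf when S = O. When O = R
    surrogacy is unmeasurable and NaN is returned with a warning.
    """
    if O < R:
        raise ValueError(f"optimal representation O={O} below random baseline R={R}")
    if O == R:
        warnings.warn("O equals R: surrogacy unmeasurable, returning NaN", stacklevel=2)
        return float("nan")
    if variant == "range_consistent":
        return (S - R) / (O - R)
    if variant == "as_printed":
        if S == O:
            return float("inf")
        return (S - R) / (O - S)
    raise ValueError(f"unknown SAI variant {variant!r}")


def _incidence(occurrence: OccurrenceMatrix | pd.DataFrame, target: Sequence) -> np.ndarray:
    df = occurrence.data if isinstance(occurrence, OccurrenceMatrix) else occurrence
    return df[list(target)].to_numpy(dtype=bool)


def random_baseline(
    occurrence: OccurrenceMatrix | pd.DataFrame,
    target: Sequence,
    k: int,
    n_random: int = 1000,
    seed: int = 0,
) -> float:
    """Mean target species represented by ``n_random`` uniform draws of ``k`` plots."""
    inc = _incidence(occurrence, target)
    n = inc.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of plots ({n})")
    if k == 0:
        return 0.0
    rng = substream(seed, "random_baseline", k)
    counts = np.empty(n_random)
    for i in range(n_random):
        idx = rng.choice(n, size=k, replace=False)
        counts[i] = inc[idx].any(axis=0).sum()
    return float(counts.mean())


@dataclass
class SAICurve:
    """SAI point estimates and 95% percentile intervals over q for one surrogate set."""

    surrogate_variables: tuple[str, ...]
    q_values: tuple[int, ...]
    sai_values: pd.DataFrame  # n_models × len(q_values), columns = q
    S_values: pd.DataFrame  # per-repetition species represented
    S_mean: pd.Series
    O: float
    R_mean: float
    site_budget: int
    sai_variant: str
    reliability_threshold: float = RELIABILITY_THRESHOLD

    @property
    def sai_mean(self) -> pd.Series:
        return self.sai_values.mean()

    @property
    def ci_low(self) -> pd.Series:
        return self.sai_values.quantile(0.025)

    @property
    def ci_high(self) -> pd.Series:
        return self.sai_values.quantile(0.975)

    def to_dict(self) -> dict:
        return {
            "surrogate_variables": list(self.surrogate_variables),
            "q_values": list(self.q_values),
            "sai_mean": self.sai_mean.tolist(),
            "ci_low": self.ci_low.tolist(),
            "ci_high": self.ci_high.tolist(),
            "S_mean": self.S_mean.tolist(),
            "O": self.O,
            "R_mean": self.R_mean,
            "site_budget": self.site_budget,
            "sai_variant": self.sai_variant,
            "reliability_threshold": self.reliability_threshold,
        }


def _resolve_target(occurrence: OccurrenceMatrix, target: Sequence | None) -> list:
    if target is not None:
        return list(target)
    thr = occurrence.threatened_ids
    if not thr:
        raise ValueError("no target given and occurrence matrix flags no threatened species")
    return thr


def _full_optimum(occurrence: OccurrenceMatrix, target: Sequence, site_budget: int | None):
    """Full-data greedy selection; O = species represented at the site budget."""
    full = greedy_richness_selection(occurrence, target)
    budget = len(full.ordered_plots) if site_budget is None else int(site_budget)
    if budget < 1:
        raise ValueError("site budget must be >= 1")
    steps = min(budget, len(full.represented))
    O = float(full.represented[steps - 1]) if steps else 0.0
    return full, budget, O


def evaluate_surrogate(
    occurrence: OccurrenceMatrix,
    covariates: CovariateTable | pd.DataFrame,
    config: EvaluationConfig,
    target: Sequence | None = None,
) -> SAICurve:
    """Evaluate one surrogate variable set; returns its SAI curve over q.

    ``target`` defaults to the threatened species flagged in ``occurrence``
    (the conservation object). Subsets whose plots hold no target species are
    redrawn with a logged warning; more redraw failures than ``n_models``
    abort the evaluation.
    """
    config.validate(covariates)
    target = _resolve_target(occurrence, target)
    cov = covariates.data if isinstance(covariates, CovariateTable) else covariates
    cov = cov[list(config.surrogate_variables)]
    if not occurrence.plot_ids.equals(cov.index):
        raise ValueError("occurrence and covariate plots misaligned")

    n = occurrence.n_plots
    inc = _incidence(occurrence, target)
    X_all = cov.to_numpy(dtype=float)

    full, budget, O = _full_optimum(occurrence, target, config.site_budget)
    R_mean = random_baseline(occurrence, target, budget, config.n_random, config.seed)

    sai_cols: dict[int, np.ndarray] = {}
    S_cols: dict[int, np.ndarray] = {}
    for q in config.q_values:
        k = int(np.ceil(q / 100 * n))
        S_reps = np.empty(config.n_models)
        failures = 0
        for m in range(config.n_models):
            while True:
                rng = substream(config.seed, "subset", q, m, failures)
                sub_idx = np.sort(rng.choice(n, size=k, replace=False))
                if inc[sub_idx].any():
                    break
                failures += 1
                logger.warning("q=%d rep %d: subset holds no target species, redrawing", q, m)
                if failures > config.n_models:
                    raise RuntimeError(f"q={q}: more subset redraws than n_models; data too sparse")
            sub_occ = occurrence.data.iloc[sub_idx]
            sub_sel = greedy_richness_selection(sub_occ, target)
            scores = importance_scores(sub_sel).to_numpy()
            forest = RandomForestRegressor(
                n_estimators=config.n_trees,
                max_features=1.0 / 3.0,  # p/3 candidates per split (floored at 1)
                random_state=spawn_int(config.seed, "forest", q, m),
                oob_score=True,
                n_jobs=1,
            )
            with warnings.catch_warnings():
                # tiny calibration subsets can leave isolated rows without OOB trees
                warnings.simplefilter("ignore", UserWarning)
                forest.fit(X_all[sub_idx], scores)
            predicted = forest.predict(X_all)
            oob = forest.oob_prediction_
            predicted[sub_idx] = np.where(np.isfinite(oob), oob, predicted[sub_idx])
            # stable sort on negated scores: ties resolved by input plot order
            chosen = np.argsort(-predicted, kind="stable")[:budget]
            S_reps[m] = inc[chosen].any(axis=0).sum()
        S_cols[q] = S_reps
        sai_cols[q] = np.array([sai(s, O, R_mean, config.sai_variant) for s in S_reps])

    sai_df = pd.DataFrame(sai_cols)
    S_df = pd.DataFrame(S_cols)
    return SAICurve(
        surrogate_variables=tuple(config.surrogate_variables),
        q_values=tuple(config.q_values),
        sai_values=sai_df,
        S_values=S_df,
        S_mean=S_df.mean(),
        O=O,
        R_mean=R_mean,
        site_budget=budget,
        sai_variant=config.sai_variant,
    )


@dataclass
class SurrogateComparison:
    """Paired SAI curves for several surrogate variable sets on shared subset draws."""

    curves: dict[str, SAICurve]
    differences: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    # columns: set_a, set_b, q, mean_diff, ci_low, ci_high (paired percentile)

    def to_dict(self) -> dict:
        return {
            "curves": {name: c.to_dict() for name, c in self.curves.items()},
            "differences": self.differences.to_dict(orient="records"),
        }


def compare_surrogates(
    occurrence: OccurrenceMatrix,
    covariates: CovariateTable | pd.DataFrame,
    variable_sets: Mapping[str, Sequence[str]],
    config: EvaluationConfig,
    target: Sequence | None = None,
) -> SurrogateComparison:
    """Evaluate several surrogate variable sets on identical subset draws.

    The calibration subsets and forest seeds depend only on (seed, q,
    repetition), not on the variable set, so per-q differences between sets
    are paired: identical sets yield bitwise-identical curves, and paired
    percentile intervals of the differences are variance-reduced.
    """
    if len(variable_sets) < 2:
        raise ValueError("need at least 2 variable sets to compare")
    curves = {
        name: evaluate_surrogate(
            occurrence, covariates, replace(config, surrogate_variables=tuple(vars_)), target
        )
        for name, vars_ in variable_sets.items()
    }
    rows = []
    names = list(curves)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            diff = curves[a].sai_values - curves[b].sai_values
            for q in config.q_values:
                d = diff[q]
                rows.append(
                    {
                        "set_a": a,
                        "set_b": b,
                        "q": q,
                        "mean_diff": float(d.mean()),
                        "ci_low": float(d.quantile(0.025)),
                        "ci_high": float(d.quantile(0.975)),
                    }
                )
    return SurrogateComparison(curves=curves, differences=pd.DataFrame(rows))
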