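"""Greedy complementarity ("species richness") reserve selection.

At each step the plot contributing the largest number of target species not
yet represented by previously selected plots is added; selection stops when no
plot adds a new target species (or an optional site budget is exhausted).
This is the classic iterative richness/complementarity heuristic for the
minimum-representation set problem. Selected plots receive conservation
importance scores in (0, 1]: the marginal gain at selection normalized by the
largest marginal gain, so the first-selected (richest) plot scores 1 and
unselected plots score 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import OccurrenceMatrix

__all__ = ["SelectionResult", "greedy_richness_selection", "importance_scores"]


@dataclass
class SelectionResult:
    """Outcome of a greedy richness selection.

    Attributes
    ----------
    ordered_plots
        Plot IDs in selection order.
    marginal_gains
        Newly represented target species contributed by each selected plot
        (strictly positive, nonincreasing).
    represented
        Cumulative count of represented target species after each step.
    target_species
        The species set the selection aims to represent.
    unrepresentable
        Target species occurring in no plot; reported, not an error.
    plot_ids
        All candidate plot IDs, in input order.
    """

    ordered_plots: list
    marginal_gains: list[int]
    represented: list[int]
    target_species: list
    unrepresentable: list
    plot_ids: list

    @property
    def n_represented(self) -> int:
        return self.represented[-1] if self.represented else 0

    @property
    def scores(self) -> pd.Series:
        return importance_scores(self)

    def to_dict(self) -> dict:
        return {
            "ordered_plots": list(self.ordered_plots),
            "marginal_gains": [int(g) for g in self.marginal_gains],
            "represented": [int(r) for r in self.represented],
            "n_target_species": len(self.target_species),
            "unrepresentable": list(self.unrepresentable),
            "importance_scores": {str(k): float(v) for k, v in self.scores.items()},
        }


def _target_matrix(
    occurrence: OccurrenceMatrix | pd.DataFrame, target: Sequence
) -> tuple[pd.DataFrame, list]:
    df = occurrence.data if isinstance(occurrence, OccurrenceMatrix) else occurrence
    target = list(target)
    if len(target) == 0:
        raise ValueError("target species set is empty")
    missing = [s for s in target if s not in df.columns]
    if missing:
        raise ValueError(f"target species not in occurrence matrix: {missing[:5]}")
    return df[target], target


def greedy_richness_selection(
    occurrence: OccurrenceMatrix | pd.DataFrame,
    target: Sequence,
    site_budget: int | None = None,
) -> SelectionResult:
    """Select plots greedily by complementary target-species richness.

    Ties (several plots adding equally many new species) are broken by input
    plot order, for determinism. ``site_budget`` optionally caps the number of
    selected plots; by default selection runs to full representation.
    """
    sub, target = _target_matrix(occurrence, target)
    incidence = sub.to_numpy(dtype=bool)  # plots × targets
    plot_ids = list(sub.index)
    unrepresentable = [s for s, present in zip(target, incidence.any(axis=0)) if not present]

    uncovered = incidence.any(axis=0)  # representable & not yet covered
    ordered: list = []
    gains: list[int] = []
    cumulative: list[int] = []
    covered = 0
    budget = len(plot_ids) if site_budget is None else int(site_budget)
    while len(ordered) < budget:
        new_counts = (incidence & uncovered).sum(axis=1)
        best = int(np.argmax(new_counts))  # argmax takes the first maximum: input-order tie-break
        if new_counts[best] == 0:
            break
        ordered.append(plot_ids[best])
        gains.append(int(new_counts[best]))
        covered += int(new_counts[best])
        cumulative.append(covered)
        uncovered &= ~incidence[best]
    return SelectionResult(
        ordered_plots=ordered,
        marginal_gains=gains,
        represented=cumulative,
        target_species=target,
        unrepresentable=unrepresentable,
        plot_ids=plot_ids,
    )


def importance_scores(selection: SelectionResult) -> pd.Series:
    """Per-plot conservation importance in [0, 1].

    Selected plots score ``marginal_gain / max(marginal_gains)`` — the first
    pick (highest richness of unrepresented species) scores exactly 1;
    unselected plots score 0. An empty selection yields all zeros.
    """
    scores = pd.Series(0.0, index=pd.Index(selection.plot_ids), name="importance")
    if selection.ordered_plots:
        top = max(selection.marginal_gains)
        for plot, gain in zip(selection.ordered_plots, selection.marginal_gains):
            scores.loc[plot] = gain / top
    return scores
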