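"""Iterative variance-inflation-factor (VIF) screening of covariates.

VIF_j = 1 / (1 - R²_j), where R²_j is the coefficient of determination of an
intercept OLS regression of covariate j on all remaining covariates. The
stepwise reduction repeatedly removes the single covariate with the largest
VIF until every remaining VIF falls below the threshold (default 3, the
conventional strict screen) or one variable remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CovariateTable

__all__ = ["CollinearityReport", "compute_vif", "reduce_collinearity"]

# R² this close to 1 is treated as exact linear dependence
_SINGULAR_TOL = 1e-10

DEFAULT_VIF_THRESHOLD = 3.0


@dataclass
class CollinearityReport:
    """Trajectory of a stepwise VIF reduction."""

    retained: list[str]
    dropped: list[tuple[str, float, int]] = field(default_factory=list)  # (name, VIF at removal, iteration)
    final_vifs: dict[str, float] = field(default_factory=dict)
    threshold: float = DEFAULT_VIF_THRESHOLD

    @property
    def dropped_names(self) -> list[str]:
        return [name for name, _, _ in self.dropped]

    def to_dict(self) -> dict:
        return {
            "retained": self.retained,
            "dropped": [
                {"variable": n, "vif_at_removal": v, "iteration": i} for n, v, i in self.dropped
            ],
            "final_vifs": self.final_vifs,
            "threshold": self.threshold,
        }


def _as_frame(covariates: CovariateTable | pd.DataFrame) -> pd.DataFrame:
    df = covariates.data if isinstance(covariates, CovariateTable) else covariates
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ValueError(f"VIF requires all-numeric covariates; encode first: {non_numeric}")
    return df


def compute_vif(covariates: CovariateTable | pd.DataFrame) -> pd.Series:
    """VIF for every covariate column.

    Exact linear dependence yields ``inf`` (a sentinel, not an exception) so
    that the stepwise reduction can still rank and remove the offender.

    Raises
    ------
    ValueError
        If fewer than 2 columns, no more rows than columns, or any column is
        constant (zero variance).
    """
    df = _as_frame(covariates)
    n, p = df.shape
    if p < 2:
        raise ValueError("VIF needs at least 2 covariates")
    if n <= p:
        raise ValueError(f"VIF needs more rows than covariates (n={n}, p={p})")
    X = df.to_numpy(dtype=float)
    sd = X.std(axis=0)
    constant = df.columns[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant covariate column(s): {constant}")

    vifs = {}
    intercept = np.ones((n, 1))
    for j, name in enumerate(df.columns):
        y = X[:, j]
        others = np.hstack([intercept, np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        vifs[name] = np.inf if 1.0 - r2 < _SINGULAR_TOL else 1.0 / (1.0 - r2)
    return pd.Series(vifs, name="VIF")


def reduce_collinearity(
    covariates: CovariateTable | pd.DataFrame,
    threshold: float = DEFAULT_VIF_THRESHOLD,
) -> CollinearityReport:
    """Stepwise VIF reduction: drop the worst covariate until all VIFs < threshold.

    Ties at the maximum VIF are broken alphabetically for determinism, so the
    retained set is invariant to the input column order.
    """
    df = _as_frame(covariates)
    dropped: list[tuple[str, float, int]] = []
    iteration = 0
    while df.shape[1] > 1:
        iteration += 1
        vifs = compute_vif(df)
        worst = vifs.max()
        if worst < threshold:
            break
        candidates = sorted(vifs.index[vifs == worst])
        victim = candidates[0]
        dropped.append((victim, float(worst), iteration))
        df = df.drop(columns=victim)
    final = compute_vif(df).to_dict() if df.shape[1] > 1 else {c: 1.0 for c in df.columns}
    return CollinearityReport(
        retained=list(df.columns), dropped=dropped, final_vifs=final, threshold=threshold
    )
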