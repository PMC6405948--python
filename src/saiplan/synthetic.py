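"""Synthetic plot-network landscapes for testing the surrogacy pipeline.

The generator emulates a Patagonian permanent-plot network: ~145 plots
surveyed for ~470 vascular plant species of which 37 are listed as
threatened, with plot-level environmental covariates including a soil organic
carbon stock (Mg C ha⁻¹ to 30 cm). The key generative assumption mirrors the
empirical pattern under study: threatened-species occurrence probability
rises with soil carbon on the log-odds scale, while the bulk of the flora is
independent of the covariates, so any surrogacy signal traces to the
threatened subset.

Generative scheme
-----------------
* soil carbon: log-normal (stocks are nonnegative and right-skewed in field
  data); standardized internally wherever it enters a model.
* other abiotic covariates: standard normal, mutually independent, except for
  ``collinear_pairs`` near-duplicate columns (r > 0.95) included to exercise
  the VIF screen.
* threatened species s: a random ``habitat_fraction`` of the plots is
  suitable habitat; within it, occurrence in plot i ~ Bernoulli with
  logit p_si = logit(b_s) + soc_effect × z(SOC_i), b_s drawn uniformly from
  ``threatened_prevalence_range``; outside its habitat the species is absent.
  The habitat masks keep threatened species complementary — without them a
  single shared soil-carbon gradient stacks every threatened species into
  the highest-carbon plot and the optimal conservation scenario collapses to
  one site, which no field network resembles.
* non-threatened species: Bernoulli(b_s), b_s uniform on
  ``baseline_prevalence_range``, independent of all covariates by default
  (``nontarget_coupling`` adds a mild soil-carbon coupling when nonzero).

Random draws use named substreams of the master seed (covariates /
baselines / occurrence), so e.g. adding a covariate never perturbs the
occurrence draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .io import CovariateTable, OccurrenceMatrix, write_covariates, write_occurrence, write_threatened

logger = logging.getLogger(__name__)

__all__ = ["SyntheticConfig", "SyntheticLandscape", "default_config", "generate_landscape", "write_landscape"]

# Fig. 2-style abiotic covariate labels (climate / topography / soil history)
ABIOTIC_NAMES = (
    "soil_age",
    "landform_class",
    "epoch_soil_formation",
    "min_ndvi",
    "temp_wettest_quarter",
    "temp_coldest_quarter",
    "topographic_variability",
    "depositional_environment",
)

SOIL_CARBON = "soil_carbon"


class ConfigurationError(ValueError):
    """Raised for an invalid synthetic-landscape configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic landscape.

    Defaults reproduce the emulated network: 145 plots, 470 species, 37
    threatened, 8 abiotic covariates plus soil carbon, and a strong positive
    soil-carbon coupling of threatened occurrence (log-odds slope 2 per SD of
    soil carbon).
    """

    n_plots: int = 145
    n_species: int = 470
    n_threatened: int = 37
    n_covariates: int = 8  # abiotic covariates besides soil carbon
    soc_effect: float = 2.0  # log-odds slope on standardized soil carbon
    baseline_prevalence_range: tuple[float, float] = (0.02, 0.35)
    threatened_prevalence_range: tuple[float, float] = (0.02, 0.10)  # within suitable habitat
    habitat_fraction: float = 0.15  # share of plots forming each threatened species' habitat
    nontarget_coupling: float = 0.0  # optional soil-carbon log-odds slope for the bulk flora
    collinear_pairs: int = 1  # near-duplicate covariate columns (r > 0.95)
    seed: int = 20190307

    def validate(self) -> None:
        if self.n_plots < 2:
            raise ConfigurationError(f"n_plots must be >= 2, got {self.n_plots}")
        if self.n_threatened > self.n_species:
            raise ConfigurationError(
                f"n_threatened ({self.n_threatened}) exceeds n_species ({self.n_species})"
            )
        if self.n_threatened < 0 or self.n_species < 1:
            raise ConfigurationError("species counts must be positive")
        for name in ("baseline_prevalence_range", "threatened_prevalence_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigurationError(f"{name} must be ordered probabilities in [0,1], got {(lo, hi)}")
        if self.n_covariates < 1:
            raise ConfigurationError("need at least one abiotic covariate")
        if self.collinear_pairs < 0 or self.collinear_pairs > self.n_covariates:
            raise ConfigurationError("collinear_pairs must be between 0 and n_covariates")
        if not 0.0 < self.habitat_fraction <= 1.0:
            raise ConfigurationError("habitat_fraction must lie in (0, 1]")


@dataclass
class SyntheticLandscape:
    """A generated landscape plus the ground truth that produced it."""

    occurrence: OccurrenceMatrix
    covariates: CovariateTable
    threatened_ids: list[str]
    truth: dict = field(default_factory=dict)  # generating log-odds slopes per covariate

    @property
    def threatened_counts(self) -> pd.Series:
        """Number of threatened species recorded in each plot."""
        mask = self.occurrence.threatened_mask.to_numpy()
        return self.occurrence.data.loc[:, mask].sum(axis=1).rename("threatened_count")


def default_config() -> SyntheticConfig:
    """The emulated network at its published scale (145 plots, 470 species, 37 threatened)."""
    return SyntheticConfig()


def _logit(p: np.ndarray | float) -> np.ndarray | float:
    return np.log(p / (1.0 - p))


def generate_landscape(config: SyntheticConfig) -> SyntheticLandscape:
    """Draw one landscape from the generative scheme in the module docstring.

    Non-threatened species observed in zero plots carry no information for
    any downstream stage and are dropped with a warning. Threatened species
    drawn all-zero are redrawn (their occurrence is conditioned on being
    present somewhere) so the threatened set keeps its configured size.
    """
    config.validate()
    seed = config.seed

    # --- covariates -------------------------------------------------------
    rng_cov = substream(seed, "covariates")
    n = config.n_plots
    soc = rng_cov.lognormal(mean=np.log(45.0), sigma=0.5, size=n)  # Mg C / ha to 30 cm
    cols: dict[str, np.ndarray] = {SOIL_CARBON: soc}
    names = [
        ABIOTIC_NAMES[i] if i < len(ABIOTIC_NAMES) else f"abiotic_{i + 1}"
        for i in range(config.n_covariates)
    ]
    for name in names:
        cols[name] = rng_cov.normal(size=n)
    for k in range(config.collinear_pairs):
        base = names[k]
        # r > 0.95 with the base column: 0.2 SD of independent noise gives r ≈ 0.98
        cols[f"{base}_dup"] = cols[base] + 0.2 * rng_cov.normal(size=n)
    covariates = CovariateTable(
        pd.DataFrame(cols, index=pd.Index([f"plot_{i + 1:03d}" for i in range(n)], name="plot_id")),
        soil_carbon_name=SOIL_CARBON,
    )
    soc_z = (soc - soc.mean()) / soc.std()

    # --- per-species baselines -------------------------------------------
    rng_base = substream(seed, "baselines")
    n_thr, n_sp = config.n_threatened, config.n_species
    species_ids = [f"sp_{i + 1:04d}" for i in range(n_sp)]
    threatened_ids = [str(s) for s in rng_base.choice(species_ids, size=n_thr, replace=False)]
    thr_set = set(threatened_ids)
    lo_t, hi_t = config.threatened_prevalence_range
    lo_b, hi_b = config.baseline_prevalence_range
    baselines = {
        s: rng_base.uniform(lo_t, hi_t) if s in thr_set else rng_base.uniform(lo_b, hi_b)
        for s in species_ids
    }

    # suitable-habitat plot mask per threatened species: keeps the threatened
    # flora complementary instead of fully nested along the carbon gradient
    rng_hab = substream(seed, "habitats")
    n_habitat = max(1, int(round(config.habitat_fraction * n)))
    habitats = {
        s: np.isin(np.arange(n), rng_hab.choice(n, size=n_habitat, replace=False))
        for s in threatened_ids
    }

    # --- occurrence -------------------------------------------------------
    rng_occ = substream(seed, "occurrence")
    occ_cols: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for s in species_ids:
        b = np.clip(baselines[s], 1e-6, 1 - 1e-6)
        if s in thr_set:
            logits = _logit(b) + config.soc_effect * soc_z
            p = np.where(habitats[s], 1.0 / (1.0 + np.exp(-logits)), 0.0)
            draw = (rng_occ.random(n) < p).astype(np.int8)
            attempts = 0
            while draw.sum() == 0 and attempts < 1000:
                draw = (rng_occ.random(n) < p).astype(np.int8)
                attempts += 1
            if draw.sum() == 0:  # pathological baseline; force presence at the likeliest plot
                draw[int(np.argmax(p))] = 1
            if attempts:
                logger.debug("threatened species %s redrawn %d time(s)", s, attempts)
        else:
            if config.nontarget_coupling:
                logits = _logit(b) + config.nontarget_coupling * soc_z
                p = 1.0 / (1.0 + np.exp(-logits))
                draw = (rng_occ.random(n) < p).astype(np.int8)
            else:
                draw = (rng_occ.random(n) < b).astype(np.int8)
            if draw.sum() == 0:
                dropped.append(s)
                continue
        occ_cols[s] = draw
    if dropped:
        logger.warning("dropped %d species observed in zero plots: %s%s",
                       len(dropped), dropped[:5], "..." if len(dropped) > 5 else "")

    occurrence = OccurrenceMatrix(pd.DataFrame(occ_cols, index=covariates.plot_ids))
    occurrence.set_threatened(threatened_ids)

    truth = {SOIL_CARBON: float(config.soc_effect), **{name: 0.0 for name in covariates.variables if name != SOIL_CARBON}}
    return SyntheticLandscape(
        occurrence=occurrence,
        covariates=covariates,
        threatened_ids=threatened_ids,
        truth={"slopes": truth, "config": asdict(config)},
    )


def write_landscape(landscape: SyntheticLandscape, outdir: str | Path) -> dict[str, Path]:
    """Write occurrence.csv, covariates.csv and threatened.csv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "occurrence": outdir / "occurrence.csv",
        "covariates": outdir / "covariates.csv",
        "threatened": outdir / "threatened.csv",
    }
    write_occurrence(landscape.occurrence, paths["occurrence"])
    write_covariates(landscape.covariates, paths["covariates"])
    write_threatened(landscape.threatened_ids, paths["threatened"])
    return paths
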