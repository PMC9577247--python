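"""Factor "heritability": variance shares, genetic h2, rankings, bootstrap CIs.

A term's heritability share is its variance divided by the sum of every
component including the residual, so the shares of one metric always sum to
one.  Genetic heritability h2 is the summed share of the biomass terms
(by default Variety and Section:Variety), i.e. the proportion of total
variance attributable to the biomass source rather than processing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .core_data import ValidationError
from .synthetic_data import GenerativeSpec, simulate_observations, spawn_seeds
from .variance_components import (RESIDUAL, EMSSolver, ModelSpec,
                                  VarianceComponents)

#: Terms counted as "genetic" (biomass-source) by default.
GENETIC_TERMS: frozenset[str] = frozenset({"Variety", "Section:Variety"})


class UndefinedShareError(ValidationError):
    """All components are zero, so variance shares are undefined."""


def _as_mapping(components) -> dict[str, float]:
    if isinstance(components, VarianceComponents):
        return dict(components.estimates)
    return {str(k): float(v) for k, v in dict(components).items()}


@dataclass
class HeritabilityEntry:
    """Variance shares of one metric (fractions in [0, 1], summing to 1)."""

    shares: dict[str, float]
    total_variance: float
    genetic_h2: float

    def shares_percent(self, decimals: int = 1) -> dict[str, float]:
        """Display-rounded percentage shares."""
        return {k: round(100.0 * v, decimals) for k, v in self.shares.items()}

    def to_frame(self, components: Mapping[str, float] | None = None) -> pd.DataFrame:
        """Groups / Variance / Std.Dev / heritability-% report table."""
        comp = _as_mapping(components) if components is not None else {
            k: v * self.total_variance for k, v in self.shares.items()}
        rows = [(k, comp[k], np.sqrt(comp[k]), 100.0 * self.shares[k])
                for k in self.shares]
        return pd.DataFrame(rows, columns=["Groups", "Variance", "Std.Dev",
                                           "Heritability (%)"])


def factor_shares(components, genetic_terms: frozenset[str] = GENETIC_TERMS
                  ) -> HeritabilityEntry:
    """Per-term variance shares; denominator is the total including residual.

    Inputs must be non-negative (truncate first if an estimator went
    negative); computing from unrounded component values is the caller's
    responsibility when reproducing published rounded tables.
    """
    comp = _as_mapping(components)
    for name, v in comp.items():
        if v < 0:
            raise ValidationError(
                f"negative component {name!r}={v}; apply truncate_negative first")
    total = sum(comp.values())
    if total <= 0:
        raise UndefinedShareError("all variance components are zero")
    shares = {k: v / total for k, v in comp.items()}
    h2 = sum(s for k, s in shares.items() if k in genetic_terms)
    return HeritabilityEntry(shares=shares, total_variance=float(total),
                             genetic_h2=float(h2))


def genetic_heritability(components,
                         genetic_terms: frozenset[str] = GENETIC_TERMS) -> float:
    """h2 = sum of genetic-term variances over the total variance.

    Unlike :func:`factor_shares`, every requested genetic term must be
    present among the components.
    """
    comp = _as_mapping(components)
    unknown = set(genetic_terms) - set(comp)
    if unknown:
        raise ValidationError(
            f"genetic term(s) not among components: {sorted(unknown)}")
    total = sum(comp.values())
    if total <= 0:
        raise UndefinedShareError("all variance components are zero")
    return float(sum(comp[t] for t in genetic_terms) / total)


def heritability_ranking(per_metric: Mapping[str, float]) -> pd.DataFrame:
    """Metrics sorted by descending h2; ties broken lexicographically."""
    if not per_metric:
        raise ValidationError("no metrics to rank")
    df = pd.DataFrame({"metric": list(per_metric.keys()),
                       "genetic_h2": [float(v) for v in per_metric.values()]})
    df = df.sort_values(["genetic_h2", "metric"],
                        ascending=[False, True], kind="mergesort")
    df.insert(0, "rank", range(1, len(df) + 1))
    return df.reset_index(drop=True)


def bootstrap_share_ci(spec: GenerativeSpec, model: ModelSpec | None = None,
                       n_boot: int = 200, seed: int = 0,
                       genetic_terms: frozenset[str] = GENETIC_TERMS
                       ) -> pd.DataFrame:
    """Parametric-bootstrap percentile intervals for every variance share.

    Simulates ``n_boot`` datasets from ``spec`` (treated as the fitted
    model), refits each by EMS, and returns the 2.5/97.5 percentiles of each
    term's share plus of genetic h2.
    """
    if n_boot < 2:
        raise ValidationError("n_boot must be >= 2")
    if model is None:
        model = (ModelSpec.literal() if spec.coding == "literal"
                 else ModelSpec.nested())
    seeds = spawn_seeds(seed, n_boot)
    solver = None
    rows = []
    for s in seeds:
        table = simulate_observations(replace(spec, seed=s))
        sub = table.subset(spec.metric)
        if solver is None:
            solver = EMSSolver(sub[["variety", "section", "energy",
                                    "nanopaper", "strip"]], model)
        fit = solver.fit(sub["value"].to_numpy())
        entry = factor_shares(fit, genetic_terms)
        rows.append({**entry.shares, "genetic_h2": entry.genetic_h2})
    reps = pd.DataFrame(rows)
    lo, hi = np.percentile(reps.to_numpy(), [2.5, 97.5], axis=0)
    return pd.DataFrame({"term": reps.columns, "lower": lo, "upper": hi})


def heritability_table(fits: Mapping[str, VarianceComponents],
                       genetic_terms: frozenset[str] = GENETIC_TERMS
                       ) -> tuple[dict[str, HeritabilityEntry], pd.DataFrame]:
    """Shares per metric plus the descending h2 ranking, from fitted components."""
    entries = {m: factor_shares(f, genetic_terms) for m, f in fits.items()}
    ranking = heritability_ranking(
        {m: e.genetic_h2 for m, e in entries.items()})
    return entries, ranking
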