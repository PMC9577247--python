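"""Synthetic observation tables and metric matrices.

The generator reproduces the statistical structure the downstream analysis
assumes: a balanced hierarchical design whose response is a sum of
independent, zero-mean Gaussian random effects (one draw per factor level)
plus residual strip-to-strip noise, and multivariate-normal metric matrices
with a chosen covariance. Defaults mirror the sorghum-to-nanopaper study
design (4 varieties x 3 sections x 3 energies x 2 duplicates x 8 strips)
with tensile-index variance components as the generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import (DesignSpec, MetricMatrix, ObservationTable,
                        ValidationError)

#: Tensile-index variance components used as the default generating truth.
DEFAULT_COMPONENTS: dict[str, float] = {
    "Variety": 6.74,
    "Section:Variety": 57.40,
    "Energy": 110.59,
    "Nanopaper": 1.28,
    "Strip:Nanopaper": 0.01,
    "Residual": 137.34,
}

#: Default grand mean for a simulated nanopaper tensile index (N m/g).
DEFAULT_GRAND_MEAN = 60.0

_CODINGS = ("literal", "nested")
_COMPONENT_KEYS = {
    "literal": ("Variety", "Section:Variety", "Energy", "Nanopaper",
                "Strip:Nanopaper", "Residual"),
    "nested": ("Variety", "Section:Variety", "Energy", "Nanopaper", "Residual"),
}


@dataclass(frozen=True)
class GenerativeSpec:
    """True parameters for one simulated metric.

    ``coding`` controls how duplicate/strip effects are drawn:

    * ``"literal"`` — duplicate labels (1..n_duplicates) and strip labels are
      shared factor levels across all samples, so the nanopaper term has
      n_duplicates draws in total and the strip-within-duplicate term
      n_duplicates * n_strips draws.  This is the coding of the purely
      random-effects tensile-index model.
    * ``"nested"`` — one nanopaper draw per (variety, section, energy,
      duplicate); strip-level variation is the residual, so a separate
      ``Strip:Nanopaper`` component is not identifiable and is rejected.
    """

    design: DesignSpec
    grand_mean: float = DEFAULT_GRAND_MEAN
    components: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPONENTS))
    seed: int = 0
    metric: str = "tensile_index"
    coding: str = "literal"

    def __post_init__(self) -> None:
        if self.coding not in _CODINGS:
            raise ValidationError(f"coding must be one of {_CODINGS}")
        allowed = set(_COMPONENT_KEYS[self.coding])
        comps = dict(self.components)
        unknown = set(comps) - allowed
        if unknown:
            raise ValidationError(
                f"unknown component(s) for coding {self.coding!r}: "
                f"{sorted(unknown)} (allowed: {sorted(allowed)}; under nested "
                f"coding fold Strip:Nanopaper into Residual)")
        for name, var in comps.items():
            if not np.isfinite(var) or var < 0:
                raise ValidationError(
                    f"variance of {name!r} must be finite and >= 0, got {var}")
        full = {k: float(comps.get(k, 0.0)) for k in _COMPONENT_KEYS[self.coding]}
        object.__setattr__(self, "components", full)


def random_effects(variance: float, labels: Sequence[str],
                   rng: np.random.Generator) -> dict[str, float]:
    """One N(0, variance) draw per label."""
    if variance < 0:
        raise ValidationError("variance must be >= 0")
    draws = rng.normal(0.0, np.sqrt(variance), size=len(labels))
    return dict(zip(labels, draws))


def _factor_frame(design: DesignSpec) -> pd.DataFrame:
    dups = [str(i + 1) for i in range(design.n_duplicates)]
    strips = [str(i + 1) for i in range(design.n_strips)]
    rows = [
        (v, s, e, d, z)
        for (v, s, e) in design.cells
        for d in dups
        for z in strips
    ]
    return pd.DataFrame(rows, columns=["variety", "section", "energy",
                                       "nanopaper", "strip"])


def simulate_observations(spec: GenerativeSpec) -> ObservationTable:
    """Draw one balanced observation table from the additive random model.

    value = grand mean + variety + section(variety) + energy + nanopaper
    + strip (literal coding only) + residual, each effect an independent
    zero-mean Gaussian with its stated variance. Identical specs (including
    the seed) yield identical tables.
    """
    design = spec.design
    comps = spec.components
    rng = np.random.default_rng(spec.seed)
    frame = _factor_frame(design)

    v_eff = random_effects(comps["Variety"], design.varieties, rng)
    sec_labels = [f"{v}\x1f{s}" for v in design.varieties
                  for s in design.sections_by_variety[v]]
    s_eff = random_effects(comps["Section:Variety"], sec_labels, rng)
    e_eff = random_effects(comps["Energy"], design.energy_levels, rng)

    dups = [str(i + 1) for i in range(design.n_duplicates)]
    strips = [str(i + 1) for i in range(design.n_strips)]
    if spec.coding == "literal":
        n_eff = random_effects(comps["Nanopaper"], dups, rng)
        z_eff = random_effects(comps["Strip:Nanopaper"],
                               [f"{d}\x1f{z}" for d in dups for z in strips], rng)
        nano = frame["nanopaper"].map(n_eff)
        strip = (frame["nanopaper"] + "\x1f" + frame["strip"]).map(z_eff)
    else:
        nano_labels = [f"{v}\x1f{s}\x1f{e}\x1f{d}"
                       for (v, s, e) in design.cells for d in dups]
        n_eff = random_effects(comps["Nanopaper"], nano_labels, rng)
        nano = (frame["variety"] + "\x1f" + frame["section"] + "\x1f"
                + frame["energy"] + "\x1f" + frame["nanopaper"]).map(n_eff)
        strip = 0.0

    resid = rng.normal(0.0, np.sqrt(comps["Residual"]), size=len(frame))
    value = (spec.grand_mean
             + frame["variety"].map(v_eff).to_numpy()
             + (frame["variety"] + "\x1f" + frame["section"]).map(s_eff).to_numpy()
             + frame["energy"].map(e_eff).to_numpy()
             + np.asarray(nano, dtype=float)
             + np.asarray(strip, dtype=float)
             + resid)
    out = frame.copy()
    out["metric"] = spec.metric
    out["value"] = value
    return ObservationTable(out)


def simulate_observations_multi(specs: Sequence[GenerativeSpec]) -> ObservationTable:
    """Concatenate independent single-metric simulations into one table."""
    if not specs:
        raise ValidationError("no generative specs given")
    names = [s.metric for s in specs]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate metric names across specs")
    frames = [simulate_observations(s).data for s in specs]
    return ObservationTable(pd.concat(frames, ignore_index=True))


@dataclass(frozen=True)
class MetricCovSpec:
    """Multivariate-normal spec for a samples x metrics matrix."""

    metric_names: tuple[str, ...]
    means: tuple[float, ...]
    covariance: np.ndarray
    n_samples: int
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "metric_names", tuple(self.metric_names))
        object.__setattr__(self, "means", tuple(float(m) for m in self.means))
        cov = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "covariance", cov)
        p = len(self.metric_names)
        if len(self.means) != p or cov.shape != (p, p):
            raise ValidationError(
                f"inconsistent dimensions: {p} metrics, means {len(self.means)}, "
                f"covariance {cov.shape}")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValidationError("covariance not symmetric within 1e-10")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")


def simulate_metric_matrix(spec: MetricCovSpec) -> MetricMatrix:
    """Draw rows from the stated multivariate normal; reproducible per seed."""
    eigvals = np.linalg.eigvalsh(spec.covariance)
    if eigvals.min() < -1e-8:
        raise ValidationError(
            f"covariance is not positive semidefinite: smallest eigenvalue "
            f"{eigvals.min():.3e}")
    rng = np.random.default_rng(spec.seed)
    draws = rng.multivariate_normal(spec.means, spec.covariance,
                                    size=spec.n_samples, method="svd")
    width = len(str(spec.n_samples))
    ids = [f"s{i + 1:0{width}d}" for i in range(spec.n_samples)]
    return MetricMatrix(pd.DataFrame(draws, index=ids,
                                     columns=list(spec.metric_names)))


def planted_block_metrics(n_samples: int, blocks: Sequence[Sequence[str]],
                          within_r: float, seed: int = 0) -> MetricMatrix:
    """Metric matrix with a planted block-correlation structure.

    Metrics inside a block are pairwise correlated ``within_r``; metrics in
    different blocks are independent. Used as a known-truth fixture for
    cluster-recovery checks.
    """
    if not 0.0 <= within_r < 1.0:
        raise ValidationError("within_r must be in [0, 1)")
    names: list[str] = []
    for block in blocks:
        for m in block:
            if m in names:
                raise ValidationError(f"blocks overlap at metric {m!r}")
            names.append(m)
    if not names:
        raise ValidationError("blocks must name at least one metric")
    p = len(names)
    cov = np.zeros((p, p))
    start = 0
    for block in blocks:
        b = len(block)
        cov[start:start + b, start:start + b] = within_r
        start += b
    np.fill_diagonal(cov, 1.0)
    return simulate_metric_matrix(MetricCovSpec(
        metric_names=tuple(names), means=(0.0,) * p, covariance=cov,
        n_samples=n_samples, seed=seed))


#: Qualitative metric families used by the default demo fixtures: fine-content
#: parameters, fibre-length parameters, and coarseness/content parameters.
MORPHOLOGY_BLOCKS: tuple[tuple[str, ...], ...] = (
    ("fine_cont", "fine_n", "fine_cont.A", "fine_cont.L", "fine_cont.L.L"),
    ("fibre_L", "fibre_L.L", "fibre_A.L"),
    ("fibre_coarse", "fibre_cont"),
)


def default_morphology_components() -> dict[str, dict[str, float]]:
    """Illustrative generating components for ten fibre-morphology metrics.

    Total variance is 100 for every metric; the biomass ("genetic") share
    spans 5%..55% so heritability rankings on simulated data are non-trivial.
    The genetic share is split 1:2 between Variety and Section:Variety, the
    remainder mostly between homogenisation energy and residual noise.
    """
    h2 = {
        "fibre_L": 0.55, "fibre_coarse": 0.45, "fibre_cont": 0.35,
        "fine_cont": 0.30, "fine_n": 0.25, "fibre_L.L": 0.20,
        "fibre_A.L": 0.15, "fine_cont.A": 0.10, "fine_cont.L": 0.08,
        "fine_cont.L.L": 0.05,
    }
    out = {}
    for metric, h in h2.items():
        rest = 1.0 - h
        out[metric] = {
            "Variety": round(100 * h / 3, 4),
            "Section:Variety": round(100 * 2 * h / 3, 4),
            "Energy": round(100 * rest * 0.40, 4),
            "Nanopaper": round(100 * rest * 0.05, 4),
            "Strip:Nanopaper": round(100 * rest * 0.01, 4),
            "Residual": round(100 * rest * 0.54, 4),
        }
    return out


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from one base seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]
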