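"""Quality scores, selection gradients, G matrix and predicted response.

The multivariate breeder's (Lande) equation, delta z = G beta, predicts the
shift in mean trait values given the trait variance-covariance matrix G and
the selection gradients beta.  Re-purposed for materials: "traits" are
characterisation metrics of a sample population, "fitness" is a tunable
material quality score, and beta_n is the OLS slope of fitness on metric n.
Comparing beta across quality definitions shows which metrics drive quality
robustly and which only matter for a particular application.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import MetricMatrix, ValidationError


@dataclass(frozen=True)
class Constituent:
    metric: str
    weight: float
    direction: int  # +1 higher-is-better, -1 lower-is-better


@dataclass(frozen=True)
class QualityDefinition:
    """Named, weighted, direction-signed combination of metrics.

    Weights must be non-negative and are normalised to sum to one; each
    constituent is min-max rescaled to [0, 1] (reversed when direction is
    -1) before the weighted mean, so scores are bounded in [0, 1] and
    invariant to positive affine rescaling of any constituent metric.
    """

    name: str
    constituents: tuple[Constituent, ...]

    def __post_init__(self) -> None:
        cons = tuple(c if isinstance(c, Constituent) else Constituent(*c)
                     for c in self.constituents)
        if not cons:
            raise ValidationError(f"{self.name}: no constituents")
        metrics = [c.metric for c in cons]
        if len(set(metrics)) != len(metrics):
            raise ValidationError(f"{self.name}: duplicate constituent metrics")
        for c in cons:
            if c.direction not in (-1, 1):
                raise ValidationError(
                    f"{self.name}: direction of {c.metric!r} must be +1 or -1")
            if c.weight < 0:
                raise ValidationError(
                    f"{self.name}: weight of {c.metric!r} must be >= 0")
        total = sum(c.weight for c in cons)
        if total <= 0:
            raise ValidationError(f"{self.name}: weights sum to zero")
        cons = tuple(Constituent(c.metric, c.weight / total, c.direction)
                     for c in cons)
        object.__setattr__(self, "constituents", cons)

    @property
    def metric_names(self) -> list[str]:
        return [c.metric for c in self.constituents]


#: Default definitions: Q1 = nanopaper tensile index alone; Q5 = nanofibre-
#: water interaction (sedimentation aspect ratio + water retention value),
#: equally weighted.
DEFAULT_DEFINITIONS: tuple[QualityDefinition, ...] = (
    QualityDefinition("Q1", (Constituent("tensile_index", 1.0, +1),)),
    QualityDefinition("Q5", (Constituent("sed_aspect_ratio", 0.5, +1),
                             Constituent("wrv", 0.5, +1))),
)


def quality_score(matrix: MetricMatrix, definition: QualityDefinition) -> pd.Series:
    """Per-sample quality in [0, 1]: weighted mean of min-max rescaled,
    direction-signed constituents."""
    df = matrix.data
    if len(df) < 2:
        raise ValidationError("need at least 2 samples to score quality")
    missing = [c.metric for c in definition.constituents
               if c.metric not in df.columns]
    if missing:
        raise ValidationError(
            f"{definition.name}: constituent metric(s) missing: {missing}")
    score = pd.Series(0.0, index=df.index)
    for c in definition.constituents:
        col = df[c.metric]
        if not np.isfinite(col.to_numpy()).all():
            raise ValidationError(
                f"{definition.name}: metric {c.metric!r} has missing values")
        lo, hi = float(col.min()), float(col.max())
        if hi == lo:
            raise ValidationError(
                f"{definition.name}: metric {c.metric!r} is constant; "
                f"min-max rescaling undefined")
        scaled = (col - lo) / (hi - lo)
        if c.direction == -1:
            scaled = 1.0 - scaled
        score = score + c.weight * scaled
    score.name = definition.name
    return score


def selection_gradient(trait, fitness, standardize_trait: bool = True) -> float:
    """OLS slope of fitness on the (optionally z-standardised) trait.

    With standardisation the gradient is in fitness units per trait standard
    deviation, so gradients of incommensurable metrics share one axis.
    """
    x = np.asarray(trait, dtype=float)
    f = np.asarray(fitness, dtype=float)
    if x.shape != f.shape or x.ndim != 1:
        raise ValidationError("trait and fitness must be 1-d and equally long")
    n = len(x)
    if n < 3:
        raise ValidationError("need at least 3 observations for a gradient")
    sx = float(np.std(x, ddof=1))
    if sx == 0:
        raise ValidationError("trait has zero spread")
    if standardize_trait:
        x = (x - x.mean()) / sx
    vx = float(np.var(x, ddof=1))
    return float(np.cov(x, f, ddof=1)[0, 1] / vx)


@dataclass
class SelectionGradients:
    """Gradients per (metric, quality definition), with fit diagnostics."""

    beta: pd.DataFrame   # index: metrics, columns: definition names
    r2: pd.DataFrame
    n: int


def selection_gradients(matrix: MetricMatrix,
                        definitions: Sequence[QualityDefinition],
                        standardize_trait: bool = True,
                        relative_fitness: bool = False) -> SelectionGradients:
    """Fit one gradient per metric per quality definition.

    ``relative_fitness`` divides each score by its mean (classical
    relative-fitness convention) before regression.
    """
    if not definitions:
        raise ValidationError("no quality definitions given")
    df = matrix.data
    betas, r2s = {}, {}
    for qd in definitions:
        f = quality_score(matrix, qd)
        if relative_fitness:
            if f.mean() == 0:
                raise ValidationError(f"{qd.name}: mean fitness is zero")
            f = f / f.mean()
        b_col, r_col = {}, {}
        for metric in df.columns:
            b = selection_gradient(df[metric].to_numpy(), f.to_numpy(),
                                   standardize_trait=standardize_trait)
            b_col[metric] = b
            r = np.corrcoef(df[metric].to_numpy(), f.to_numpy())[0, 1]
            r_col[metric] = float(r**2) if np.isfinite(r) else np.nan
        betas[qd.name] = b_col
        r2s[qd.name] = r_col
    beta = pd.DataFrame(betas).loc[list(df.columns)]
    r2 = pd.DataFrame(r2s).loc[list(df.columns)]
    return SelectionGradients(beta=beta, r2=r2, n=len(df))


@dataclass
class GMatrix:
    """Trait variance-covariance (or correlation) matrix."""

    labels: tuple[str, ...]
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        vals = self.values.to_numpy()
        if vals.shape != (len(self.labels),) * 2:
            raise ValidationError("G shape does not match labels")
        if not np.allclose(vals, vals.T, atol=1e-10):
            raise ValidationError("G not symmetric")
        if np.linalg.eigvalsh(vals).min() < -1e-8:
            raise ValidationError("G not positive semidefinite within 1e-8")


def g_matrix(matrix: MetricMatrix, standardized: bool = True) -> GMatrix:
    """Sample covariance (ddof=1) of the metrics; the correlation matrix when
    ``standardized`` (the default, matching standardised gradients)."""
    df = matrix.data
    if len(df) < 2:
        raise ValidationError("need at least 2 samples for G")
    X = df.to_numpy()
    if not np.isfinite(X).all():
        raise ValidationError("missing/non-finite entries in metric matrix")
    if standardized:
        sd = X.std(axis=0, ddof=1)
        bad = [df.columns[i] for i in np.flatnonzero(sd == 0)]
        if bad:
            raise ValidationError(f"zero-spread metric(s): {bad}")
        G = np.corrcoef(X, rowvar=False)
        G = (G + G.T) / 2.0
    else:
        G = np.cov(X, rowvar=False, ddof=1)
    labels = tuple(str(c) for c in df.columns)
    return GMatrix(labels, pd.DataFrame(G, index=labels, columns=labels))


def predicted_response(G: GMatrix, beta) -> pd.Series:
    """delta z = G beta, aligning by metric label and erroring on mismatch."""
    b = pd.Series(beta, dtype=float)
    g_set, b_set = set(G.labels), set(b.index.astype(str))
    if g_set != b_set:
        raise ValidationError(
            "metric labels of G and beta differ; only in G: "
            f"{sorted(g_set - b_set)}, only in beta: {sorted(b_set - g_set)}")
    b = b.loc[list(G.labels)]
    dz = G.values.to_numpy() @ b.to_numpy()
    return pd.Series(dz, index=list(G.labels), name="delta_z")


def cross_quality_table(gradients: SelectionGradients) -> pd.DataFrame:
    """Per-metric comparison of gradients across quality definitions.

    Columns: one per definition, plus the mean and the range (max - min);
    rows ordered by ascending mean (ties broken by metric name).
    """
    beta = gradients.beta
    if beta.shape[1] < 2:
        raise ValidationError("need gradients for at least 2 quality definitions")
    if beta.isna().any().any():
        raise ValidationError("gradient table contains missing values")
    out = beta.copy()
    out["mean"] = beta.mean(axis=1)
    out["range"] = beta.max(axis=1) - beta.min(axis=1)
    out.index.name = "metric"
    out = out.assign(_m=out.index).sort_values(["mean", "_m"],
                                               kind="mergesort").drop(columns="_m")
    return out
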