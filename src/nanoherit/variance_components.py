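"""Variance-component estimation for the biomass-to-nanopaper random model.

Two estimators for the same Gaussian random-intercept model

    y = mu + sum_i Z_i u_i + e,   u_i ~ N(0, sigma_i^2 I),  e ~ N(0, sigma_e^2 I):

* ``ems_components`` — method of moments on sequential ANOVA strata.  For a
  balanced design each stratum's observed mean square is equated to its
  expectation, which is linear in the variance components; the resulting
  square system is solved exactly.  Requires balance.
* ``reml_components`` — EM iteration on the restricted likelihood.  Works on
  unbalanced data, keeps every component non-negative, and ascends the
  restricted log-likelihood monotonically.

Term coding
-----------
``ModelSpec.nested()`` (default) treats nanopaper duplicates as nested within
(variety, section, energy) samples; strip-to-strip variation is the residual
stratum, because with one measurement per strip a separate strip term is
confounded with the residual.  ``ModelSpec.literal()`` reproduces the coding
in which duplicate labels (1..2) and strip labels (1..8) are factor levels
shared across samples, giving the six-component decomposition of the
tensile-index analysis (variety, section:variety, energy, nanopaper,
strip:nanopaper, residual).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, orth

from .core_data import FACTORS, ObservationTable, ValidationError

RESIDUAL = "Residual"


class BalanceError(ValidationError):
    """Raised when the EMS estimator meets unbalanced data."""


@dataclass(frozen=True)
class Term:
    """One random term, defined by the factor columns whose combination
    indexes its levels (e.g. ("variety", "section") for section-within-variety)."""

    name: str
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "columns", tuple(self.columns))
        if not self.columns:
            raise ValidationError(f"term {self.name!r} has no factor columns")
        unknown = set(self.columns) - set(FACTORS)
        if unknown:
            raise ValidationError(
                f"term {self.name!r} references unknown factor(s): {sorted(unknown)}")
        if self.name == RESIDUAL:
            raise ValidationError(f"{RESIDUAL!r} is reserved for the error term")


@dataclass(frozen=True)
class ModelSpec:
    """Ordered random terms; the residual is implied."""

    terms: tuple[Term, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate term names: {names}")
        if not self.terms:
            raise ValidationError("model needs at least one random term")

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    @classmethod
    def nested(cls) -> "ModelSpec":
        return cls((
            Term("Variety", ("variety",)),
            Term("Section:Variety", ("variety", "section")),
            Term("Energy", ("energy",)),
            Term("Nanopaper", ("variety", "section", "energy", "nanopaper")),
        ))

    @classmethod
    def literal(cls) -> "ModelSpec":
        return cls((
            Term("Variety", ("variety",)),
            Term("Section:Variety", ("variety", "section")),
            Term("Energy", ("energy",)),
            Term("Nanopaper", ("nanopaper",)),
            Term("Strip:Nanopaper", ("nanopaper", "strip")),
        ))

    @classmethod
    def oneway(cls, column: str = "variety", name: str = "Group") -> "ModelSpec":
        return cls((Term(name, (column,)),))


@dataclass
class VarianceComponents:
    """Named non-negative variance estimates plus residual.

    ``raw`` keeps pre-truncation values (EMS solutions may be negative);
    ``truncated`` lists terms clipped to zero.  ``loglik_trace`` records the
    restricted log-likelihood per REML iteration.
    """

    estimates: dict[str, float]
    method: str
    raw: dict[str, float] = field(default_factory=dict)
    truncated: tuple[str, ...] = ()
    converged: bool = True
    n_iterations: int = 0
    loglik_trace: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if RESIDUAL not in self.estimates:
            raise ValidationError("estimates must include the residual")
        for name, v in self.estimates.items():
            if not np.isfinite(v) or v < 0:
                raise ValidationError(
                    f"estimate of {name!r} must be finite and >= 0, got {v}")
        if not self.raw:
            self.raw = dict(self.estimates)

    @property
    def std_dev(self) -> dict[str, float]:
        return {k: float(np.sqrt(v)) for k, v in self.estimates.items()}

    @property
    def total(self) -> float:
        return float(sum(self.estimates.values()))

    def to_frame(self) -> pd.DataFrame:
        """Report in Groups / Variance / Std.Dev layout."""
        rows = [(k, v, np.sqrt(v)) for k, v in self.estimates.items()]
        return pd.DataFrame(rows, columns=["Groups", "Variance", "Std.Dev"])


def truncate_negative(components) -> VarianceComponents:
    """Clip negative entries to zero, keeping a record of which were clipped.

    Accepts a ``VarianceComponents`` or a plain term -> value mapping.
    """
    if isinstance(components, VarianceComponents):
        raw = dict(components.raw)
        method = components.method
        meta = dict(converged=components.converged,
                    n_iterations=components.n_iterations,
                    loglik_trace=components.loglik_trace)
    else:
        raw = {k: float(v) for k, v in dict(components).items()}
        method = "input"
        meta = {}
    clipped = {k: max(v, 0.0) for k, v in raw.items()}
    flagged = tuple(k for k, v in raw.items() if v < 0)
    return VarianceComponents(estimates=clipped, method=method, raw=raw,
                              truncated=flagged, **meta)


# ---------------------------------------------------------------------------
# design matrices and balance
# ---------------------------------------------------------------------------

def term_design_matrix(factors: pd.DataFrame, term: Term) -> np.ndarray:
    """0/1 incidence matrix of the term's level combinations (sorted levels)."""
    key = factors[list(term.columns)].astype(str).agg("\x1f".join, axis=1)
    codes, _ = pd.factorize(key, sort=True)
    Z = np.zeros((len(key), int(codes.max()) + 1))
    Z[np.arange(len(key)), codes] = 1.0
    return Z


def _is_balanced(factors: pd.DataFrame) -> bool:
    """Balance w.r.t. the full design hierarchy: complete energy crossing,
    equal strip counts per duplicate and equal duplicate counts per cell."""
    if factors.empty:
        return False
    n_energy = factors["energy"].nunique()
    per_vs = factors.groupby(["variety", "section"])["energy"].nunique()
    if (per_vs != n_energy).any():
        return False
    cell = factors.groupby(["variety", "section", "energy"])
    if cell.size().nunique() != 1:
        return False
    if cell["nanopaper"].nunique().nunique() != 1:
        return False
    dup = factors.groupby(["variety", "section", "energy", "nanopaper"]).size()
    return dup.nunique() == 1


class EMSSolver:
    """Sequential-ANOVA method-of-moments solver, reusable across responses.

    Strata are built in model-term order (outermost first, residual last);
    ties in stratum ordering are therefore broken by the order terms appear
    in the ``ModelSpec``.  Building the solver once and calling :meth:`fit`
    on many response vectors makes large Monte-Carlo recovery studies cheap.
    """

    def __init__(self, factors: pd.DataFrame, model: ModelSpec):
        factors = factors.reset_index(drop=True)
        n = len(factors)
        if n < 2:
            raise ValidationError("need at least 2 observations")
        self.model = model
        self.n = n
        Zs = [term_design_matrix(factors, t) for t in model.terms]
        bases: list[np.ndarray] = []
        current = np.full((n, 1), 1.0 / np.sqrt(n))
        for t, Z in zip(model.terms, Zs):
            resid = Z - current @ (current.T @ Z)
            B = orth(resid)
            if B.shape[1] == 0:
                raise ValidationError(
                    f"term {t.name!r} is aliased with earlier terms")
            bases.append(B)
            current = np.hstack([current, B])
        df_res = n - current.shape[1]
        if df_res <= 0:
            raise ValidationError(
                "no residual degrees of freedom: model saturates the data")
        k = len(Zs)
        # A[t, i] = tr(Z_i' Q_t Z_i); last row/column = residual stratum / sigma_e^2
        A = np.zeros((k + 1, k + 1))
        for trow, B in enumerate(bases):
            for i, Z in enumerate(Zs):
                A[trow, i] = np.sum((B.T @ Z) ** 2)
            A[trow, k] = B.shape[1]
        for i, Z in enumerate(Zs):
            A[k, i] = np.sum(Z**2) - np.sum((current.T @ Z) ** 2)
        A[k, k] = df_res
        self._A = A
        self._bases = bases
        self._span = current
        self.df_residual = df_res

    def sums_of_squares(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        b = np.array([np.sum((B.T @ y) ** 2) for B in self._bases]
                     + [float(y @ y - np.sum((self._span.T @ y) ** 2))])
        return b

    def fit(self, y: np.ndarray) -> VarianceComponents:
        sol = np.linalg.solve(self._A, self.sums_of_squares(y))
        names = self.model.term_names + [RESIDUAL]
        raw = {name: float(v) for name, v in zip(names, sol)}
        out = truncate_negative(raw)
        out.method = "EMS"
        return out


def ems_components(table: ObservationTable, model: ModelSpec | None = None,
                   metric: str | None = None) -> VarianceComponents:
    """Expected-mean-squares estimates for one metric of a balanced table.

    Negative stratum solutions are truncated to zero and flagged; the raw
    solutions stay available in ``.raw``.  Unbalanced data (including
    imbalance induced by missing values) raises :class:`BalanceError`.
    """
    model = model or ModelSpec.nested()
    metric = _resolve_metric(table, metric)
    sub = table.subset(metric).dropna(subset=["value"])
    factors = sub[list(FACTORS)]
    if not _is_balanced(factors):
        raise BalanceError(
            f"data for metric {metric!r} is unbalanced; EMS requires a complete "
            f"balanced design — use reml_components instead")
    return EMSSolver(factors, model).fit(sub["value"].to_numpy())


def _resolve_metric(table: ObservationTable, metric: str | None) -> str:
    if metric is not None:
        return metric
    metrics = table.metrics
    if len(metrics) != 1:
        raise ValidationError(
            f"metric must be named when the table holds several: {metrics}")
    return metrics[0]


# ---------------------------------------------------------------------------
# EM-REML
# ---------------------------------------------------------------------------

def reml_components(table: ObservationTable, model: ModelSpec | None = None,
                    metric: str | None = None, tol: float = 1e-8,
                    max_iter: int = 500) -> VarianceComponents:
    """EM-REML estimates for one metric; valid for unbalanced data.

    Starts every component at var(y)/(k+1) and applies the standard EM
    updates, which keep components non-negative and never decrease the
    restricted log-likelihood.  Stops when the largest absolute component
    change falls below ``tol`` (``converged`` records whether that happened
    within ``max_iter``).  The restricted log-likelihood per iteration is
    kept in ``loglik_trace``.
    """
    model = model or ModelSpec.nested()
    metric = _resolve_metric(table, metric)
    sub = table.subset(metric).dropna(subset=["value"])
    y = sub["value"].to_numpy()
    n = len(y)
    if n < 2:
        raise ValidationError("need at least 2 observations for REML")
    factors = sub[list(FACTORS)].reset_index(drop=True)
    Zs = [term_design_matrix(factors, t) for t in model.terms]
    for t, Z in zip(model.terms, Zs):
        if Z.shape[1] >= n:
            raise ValidationError(
                f"term {t.name!r} has one level per observation and is "
                f"confounded with the residual")
    names = model.term_names + [RESIDUAL]
    k = len(Zs)

    sy2 = float(np.var(y, ddof=1))
    if sy2 <= 1e-300:
        est = {name: 0.0 for name in names}
        return VarianceComponents(estimates=est, method="REML", converged=True)

    s = np.full(k + 1, sy2 / (k + 1))
    qs = [Z.shape[1] for Z in Zs]
    I = np.eye(n)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        V = s[-1] * I
        for sig, Z in zip(s[:-1], Zs):
            if sig > 0:
                V += sig * (Z @ Z.T)
        c, low = cho_factor(V, lower=True)
        Vinv = cho_solve((c, low), I)
        logdetV = 2.0 * float(np.sum(np.log(np.diag(c))))
        vx = Vinv.sum(axis=1)           # V^{-1} 1, since X = 1
        xvx = float(vx.sum())           # 1' V^{-1} 1
        P = Vinv - np.outer(vx, vx) / xvx
        Py = P @ y
        ll = -0.5 * (logdetV + np.log(xvx) + float(y @ Py))
        trace.append(ll)

        new = np.empty_like(s)
        for i, (Z, q) in enumerate(zip(Zs, qs)):
            if s[i] == 0.0:
                new[i] = 0.0
                continue
            w = Z.T @ Py
            tr = float(np.einsum("ij,ji->", Z.T, P @ Z))
            new[i] = max(s[i] + s[i] ** 2 * (float(w @ w) - tr) / q, 0.0)
        new[-1] = max(s[-1] + s[-1] ** 2 * (float(Py @ Py) - float(np.trace(P))) / n,
                      0.0)
        delta = float(np.max(np.abs(new - s)))
        s = new
        if delta < tol:
            converged = True
            break

    est = {name: float(v) for name, v in zip(names, s)}
    return VarianceComponents(estimates=est, method="REML", raw=dict(est),
                              truncated=(), converged=converged,
                              n_iterations=it, loglik_trace=tuple(trace))


def restricted_loglik(components: Mapping[str, float], factors: pd.DataFrame,
                      y: np.ndarray, model: ModelSpec) -> float:
    """Restricted log-likelihood (up to constants) at given component values."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    Zs = [term_design_matrix(factors.reset_index(drop=True), t)
          for t in model.terms]
    V = components[RESIDUAL] * np.eye(n)
    for t, Z in zip(model.terms, Zs):
        V += components[t.name] * (Z @ Z.T)
    c, low = cho_factor(V, lower=True)
    Vinv = cho_solve((c, low), np.eye(n))
    vx = Vinv.sum(axis=1)
    xvx = float(vx.sum())
    P = Vinv - np.outer(vx, vx) / xvx
    return -0.5 * (2.0 * float(np.sum(np.log(np.diag(c)))) + np.log(xvx)
                   + float(y @ (P @ y)))
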