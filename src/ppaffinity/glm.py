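"""Gaussian GLM with logarithmic link for affinity prediction.

The scoring model is E[pKd] = exp(eta), eta = b0 + sum_i b_i x_i (plus
optional pairwise interaction products), with additive Gaussian error on
the response scale.  Fitting is iteratively reweighted least squares
(IRLS); the Gaussian log-likelihood is evaluated at the MLE with the
dispersion sigma^2 = RSS/n profiled out, and AIC = 2k - 2*lnL counts the
dispersion as an estimated parameter (k = #coefficients + 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "FittedModel",
    "RankDeficientError",
    "design_matrix",
    "fit_glm",
    "predict",
    "aic",
    "gaussian_loglik",
]


class RankDeficientError(ValueError):
    """The design matrix has linearly dependent (aliased) columns."""

    def __init__(self, aliased: list[str]):
        self.aliased = aliased
        super().__init__(f"rank-deficient design; aliased columns: {aliased}")


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: main-effect terms plus pairwise interactions.

    With ``marginality`` on, every interaction's two parent features must
    appear among the main terms (the hierarchy constraint used during
    model selection).
    """

    main_terms: frozenset[str]
    interaction_terms: frozenset[frozenset[str]] = frozenset()
    marginality: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "main_terms", frozenset(self.main_terms))
        object.__setattr__(
            self, "interaction_terms", frozenset(frozenset(p) for p in self.interaction_terms)
        )
        for pair in self.interaction_terms:
            if len(pair) != 2:
                raise ValueError(f"interaction term must pair two distinct features: {set(pair)}")
            if self.marginality and not pair <= self.main_terms:
                raise ValueError(f"marginality violated: {set(pair)} not within main terms")

    @property
    def n_terms(self) -> int:
        return len(self.main_terms) + len(self.interaction_terms)

    def term_names(self) -> list[str]:
        mains = sorted(self.main_terms)
        inters = sorted(":".join(sorted(p)) for p in self.interaction_terms)
        return mains + inters

    def __str__(self) -> str:
        return " + ".join(["1"] + self.term_names())


@dataclass
class FittedModel:
    spec: ModelSpec
    coefficients: dict[str, float]  # keyed by "(intercept)", mains, "a:b"
    log_likelihood: float
    aic: float
    n_obs: int
    converged: bool
    sigma2: float
    n_iter: int
    flagged_rows: list[int] = field(default_factory=list)

    @property
    def k(self) -> int:
        """Estimated parameter count: coefficients plus the dispersion."""
        return len(self.coefficients) + 1


def aic(log_likelihood: float, k: int) -> float:
    """Akaike information criterion, 2k - 2*lnL."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 2.0 * k - 2.0 * log_likelihood


def gaussian_loglik(y: np.ndarray, mu: np.ndarray) -> tuple[float, float]:
    """Profile Gaussian log-likelihood and the MLE dispersion RSS/n."""
    y = np.asarray(y, dtype=float)
    n = y.size
    sigma2 = float(((y - mu) ** 2).sum() / n)
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    return float(-0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)), sigma2


def design_matrix(X: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Intercept + main-effect columns + interaction products, named."""
    missing = sorted(set(spec.main_terms) - set(X.columns))
    for pair in spec.interaction_terms:
        missing += sorted(set(pair) - set(X.columns))
    if missing:
        raise KeyError(f"features absent from table: {sorted(set(missing))}")
    names = ["(intercept)"]
    cols = [np.ones(len(X))]
    for name in sorted(spec.main_terms):
        names.append(name)
        cols.append(X[name].to_numpy(dtype=float))
    for pair in sorted(spec.interaction_terms, key=lambda p: ":".join(sorted(p))):
        a, b = sorted(pair)
        names.append(f"{a}:{b}")
        cols.append(X[a].to_numpy(dtype=float) * X[b].to_numpy(dtype=float))
    return np.column_stack(cols), names


def _check_rank(M: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        # identify an aliased subset by greedy QR-style elimination
        aliased = []
        kept: list[int] = []
        for j in range(M.shape[1]):
            trial = M[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                aliased.append(names[j])
        raise RankDeficientError(aliased)


def fit_glm(
    X: pd.DataFrame,
    y,
    spec: ModelSpec,
    max_iter: int = 100,
    tol: float = 1e-10,
    nonpositive: str = "raise",
) -> FittedModel:
    """Maximum-likelihood fit of the log-link Gaussian GLM.

    IRLS with working weights mu^2 and working response eta + (y-mu)/mu;
    started at b0 = ln(mean y), all other coefficients 0; converged when
    the relative deviance (RSS) change falls below ``tol``.

    ``nonpositive`` controls rows with y <= 0 (the log link constrains the
    fitted mean, not the response): "raise" (default) errors naming the
    rows, "flag" fits anyway and records them in ``flagged_rows``.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) != len(X):
        raise ValueError("y must be a vector aligned with X rows")
    bad = np.flatnonzero(y <= 0).tolist()
    if bad and nonpositive == "raise":
        raise ValueError(f"response must be positive for the log link; rows {bad}")
    M, names = design_matrix(X, spec)
    n, p = M.shape
    if n <= p:
        raise ValueError(f"need n_obs > n_params ({n} <= {p})")
    _check_rank(M, names)

    mean_y = float(np.mean(y))
    if mean_y <= 0:
        mean_y = max(float(np.mean(np.abs(y))), 1e-6)
    beta = np.zeros(p)
    beta[0] = math.log(mean_y)

    eta = M @ beta
    mu = np.exp(eta)
    deviance = float(((y - mu) ** 2).sum())
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu * mu  # (dmu/deta)^2 for the log link, Gaussian variance const
        z = eta + (y - mu) / mu
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(M * sw[:, None], z * sw, rcond=None)
        eta_new = M @ beta_new
        # step-halving keeps exp(eta) finite on aggressive steps
        step = 1.0
        while not np.all(np.isfinite(np.exp(eta_new))) and step > 1e-8:
            step /= 2.0
            beta_new = beta + step * (beta_new - beta)
            eta_new = M @ beta_new
        beta, eta = beta_new, eta_new
        mu = np.exp(eta)
        new_dev = float(((y - mu) ** 2).sum())
        if abs(new_dev - deviance) <= tol * (abs(deviance) + tol):
            deviance = new_dev
            converged = True
            break
        deviance = new_dev
    llf, sigma2 = gaussian_loglik(y, mu)
    coefs = dict(zip(names, beta.tolist()))
    k = p + 1  # coefficients + dispersion
    return FittedModel(
        spec=spec,
        coefficients=coefs,
        log_likelihood=llf,
        aic=aic(llf, k),
        n_obs=n,
        converged=converged,
        sigma2=sigma2,
        n_iter=it,
        flagged_rows=bad,
    )


def predict(model: FittedModel, X: pd.DataFrame) -> np.ndarray:
    """Predicted pKd, exp(X beta); strictly positive."""
    M, names = design_matrix(X, model.spec)
    beta = np.array([model.coefficients[name] for name in names])
    return np.exp(M @ beta)
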