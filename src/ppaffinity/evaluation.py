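"""Cross-validation, accuracy metrics and correlation-comparison statistics.

Model accuracy is assessed by repeated leave-one-out cross-validation:
each replicate holds out a single complex (sampled without replacement
until the dataset is exhausted, then reshuffled), refits the modelling
procedure on the rest, and predicts the held-out pKd.  Because a single
held-out point has no correlation, r^2 and RMSD are computed on the pooled
held-out predictions; per-replicate records are kept for standard errors.

Accuracies are compared with Welch's t, the Mann-Whitney U, Fisher's
z-transformation for two independent correlations, and Williams' t for
two dependent correlations sharing the observed-affinity variable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .glm import ModelSpec, fit_glm, predict

__all__ = [
    "EvaluationResult",
    "ComparisonResult",
    "glm_procedure",
    "loo_cv",
    "pearson_r2",
    "rmsd_metric",
    "fisher_compare",
    "williams_test",
    "welch_t",
    "mann_whitney_u",
    "subsample_control",
    "estimate_assay_offsets",
]

# (train_X, train_y) -> predictor(test_X) -> predictions
Procedure = Callable[[pd.DataFrame, np.ndarray], Callable[[pd.DataFrame], np.ndarray]]


def glm_procedure(spec: ModelSpec, **fit_kwargs) -> Procedure:
    """A modelling procedure that refits a fixed-spec GLM on each fold."""

    def fit(train_X: pd.DataFrame, train_y: np.ndarray):
        model = fit_glm(train_X, train_y, spec, **fit_kwargs)
        return lambda test_X: predict(model, test_X)

    return fit


@dataclass
class EvaluationResult:
    predictions: pd.DataFrame  # complex_id, replicate, predicted, observed
    r2: float
    rmsd: float
    se_r2: float
    se_rmsd: float
    n_replicates: int
    seed: int | None
    n_skipped: int = 0


@dataclass
class ComparisonResult:
    statistic_name: str
    statistic: float
    tails: str
    p_value: float
    inputs: dict

    def __post_init__(self) -> None:
        if self.tails not in ("one", "two"):
            raise ValueError("tails must be 'one' or 'two'")


def pearson_r2(pred, obs) -> float:
    """Squared Pearson correlation between predictions and observations."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.size < 3 or pred.size != obs.size:
        raise ValueError("need >= 3 aligned pairs")
    if np.std(pred) == 0 or np.std(obs) == 0:
        raise ValueError("zero variance; correlation undefined")
    r = float(np.corrcoef(pred, obs)[0, 1])
    return r * r


def rmsd_metric(pred, obs) -> float:
    """Root mean squared deviation, in pKd units."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.size == 0 or pred.size != obs.size:
        raise ValueError("need >= 1 aligned pair")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def loo_cv(
    X: pd.DataFrame,
    y,
    procedure: Procedure,
    n_replicates: int = 100,
    seed: int | None = None,
) -> EvaluationResult:
    """Repeated single-complex-holdout cross-validation, pooled scoring.

    Holdouts are drawn without replacement until every complex has been
    used, then the order is reshuffled.  ``r2``/``rmsd`` are computed on
    the pooled held-out predictions; their standard errors use the
    large-sample SE of r (delta method for r^2) and, for RMSD, the SE of
    the mean squared error propagated through the square root.
    Training-fold fit failures skip the replicate (counted).
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    y = np.asarray(y, dtype=float)
    n = len(X)
    if n < 10:
        raise ValueError("need at least 10 complexes")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    pos = 0
    rows = []
    skipped = 0
    ids = list(X.index)
    for rep in range(n_replicates):
        if pos >= len(order):
            order = rng.permutation(n)
            pos = 0
        hold = int(order[pos])
        pos += 1
        mask = np.ones(n, dtype=bool)
        mask[hold] = False
        try:
            predictor = procedure(X.iloc[mask], y[mask])
            pred = float(np.asarray(predictor(X.iloc[[hold]]))[0])
        except (ValueError, np.linalg.LinAlgError):
            skipped += 1
            continue
        rows.append((ids[hold], rep, pred, float(y[hold])))
    preds = pd.DataFrame(rows, columns=["complex_id", "replicate", "predicted", "observed"])
    if len(preds) < 3:
        raise RuntimeError("too few successful replicates to score")
    r2 = pearson_r2(preds["predicted"], preds["observed"])
    rmsd = rmsd_metric(preds["predicted"], preds["observed"])
    m = len(preds)
    r = math.sqrt(r2)
    se_r = math.sqrt(max(1.0 - r2, 0.0) / max(m - 2, 1))
    se_r2 = 2.0 * r * se_r
    sq_err = (preds["predicted"] - preds["observed"]) ** 2
    se_mse = float(sq_err.std(ddof=1) / math.sqrt(m))
    se_rmsd = se_mse / (2.0 * rmsd) if rmsd > 0 else 0.0
    return EvaluationResult(preds, r2, rmsd, se_r2, se_rmsd, n_replicates, seed, skipped)


def fisher_compare(
    r2_a: float, n_a: int, r2_b: float, n_b: int, tails: str = "two"
) -> ComparisonResult:
    """Fisher z-test for two independent correlations, given as r^2.

    z = |atanh(r_a) - atanh(r_b)| / sqrt(1/(n_a-3) + 1/(n_b-3)) with
    r = sqrt(r^2); the p-value comes from the standard-normal tail(s).
    """
    for r2, n in ((r2_a, n_a), (r2_b, n_b)):
        if not 0.0 <= r2 < 1.0:
            raise ValueError(f"r^2 must be in [0, 1), got {r2} (atanh diverges at 1)")
        if n <= 3:
            raise ValueError("need n > 3 per sample")
    z = abs(math.atanh(math.sqrt(r2_a)) - math.atanh(math.sqrt(r2_b))) / math.sqrt(
        1.0 / (n_a - 3) + 1.0 / (n_b - 3)
    )
    p_one = float(stats.norm.sf(z))
    p = min(2.0 * p_one, 1.0) if tails == "two" else p_one
    return ComparisonResult(
        "fisher_z", z, tails, max(p, np.finfo(float).tiny),
        {"r2_a": r2_a, "n_a": n_a, "r2_b": r2_b, "n_b": n_b},
    )


def williams_test(
    r13: float, r23: float, r12: float, n: int, tails: str = "two"
) -> ComparisonResult:
    """Williams' t for two dependent correlations sharing one variable.

    ``r13``/``r23`` correlate each model's predictions (1, 2) with the
    observed affinities (3); ``r12`` correlates the two prediction sets.
    t has n - 3 degrees of freedom.  Signed correlations are expected.
    """
    if n <= 3:
        raise ValueError("need n > 3")
    for r in (r13, r23, r12):
        if not -1.0 < r < 1.0:
            raise ValueError(f"correlation {r} outside (-1, 1)")
    det = 1.0 - r13**2 - r23**2 - r12**2 + 2.0 * r13 * r23 * r12
    if det <= 0:
        raise ValueError("inconsistent correlation triple (non-positive-definite)")
    rbar = 0.5 * (r13 + r23)
    denom = 2.0 * det * (n - 1) / (n - 3) + rbar**2 * (1.0 - r12) ** 3
    t = (r13 - r23) * math.sqrt((n - 1) * (1.0 + r12) / denom)
    df = n - 3
    p_one = float(stats.t.sf(abs(t), df))
    p = min(2.0 * p_one, 1.0) if tails == "two" else p_one
    return ComparisonResult(
        "williams_t", t, tails, max(p, np.finfo(float).tiny),
        {"r13": r13, "r23": r23, "r12": r12, "n": n},
    )


def welch_t(sample_a, sample_b, tails: str = "two") -> ComparisonResult:
    """Two-sample t test with unequal variances (Welch-Satterthwaite df)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per sample")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return ComparisonResult("welch_t", 0.0, tails, 1.0, {"n_a": a.size, "n_b": b.size})
        raise ValueError("both samples degenerate with zero variance")
    t, p_two = stats.ttest_ind(a, b, equal_var=False)
    p = float(p_two) if tails == "two" else float(p_two) / 2.0
    return ComparisonResult(
        "welch_t", float(t), tails, max(p, np.finfo(float).tiny),
        {"n_a": int(a.size), "n_b": int(b.size)},
    )


def mann_whitney_u(sample_a, sample_b, tails: str = "two") -> ComparisonResult:
    """Mann-Whitney U; exact enumeration for small tie-free samples,
    otherwise the tie-corrected normal approximation."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    alternative = "two-sided" if tails == "two" else "greater"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return ComparisonResult(
        "mann_whitney_u", float(res.statistic), tails, float(res.pvalue),
        {"n_a": int(a.size), "n_b": int(b.size), "method": method},
    )


def subsample_control(
    X: pd.DataFrame,
    y,
    subset_size: int,
    evaluation: Callable[[pd.DataFrame, np.ndarray], float],
    n_reps: int = 1000,
    seed: int | None = None,
    observed_r2: float | None = None,
) -> tuple[np.ndarray, float | None]:
    """Null distribution of accuracy under random equal-size subsampling.

    Draws ``n_reps`` uniform subsets of ``subset_size`` complexes, applies
    ``evaluation`` (e.g. a pooled LOO-CV r^2) to each, and returns the
    accuracy distribution plus the add-one empirical p-value
    (1 + #{null >= observed}) / (n_reps + 1) when ``observed_r2`` given.
    """
    y = np.asarray(y, dtype=float)
    n = len(X)
    if not 0 < subset_size < n:
        raise ValueError("subset_size must be in (0, n)")
    rng = np.random.default_rng(seed)
    values = np.empty(n_reps)
    for i in range(n_reps):
        idx = rng.choice(n, size=subset_size, replace=False)
        values[i] = evaluation(X.iloc[idx], y[idx])
    p = None
    if observed_r2 is not None:
        p = (1.0 + np.sum(values >= observed_r2)) / (n_reps + 1.0)
    return values, p


def estimate_assay_offsets(
    X: pd.DataFrame, y, methods, spec: ModelSpec
) -> dict[str, tuple[float, float]]:
    """Additive per-assay-method pKd offsets from base-model residuals.

    Fits the base (method-blind) GLM, then estimates each method's offset
    as its mean residual, centred so offsets sum (weighted) to zero;
    consistent when assay method is assigned independently of structure.
    Returns {method: (offset, standard error)}.
    """
    y = np.asarray(y, dtype=float)
    methods = np.asarray(methods)
    model = fit_glm(X, y, spec)
    resid = y - predict(model, X)
    grand = float(resid.mean())
    out = {}
    for m in np.unique(methods):
        r = resid[methods == m]
        if r.size < 2:
            continue
        out[str(m)] = (float(r.mean() - grand), float(r.std(ddof=1) / math.sqrt(r.size)))
    return out
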