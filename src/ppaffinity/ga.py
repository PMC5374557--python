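"""Genetic-algorithm model selection by AIC.

Candidate models are bit vectors: one bit per main effect and, at level 2,
one bit per unordered feature pair (the interaction).  The population
evolves by tournament selection, single-point crossover and per-bit
mutation, with elitism; with marginality enabled, every variation step is
followed by a repair that switches on the parent main effects of any
active interaction, so the hierarchy constraint always holds.  Every
distinct candidate evaluated is logged with its AIC; the minimum-AIC
candidate wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .glm import FittedModel, ModelSpec, RankDeficientError, fit_glm

__all__ = ["GAConfig", "GAResult", "ga_select", "exhaustive_select", "admissible_specs"]


@dataclass(frozen=True)
class GAConfig:
    """Knobs of the search; defaults follow common GA-selection practice.

    ``n_candidates`` caps the number of distinct candidate models
    evaluated; ``population_size`` is the per-generation population.  The
    two are deliberately independent knobs.
    """

    population_size: int = 500
    n_candidates: int = 500
    level: int = 2
    marginality: bool = True
    crossover_p: float = 0.9
    mutation_p: float = 0.02
    elitism: int = 10
    stale_generations: int = 20
    tournament_size: int = 3
    # when the whole admissible space fits inside the candidate budget,
    # spend the budget on complete enumeration instead of evolution: same
    # cost, exact optimum
    enumerate_small: bool = True


@dataclass
class GAResult:
    best_spec: ModelSpec
    best_model: FittedModel
    ledger: list[tuple[ModelSpec, float]]  # every evaluated candidate with its AIC
    n_generations: int
    discarded: int  # candidates that failed to fit (logged, AIC = +inf)


def _spec_from_bits(
    bits: np.ndarray, features: list[str], pairs: list[tuple[str, str]], marginality: bool
) -> ModelSpec:
    nf = len(features)
    mains = {features[i] for i in range(nf) if bits[i]}
    inters = {pairs[j] for j in range(len(pairs)) if bits[nf + j]}
    if marginality:
        for a, b in inters:
            mains.add(a)
            mains.add(b)
    return ModelSpec(
        frozenset(mains),
        frozenset(frozenset(p) for p in inters),
        marginality=marginality,
    )


def _repair(bits: np.ndarray, nf: int, pairs: list[tuple[int, int]]) -> None:
    """Switch on the parent mains of every active interaction bit (in place)."""
    for j, (a, b) in enumerate(pairs):
        if bits[nf + j]:
            bits[a] = 1
            bits[b] = 1


def ga_select(
    X: pd.DataFrame,
    y,
    config: GAConfig | None = None,
    seed: int | None = None,
) -> GAResult:
    """Search model space for the minimum-AIC log-link Gaussian GLM.

    Deterministic given ``seed``.  Candidates whose fit is infeasible
    (rank deficiency, too few observations) are discarded with AIC = +inf
    and counted in ``discarded``.
    """
    config = config or GAConfig()
    if config.level not in (1, 2):
        raise ValueError("level must be 1 (mains only) or 2 (pairwise interactions)")
    features = list(X.columns)
    if len(features) < 2:
        raise ValueError("need at least 2 features to select over")
    pair_names = list(combinations(features, 2)) if config.level == 2 else []
    pair_idx = [(features.index(a), features.index(b)) for a, b in pair_names]
    nf = len(features)
    nbits = nf + len(pair_names)
    rng = np.random.default_rng(seed)

    cache: dict[bytes, tuple[ModelSpec, FittedModel | None, float]] = {}
    ledger: list[tuple[ModelSpec, float]] = []
    discarded = 0

    if config.enumerate_small and _count_admissible(
        nf, len(pair_names), config.level, config.marginality
    ) <= config.n_candidates:
        best: tuple[ModelSpec, FittedModel] | None = None
        for spec in admissible_specs(features, config.level, config.marginality):
            try:
                model = fit_glm(X, y, spec)
                score = model.aic
            except (RankDeficientError, ValueError):
                model, score = None, np.inf
                discarded += 1
            ledger.append((spec, score))
            if model is not None and (best is None or score < best[1].aic):
                best = (spec, model)
        if best is None:
            raise RuntimeError("no candidate model could be fitted")
        return GAResult(best[0], best[1], ledger, 0, discarded)

    def evaluate(bits: np.ndarray) -> float:
        nonlocal discarded
        if config.marginality:
            _repair(bits, nf, pair_idx)
        key = bits.tobytes()
        if key in cache:
            return cache[key][2]
        spec = _spec_from_bits(bits, features, pair_names, config.marginality)
        try:
            model = fit_glm(X, y, spec)
            score = model.aic
        except (RankDeficientError, ValueError):
            model, score = None, np.inf
            discarded += 1
        cache[key] = (spec, model, score)
        ledger.append((spec, score))
        return score

    pop = (rng.random((config.population_size, nbits)) < 0.5).astype(np.int8)
    pop[0] = 0  # seed the null model so the baseline is always in the ledger
    fitness = np.array([evaluate(pop[i]) for i in range(len(pop))])

    best_score = fitness.min()
    stale = 0
    gen = 0
    while len(cache) < config.n_candidates and stale < config.stale_generations:
        gen += 1
        order = np.argsort(fitness, kind="stable")
        elite = pop[order[: config.elitism]].copy()
        children = []
        while len(children) < config.population_size - len(elite):
            idx = rng.integers(0, len(pop), size=(2, config.tournament_size))
            p1 = pop[idx[0][np.argmin(fitness[idx[0]])]].copy()
            p2 = pop[idx[1][np.argmin(fitness[idx[1]])]].copy()
            if nbits > 1 and rng.random() < config.crossover_p:
                cut = int(rng.integers(1, nbits))
                p1[cut:], p2[cut:] = p2[cut:].copy(), p1[cut:].copy()
            for child in (p1, p2):
                flip = rng.random(nbits) < config.mutation_p
                child[flip] ^= 1
                children.append(child)
        pop = np.vstack([elite] + children)[: config.population_size]
        fitness = np.array([evaluate(pop[i]) for i in range(len(pop))])
        if fitness.min() < best_score - 1e-12:
            best_score = fitness.min()
            stale = 0
        else:
            stale += 1

    finite = [(spec, model, score) for spec, model, score in cache.values() if model is not None]
    if not finite:
        raise RuntimeError("no candidate model could be fitted")
    best_spec, best_model, _ = min(finite, key=lambda t: t[2])
    return GAResult(best_spec, best_model, ledger, gen, discarded)


def _count_admissible(nf: int, n_pairs: int, level: int, marginality: bool) -> int:
    from math import comb

    if level == 1:
        return 2**nf
    if not marginality:
        return 2 ** (nf + n_pairs)
    return sum(comb(nf, k) * 2 ** comb(k, 2) for k in range(nf + 1))


def admissible_specs(
    features: list[str], level: int = 2, marginality: bool = True
) -> list[ModelSpec]:
    """Every admissible ModelSpec (small feature sets only: 2^(f + C(f,2)))."""
    specs = []
    all_pairs = list(combinations(sorted(features), 2)) if level == 2 else []
    for mask in range(2 ** len(features)):
        mains = frozenset(f for i, f in enumerate(sorted(features)) if mask >> i & 1)
        if level == 1:
            specs.append(ModelSpec(mains, frozenset(), marginality=marginality))
            continue
        pairs = [p for p in all_pairs if not marginality or set(p) <= mains]
        for pmask in range(2 ** len(pairs)):
            inters = frozenset(
                frozenset(p) for j, p in enumerate(pairs) if pmask >> j & 1
            )
            specs.append(ModelSpec(mains, inters, marginality=marginality))
    return specs


def exhaustive_select(
    X: pd.DataFrame, y, level: int = 2, marginality: bool = True
) -> tuple[ModelSpec, FittedModel]:
    """Brute-force AIC optimum over all admissible specs (oracle for tests)."""
    best: tuple[ModelSpec, FittedModel] | None = None
    for spec in admissible_specs(list(X.columns), level, marginality):
        try:
            model = fit_glm(X, y, spec)
        except (RankDeficientError, ValueError):
            continue
        if best is None or model.aic < best[1].aic:
            best = (spec, model)
    assert best is not None
    return best
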