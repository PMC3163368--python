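"""Feature selection: per-m/z t-statistic ranking and k-subset search.

Every m/z grid point is treated as an independent feature.  The two-sample
statistic is

    t = (Xbar_d - Xbar_c) / sqrt(Var_d/n_d + Var_c/n_c)

with unbiased group variances and *pooled* degrees of freedom
df = n_d + n_c - 2.  Note this pairs the unpooled-variance denominator with
the pooled df rather than the Welch-Satterthwaite df; the combination is
deliberate and documented in the methods note.  Two-sided p-values come from the Student
t distribution at that df.

The discriminatory-subset search looks for k m/z indices (k = 5 by
default) whose joint amplitude pattern separates cancers from controls.
A candidate subset is *rated* by its leave-one-out nearest-centroid
accuracy in the k-dimensional amplitude space; the search keeps an elite
of the highest-rated subsets and reshuffles their indices (recombination
plus random mutation) into new candidates until a subset fully
discriminates the cohort (rating 1.0) or the iteration budget is spent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, DataError, InsufficientDataError
from .spectra import CANCER, CONTROL, GroupStats, SpectraSet, group_stats

# ---------------------------------------------------------------------------
# t statistic and ranking
# ---------------------------------------------------------------------------


def _t_arrays(stats: GroupStats) -> tuple[np.ndarray, int, np.ndarray]:
    """Vectorized (t, df, p) over all features, with zero-variance rules.

    Features where both group variances vanish get t = 0, p = 1 when the
    means agree, and an infinite-separation sentinel t = +/-inf, p = 0 when
    they differ; the sentinel outranks every finite |t|.
    """
    if stats.n_cancer < 2 or stats.n_control < 2:
        raise InsufficientDataError("t statistic needs >= 2 samples per class")
    diff = np.asarray(stats.mean_cancer - stats.mean_control, dtype=float)
    se2 = np.asarray(
        stats.var_cancer / stats.n_cancer + stats.var_control / stats.n_control,
        dtype=float,
    )
    df = stats.n_cancer + stats.n_control - 2
    zero_se = se2 == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        t = np.where(zero_se & (diff == 0.0), 0.0, t)
        t = np.where(zero_se & (diff != 0.0), np.sign(diff) * np.inf, t)
    p = np.empty_like(t)
    finite = np.isfinite(t)
    p[finite] = 2.0 * sps.t.sf(np.abs(t[finite]), df)
    p[~finite] = 0.0
    return t, df, p


def t_statistic(stats: GroupStats, feature_index: int) -> tuple[float, int, float]:
    """(t, df, p) for one feature from precomputed group statistics."""
    t, df, p = _t_arrays(stats)
    t = np.atleast_1d(t)
    p = np.atleast_1d(p)
    return float(t[feature_index]), df, float(p[feature_index])


@dataclass(frozen=True)
class FeatureRanking:
    """All-features t statistics plus the |t|-descending rank permutation."""

    mz: np.ndarray
    t: np.ndarray
    df: int
    p: np.ndarray
    order: np.ndarray  # feature indices, |t| descending, ties to lower index

    def top(self, k: int) -> np.ndarray:
        """Indices of the k highest-|t| features."""
        return self.order[:k]

    def to_frame(self) -> pd.DataFrame:
        """Rank-ordered table with columns ``index,mz,t,p,rank``."""
        return pd.DataFrame(
            {
                "index": self.order,
                "mz": self.mz[self.order],
                "t": self.t[self.order],
                "p": self.p[self.order],
                "rank": np.arange(1, len(self.order) + 1),
            }
        )


def rank_features(sset: SpectraSet) -> FeatureRanking:
    """Rank every m/z point by the absolute value of its t statistic.

    Ties (and the +/-inf sentinels among themselves) break toward the lower
    m/z, i.e. the lower feature index, so the permutation is deterministic.
    """
    stats = group_stats(sset)
    t, df, p = _t_arrays(stats)
    abs_t = np.abs(t)
    # lexsort: primary key -|t| ascending == |t| descending; secondary index.
    order = np.lexsort((np.arange(abs_t.size), -abs_t))
    return FeatureRanking(mz=sset.grid.values.copy(), t=t, df=df, p=p, order=order)


# ---------------------------------------------------------------------------
# Subset rating
# ---------------------------------------------------------------------------


def _loo_nearest_centroid_accuracy(x: np.ndarray, is_cancer: np.ndarray) -> float:
    """Leave-one-out nearest-centroid accuracy, fully vectorized.

    A held-out sample counts as correct iff it is strictly closer to its
    own class centroid (recomputed without it) than to the other class's
    centroid.  A sample whose class would be emptied by holding it out
    cannot be correct.
    """
    n = x.shape[0]
    sums = {True: x[is_cancer].sum(axis=0), False: x[~is_cancer].sum(axis=0)}
    counts = {True: int(is_cancer.sum()), False: int(n - is_cancer.sum())}
    correct = 0
    for own in (True, False):
        mask = is_cancer == own
        if counts[own] == 0:
            continue
        xo = x[mask]
        if counts[own] == 1:
            continue  # own centroid undefined when held out
        own_centroid = (sums[own] - xo) / (counts[own] - 1)
        other_centroid = sums[not own] / counts[not own] if counts[not own] else None
        if other_centroid is None:
            correct += counts[own]
            continue
        d_own = np.sum((xo - own_centroid) ** 2, axis=1)
        d_other = np.sum((xo - other_centroid) ** 2, axis=1)
        correct += int(np.sum(d_own < d_other))
    return correct / n


def rate_subset(sset: SpectraSet, indices: Sequence[int]) -> float:
    """Rating in [0, 1] of a feature subset's class-separating power.

    The rating is the leave-one-out nearest-centroid classification
    accuracy in the amplitude space restricted to ``indices``; 1.0 means
    every held-out sample lies strictly closer to its own class centroid
    — the subset fully discriminates the cohort.
    """
    idx = np.unique(np.asarray(list(indices), dtype=int))
    if idx.size == 0:
        raise DataError("empty feature subset")
    if idx.min() < 0 or idx.max() >= sset.n_features:
        raise DataError(f"feature index out of bounds (grid has {sset.n_features} points)")
    counts = sset.class_counts()
    if counts[CANCER] < 1 or counts[CONTROL] < 1:
        raise InsufficientDataError("subset rating needs >= 1 sample per class")
    x = sset.intensity_matrix()[:, idx]
    return _loo_nearest_centroid_accuracy(x, sset.label_array() == CANCER)


RATING_FUNCTIONS: dict[str, Callable[[SpectraSet, Sequence[int]], float]] = {
    "loo-nearest-centroid": rate_subset,
}


# ---------------------------------------------------------------------------
# Iterative subset search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureSubset:
    """A k-subset of feature indices with its discrimination rating."""

    indices: tuple[int, ...]
    rating: float


@dataclass(frozen=True)
class SearchConfig:
    k: int = 5
    population_size: int = 50
    n_elite: int = 10
    mutation_rate: float = 0.1
    max_iterations: int = 100
    seed: int = 0
    rating: str = "loo-nearest-centroid"

    def __post_init__(self):
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if not (1 <= self.n_elite <= self.population_size):
            raise ConfigError("need 1 <= n_elite <= population_size")
        if self.max_iterations < 1:
            raise ConfigError("max_iterations must be >= 1")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ConfigError("mutation_rate must be in [0, 1]")
        if self.rating not in RATING_FUNCTIONS:
            raise ConfigError(f"unknown rating function {self.rating!r}")


def _random_subset(rng: np.random.Generator, n_features: int, k: int) -> tuple[int, ...]:
    return tuple(sorted(rng.choice(n_features, size=k, replace=False).tolist()))


def _make_child(
    rng: np.random.Generator,
    elite_pool: np.ndarray,
    n_features: int,
    k: int,
    mutation_rate: float,
) -> tuple[int, ...]:
    """Recombine indices from the elite pool, then mutate.

    The child draws k distinct indices from the union of elite indices
    (padded with random features if the pool is too small); each position
    is then replaced, with probability ``mutation_rate``, by a uniformly
    random feature, keeping the k indices distinct.
    """
    if elite_pool.size >= k:
        child = set(rng.choice(elite_pool, size=k, replace=False).tolist())
    else:
        child = set(elite_pool.tolist())
        while len(child) < k:
            child.add(int(rng.integers(n_features)))
    mutated = set()
    for idx in sorted(child):
        if rng.random() < mutation_rate:
            new = int(rng.integers(n_features))
            while new in mutated or new in child:
                new = int(rng.integers(n_features))
            child.discard(idx)
            mutated.add(new)
        else:
            mutated.add(idx)
    return tuple(sorted(mutated))


def search_subsets(
    sset: SpectraSet, config: SearchConfig
) -> tuple[FeatureSubset, list[float]]:
    """Iterative elitist search for a fully discriminating k-subset.

    Starts from ``population_size`` random k-subsets, keeps the ``n_elite``
    best each iteration, and breeds replacements by recombining elite
    indices with mutation.  Stops as soon as some subset reaches rating 1.0
    (full discrimination of the cohort) or after ``max_iterations``.
    Returns the best subset ever seen and the per-iteration best-so-far
    rating log, which is non-decreasing by construction.
    """
    n_features = sset.n_features
    if config.k > n_features:
        raise ConfigError(f"k={config.k} exceeds feature count {n_features}")
    rate = RATING_FUNCTIONS[config.rating]
    rng = np.random.default_rng(config.seed)
    cache: dict[tuple[int, ...], float] = {}

    def rated(subset: tuple[int, ...]) -> float:
        if subset not in cache:
            cache[subset] = rate(sset, subset)
        return cache[subset]

    population = [_random_subset(rng, n_features, config.k) for _ in range(config.population_size)]
    best = max(
        (FeatureSubset(s, rated(s)) for s in population),
        key=lambda fs: (fs.rating, tuple(-i for i in fs.indices)),
    )
    log = [best.rating]
    for _ in range(config.max_iterations):
        if best.rating >= 1.0:
            break
        ranked = sorted(population, key=lambda s: (-rated(s), s))
        elite = ranked[: config.n_elite]
        elite_pool = np.unique(np.concatenate([np.array(s) for s in elite]))
        children = [
            _make_child(rng, elite_pool, n_features, config.k, config.mutation_rate)
            for _ in range(config.population_size - config.n_elite)
        ]
        population = elite + children
        for subset in children:
            candidate = FeatureSubset(subset, rated(subset))
            if candidate.rating > best.rating:
                best = candidate
        log.append(best.rating)
    return best, log
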