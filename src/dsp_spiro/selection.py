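"""All-relevant feature selection by the Boruta shadow-feature procedure.

Each iteration duplicates every predictor as a row-permuted "shadow" copy,
fits a random forest on the augmented design, and scores a *hit* for every
real feature whose importance strictly exceeds the best shadow importance.
Hits accumulate across iterations; after each iteration a two-sided binomial
test against Binomial(iterations, 1/2), Bonferroni-corrected over the
currently undecided features, confirms features with significantly many
hits and rejects (and removes) those with significantly few. Features still
undecided when the iteration budget runs out are *tentative*.

Targets here are continuous spirometric indices, so the forests are
regression forests; importances are the forest's impurity-decrease scores,
as in the reference implementations of the algorithm.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.ensemble import RandomForestRegressor

from .errors import DataError, ParameterError
from .features import ACOUSTIC_GROUP, IMU_GROUP, INDEX_TO_TARGET

logger = logging.getLogger(__name__)

SHADOW_PREFIX = "shadow__"


@dataclass(frozen=True)
class BorutaConfig:
    n_iterations: int = 100
    n_trees: int = 500
    alpha: float = 0.05
    correction: str = "bonferroni"
    seed: int = 0
    tentative_policy: str = "reject"  # {"reject", "keep"}
    max_features: str | float = "sqrt"

    def __post_init__(self) -> None:
        if self.n_iterations < 10:
            raise ParameterError("n_iterations must be >= 10")
        if not (0 < self.alpha < 1):
            raise ParameterError("alpha must lie in (0, 1)")
        if self.correction != "bonferroni":
            raise ParameterError(f"unknown correction {self.correction!r}")
        if self.tentative_policy not in ("reject", "keep"):
            raise ParameterError(f"unknown tentative_policy {self.tentative_policy!r}")


@dataclass(frozen=True)
class BorutaResult:
    confirmed: frozenset[str]
    rejected: frozenset[str]
    tentative: frozenset[str]
    hit_counts: Mapping[str, int]
    n_iterations_run: int

    def selected(self, tentative_policy: str = "reject") -> frozenset[str]:
        if tentative_policy == "keep":
            return self.confirmed | self.tentative
        return self.confirmed


def make_shadow_features(X: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Append an independently row-permuted copy of every column."""
    if len(X) < 2:
        raise DataError("need at least 2 rows to build shadow features")
    rng = np.random.default_rng(seed)
    shadows = {f"{SHADOW_PREFIX}{c}": rng.permutation(X[c].to_numpy())
               for c in X.columns}
    return pd.concat([X.reset_index(drop=True),
                      pd.DataFrame(shadows)], axis=1)


def importance(X_augmented: pd.DataFrame, y: np.ndarray, n_trees: int,
               seed: int, max_features: str | float = "sqrt") -> dict[str, float]:
    """Impurity-decrease importances from a seeded regression forest."""
    forest = RandomForestRegressor(n_estimators=n_trees, random_state=seed,
                                   max_features=max_features, n_jobs=1)
    forest.fit(X_augmented.to_numpy(), np.asarray(y, dtype=float))
    return dict(zip(X_augmented.columns, forest.feature_importances_))


def run_boruta(X: pd.DataFrame, y: Sequence[float],
               config: BorutaConfig | None = None) -> BorutaResult:
    """Run the shadow-feature procedure until every feature is decided or the
    iteration budget is exhausted."""
    config = config or BorutaConfig()
    if len(X) < 10:
        raise DataError("need at least 10 rows")
    y = np.asarray(y, dtype=float)
    all_features = list(X.columns)
    undecided = set(all_features)
    confirmed: set[str] = set()
    rejected: set[str] = set()
    hits = {f: 0 for f in all_features}
    rng = np.random.default_rng(config.seed)
    it = 0
    for it in range(1, config.n_iterations + 1):
        if not undecided:
            it -= 1
            break
        active = [f for f in all_features if f not in rejected]
        # rejected features leave the competition, but the shadow null field
        # keeps its full original width: shrinking it with the rejections
        # weakens the max-shadow benchmark and lets chance correlations
        # accumulate hits late in the run
        shadow_rng = np.random.default_rng(int(rng.integers(2 ** 31)))
        shadows = {f"{SHADOW_PREFIX}{c}": shadow_rng.permutation(X[c].to_numpy())
                   for c in all_features}
        aug = pd.concat([X[active].reset_index(drop=True),
                         pd.DataFrame(shadows)], axis=1)
        imp = importance(aug, y, config.n_trees,
                         seed=int(rng.integers(2 ** 31)), max_features=config.max_features)
        shadow_max = max(v for k, v in imp.items() if k.startswith(SHADOW_PREFIX))
        for f in active:
            if f in undecided and imp[f] > shadow_max:
                hits[f] += 1
        # two-sided binomial test vs. Binomial(it, 0.5); Bonferroni over all
        # input features, as in the reference algorithm — correcting only
        # over the shrinking undecided set lets chance correlations through
        # late in the run
        n_tests = len(all_features)
        for f in list(undecided):
            k = hits[f]
            p_hi = binom.sf(k - 1, it, 0.5)   # P[K >= k]
            p_lo = binom.cdf(k, it, 0.5)      # P[K <= k]
            p_two = min(1.0, 2.0 * min(p_hi, p_lo))
            if p_two * n_tests <= config.alpha:
                undecided.discard(f)
                if k > it / 2:
                    confirmed.add(f)
                else:
                    rejected.add(f)
    tentative = set(undecided)
    if tentative:
        logger.info("%d features remain tentative after %d iterations "
                    "(policy: %s)", len(tentative), it, config.tentative_policy)
    return BorutaResult(confirmed=frozenset(confirmed),
                        rejected=frozenset(rejected),
                        tentative=frozenset(tentative),
                        hit_counts=dict(hits), n_iterations_run=it)


def select_per_group(table: pd.DataFrame, config: BorutaConfig | None = None
                     ) -> dict[tuple[str, str], frozenset[str]]:
    """Run Boruta separately per modality (tracheal-sound vs IMU-derived) and
    per spirometric index on the full table, as a pre-CV screen.

    Returns the confirmed names (after tentative policy) keyed by
    (modality, index). Applying the screen once on all rows, before
    cross-validation, mirrors the study protocol and shares its acknowledged
    optimistic bias.
    """
    config = config or BorutaConfig()
    groups = {"acoustic": [c for c in ACOUSTIC_GROUP if c in table.columns],
              "imu": [c for c in IMU_GROUP if c in table.columns]}
    out: dict[tuple[str, str], frozenset[str]] = {}
    for g_name, cols in groups.items():
        for index, target in INDEX_TO_TARGET.items():
            res = run_boruta(table[cols], table[target].to_numpy(), config)
            out[(g_name, index)] = res.selected(config.tentative_policy)
    return out
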