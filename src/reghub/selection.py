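"""All-relevant feature selection with a repeated-run stability filter.

The selector is the shadow-feature algorithm: every remaining real feature is
duplicated as a value-permuted "shadow" copy, a randomized tree ensemble is
fit on the combined matrix, and a real feature scores a *hit* in an iteration
when its importance exceeds the maximum shadow importance.  Hit counts follow
Binomial(iterations, 1/2) for an irrelevant feature, so after each iteration
every undecided feature gets a two-sided binomial test (Bonferroni-corrected
across the currently undecided features); significantly many hits confirms
the feature, significantly few rejects it.  Iteration stops when every
feature is decided or ``max_iterations`` is reached (survivors stay
*tentative*).

Because a single run is stochastic, the selector is executed ``n_runs`` times
(default 50) with consecutive seeds, and only features confirmed in at least
``retention_fraction`` of the runs (default 95%, i.e. 48 of 50 — exact
integer arithmetic via ceil) are retained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import stats

from ._trees import extra_trees_importances
from .expression import HubDesign

logger = logging.getLogger(__name__)

UNDECIDED, CONFIRMED, REJECTED = 0, 1, -1


@dataclass(frozen=True)
class SelectionParams:
    """Knobs of the selection procedure.

    ``n_runs`` and ``retention_fraction`` are the stability filter (50 runs,
    features kept when confirmed in >= 95% of them).  ``alpha`` is the level
    of the per-iteration binomial tests, Bonferroni-corrected across the
    undecided features of that run.  ``count_tentative`` widens "significant"
    to include features still undecided at ``max_iterations``; the default
    counts Confirmed status only.
    """

    n_runs: int = 50
    retention_fraction: float = 0.95
    max_iterations: int = 100
    alpha: float = 0.05
    n_trees: int = 100
    base_seed: int = 0
    min_shadows: int = 5
    count_tentative: bool = False
    estimator: Literal["extratrees", "permutation", "sklearn"] = "extratrees"

    def __post_init__(self) -> None:
        if not (0 < self.retention_fraction <= 1):
            raise ValueError("retention_fraction must be in (0, 1]")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    @property
    def min_confirmed_runs(self) -> int:
        """Runs needed to retain: ceil(retention_fraction * n_runs)."""
        return math.ceil(self.retention_fraction * self.n_runs - 1e-9)


@dataclass(frozen=True)
class FeatureSelectionResult:
    """Outcome of the stability filter for one target gene."""

    target_gene_id: str
    retention_fraction_per_feature: dict
    retained_features: tuple[str, ...]
    feature_intervals: dict = field(default_factory=dict)


def _importances(X: np.ndarray, y: np.ndarray, n_trees: int, seed: int, estimator: str) -> np.ndarray:
    if estimator == "sklearn":
        from sklearn.ensemble import ExtraTreesRegressor

        model = ExtraTreesRegressor(
            n_estimators=n_trees, max_features=max(1, X.shape[1] // 3),
            random_state=seed,
        )
        model.fit(X, y)
        return model.feature_importances_
    if estimator == "permutation":
        from ._trees import permutation_importances

        return permutation_importances(X, y, n_trees=n_trees, seed=seed)
    return extra_trees_importances(X, y, n_trees=n_trees, seed=seed)


def boruta_select(
    design: HubDesign,
    seed: int,
    params: SelectionParams = SelectionParams(),
) -> set[str]:
    """One run of the shadow-feature algorithm; returns the Confirmed set.

    Deterministic given ``(design, seed, params)``.  Zero-variance features
    are rejected up front; a constant response is an error.
    """
    confirmed, _ = _boruta_run(
        np.asarray(design.feature_matrix, float),
        np.asarray(design.response, float),
        seed,
        params,
    )
    ids = np.asarray(design.feature_ids, dtype=object)
    return set(ids[confirmed])


def _boruta_run(
    X: np.ndarray, y: np.ndarray, seed: int, params: SelectionParams
) -> tuple[np.ndarray, np.ndarray]:
    """Return (confirmed mask, status vector) over the columns of X."""
    n, p = X.shape
    if n < 2:
        raise ValueError("need >= 2 samples")
    if p < 1:
        raise ValueError("need >= 1 candidate feature")
    if np.ptp(y) == 0:
        raise ValueError("response is constant; nothing to select against")

    rng = np.random.default_rng(seed)
    status = np.full(p, UNDECIDED, dtype=int)
    dead = np.ptp(X, axis=0) == 0
    if dead.any():
        logger.info("auto-rejecting %d zero-variance features", int(dead.sum()))
        status[dead] = REJECTED

    hits = np.zeros(p, dtype=int)
    n_iters = 0
    for _ in range(params.max_iterations):
        undecided = np.flatnonzero(status == UNDECIDED)
        if undecided.size == 0:
            break
        live = np.flatnonzero(status != REJECTED)  # confirmed + undecided
        Xl = X[:, live]
        # canonical shadow scheme: permuted copies of the surviving features,
        # padded to at least min_shadows columns when few survive
        shadows = Xl.copy()
        for c in range(shadows.shape[1]):
            shadows[:, c] = shadows[rng.permutation(n), c]
        if shadows.shape[1] < params.min_shadows:
            reps = math.ceil(params.min_shadows / shadows.shape[1])
            shadows = np.tile(shadows, (1, reps))[:, : params.min_shadows]
        Z = np.hstack([Xl, shadows])
        imp = _importances(
            Z, y, params.n_trees, int(rng.integers(2**31 - 1)), params.estimator
        )
        shadow_max = imp[Xl.shape[1] :].max()
        live_hit = imp[: Xl.shape[1]] > shadow_max
        pos = {f: k for k, f in enumerate(live)}
        for f in undecided:
            if live_hit[pos[f]]:
                hits[f] += 1
        n_iters += 1

        # two-sided binomial test at p = 1/2, Bonferroni over undecided
        m = undecided.size
        h = hits[undecided]
        tail = np.minimum(
            stats.binom.cdf(h, n_iters, 0.5), stats.binom.sf(h - 1, n_iters, 0.5)
        )
        pvals = np.minimum(1.0, 2 * tail) * m
        decided = pvals <= params.alpha
        status[undecided[decided & (h * 2 > n_iters)]] = CONFIRMED
        status[undecided[decided & (h * 2 < n_iters)]] = REJECTED

    return status == CONFIRMED, status


def stability_run(
    design: HubDesign, params: SelectionParams = SelectionParams()
) -> FeatureSelectionResult:
    """Run the selector ``n_runs`` times and apply the retention filter.

    Run ``r`` uses seed ``base_seed + r``; a feature is retained iff it was
    significant (Confirmed, or also Tentative under ``count_tentative``) in at
    least ``ceil(retention_fraction * n_runs)`` runs.
    """
    X = np.asarray(design.feature_matrix, float)
    y = np.asarray(design.response, float)
    counts = np.zeros(X.shape[1], dtype=int)
    for r in range(params.n_runs):
        run_seed = params.base_seed + r
        confirmed, status = _boruta_run(X, y, run_seed, params)
        significant = confirmed | (
            (status == UNDECIDED) if params.count_tentative else False
        )
        counts += significant
        logger.debug(
            "stability run %d (seed %d): %d significant", r, run_seed, significant.sum()
        )

    fractions = {
        fid: counts[k] / params.n_runs for k, fid in enumerate(design.feature_ids)
    }
    retained = tuple(
        fid
        for k, fid in enumerate(design.feature_ids)
        if counts[k] >= params.min_confirmed_runs
    )
    logger.info(
        "stability_run[%s]: retained %d of %d features (>= %d/%d runs)",
        design.target_gene_id, len(retained), len(design.feature_ids),
        params.min_confirmed_runs, params.n_runs,
    )
    return FeatureSelectionResult(
        target_gene_id=design.target_gene_id,
        retention_fraction_per_feature=fractions,
        retained_features=retained,
        feature_intervals=dict(design.feature_intervals),
    )
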