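"""Training-fold-only covariate selection.

Two procedures are provided. The correlation threshold-ladder scans the
descending thresholds 0.7, 0.6, 0.5, 0.4, 0.3 and keeps, at the first
threshold reached by at least one feature, every feature whose absolute
Pearson correlation with the training response meets it; if none reaches
0.3 the selection is empty and the model trains without covariates. The
Boruta procedure repeatedly fits a random forest on the real features
plus permuted "shadow" copies, scores a hit whenever a real feature's
importance exceeds the best shadow, and labels features Confirmed /
Tentative / Rejected with an exact binomial test on the hit count.

Both selectors receive training-fold rows only: the interface never sees
held-out responses, which is what makes the downstream evaluation
leakage-safe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

CONFIRMED = "Confirmed"
TENTATIVE = "Tentative"
REJECTED = "Rejected"

DEFAULT_LADDER = (0.7, 0.6, 0.5, 0.4, 0.3)
DEFAULT_ALPHA = 0.01
DEFAULT_MAX_RUNS = 100
# max_features=1/3 mirrors the mtry = p/3 regression default of the random
# forests the original shadow-feature procedure is built on; considering all
# features at every split would make the forest greedy and starve correlated
# relevant features of importance.
DEFAULT_RF_PARAMS = {"n_estimators": 300, "max_features": 1 / 3, "n_jobs": 1}
MIN_SHADOWS = 5


class SelectionError(ValueError):
    pass


@dataclass
class SelectionOutcome:
    """Result of one selector run on one training fold."""

    method: str  # "correlation" | "boruta"
    selected: np.ndarray  # column indices, sorted
    threshold_used: float | None = None
    per_feature: dict = field(default_factory=dict)
    joint_space: bool = False  # True when markers and covariates were pooled

    def __post_init__(self) -> None:
        self.selected = np.sort(np.asarray(self.selected, dtype=int))

    @property
    def n_selected(self) -> int:
        return self.selected.size

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "selected": self.selected.tolist(),
            "threshold_used": self.threshold_used,
            "joint_space": self.joint_space,
            "per_feature": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.per_feature.items()
            },
        }


def pearson_columns(features: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column with y; constant columns get 0."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise SelectionError(f"features have {X.shape[0]} rows but y has {y.size}")
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    if sy == 0:
        raise SelectionError("training response has zero variance")
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r[~np.isfinite(r)] = 0.0
    return r


def correlation_ladder_select(
    features: np.ndarray,
    y_train: np.ndarray,
    ladder: Sequence[float] = DEFAULT_LADDER,
) -> SelectionOutcome:
    """Walk the threshold ladder from the largest value down.

    Returns the features passing the first threshold any feature
    reaches; an empty selection (``threshold_used = None``) when none
    reaches the smallest rung.
    """
    r = pearson_columns(features, y_train)
    abs_r = np.abs(r)
    selected: np.ndarray = np.array([], dtype=int)
    threshold_used: float | None = None
    for tc in sorted(ladder, reverse=True):
        hits = np.flatnonzero(abs_r >= tc)
        if hits.size:
            selected, threshold_used = hits, float(tc)
            break
    return SelectionOutcome(
        method="correlation",
        selected=selected,
        threshold_used=threshold_used,
        per_feature={"correlation": r},
    )


def boruta_hit_test(hits: int, runs: int, alpha: float = DEFAULT_ALPHA) -> str:
    """Label a feature from its shadow-beating hit count.

    Confirmed when the exact binomial upper tail P(X >= hits | runs, 1/2)
    is below alpha, Rejected when the lower tail P(X <= hits) is below
    alpha, Tentative otherwise.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if runs < 1 or not 0 <= hits <= runs:
        raise ValueError(f"need 0 <= hits <= runs with runs >= 1, got hits={hits}, runs={runs}")
    upper = stats.binom.sf(hits - 1, runs, 0.5)  # P(X >= hits)
    lower = stats.binom.cdf(hits, runs, 0.5)  # P(X <= hits)
    if upper < alpha:
        return CONFIRMED
    if lower < alpha:
        return REJECTED
    return TENTATIVE


def boruta_select(
    features: np.ndarray,
    y_train: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    max_runs: int = DEFAULT_MAX_RUNS,
    include_tentative: bool = False,
    rf_params: dict | None = None,
    seed: int | np.random.Generator = 0,
    joint_space: bool = False,
    mc_adjust: bool = True,
) -> SelectionOutcome:
    """Shadow-feature selection with a random-forest importance race.

    Rejected features are removed from subsequent forests; Confirmed
    features stay in (they shape the importances of the undecided ones).
    Stops when every feature is decided or after ``max_runs`` forests;
    survivors are Tentative.

    With ``mc_adjust`` (the default, mirroring the reference
    implementation) confirmation is tested at the Bonferroni-adjusted
    level ``alpha / q``; rejection stays at ``alpha`` because dropping a
    feature is the conservative outcome for downstream prediction.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(y_train, dtype=float)
    n, q = X.shape
    if n != y.size:
        raise SelectionError(f"features have {n} rows but y has {y.size}")
    if n < 10:
        raise SelectionError(f"Boruta needs at least 10 training rows, got {n}")
    if y.std() == 0:
        raise SelectionError("training response has zero variance")
    if max_runs < 10:
        raise ValueError(f"max_runs must be >= 10, got {max_runs}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    params = dict(DEFAULT_RF_PARAMS)
    params.update(rf_params or {})

    alpha_confirm = alpha / q if mc_adjust else alpha

    status = np.full(q, TENTATIVE, dtype=object)
    hits = np.zeros(q, dtype=int)
    runs_done = np.zeros(q, dtype=int)
    for run in range(1, max_runs + 1):
        active = np.flatnonzero(status != REJECTED)
        undecided = np.flatnonzero(status == TENTATIVE)
        if undecided.size == 0:
            break
        Xa = X[:, active]
        shadows = rng.permuted(Xa, axis=0)
        if shadows.shape[1] < MIN_SHADOWS:
            extra = rng.integers(0, Xa.shape[1], size=MIN_SHADOWS - shadows.shape[1])
            shadows = np.hstack([shadows, rng.permuted(Xa[:, extra], axis=0)])
        forest = RandomForestRegressor(
            random_state=int(rng.integers(2**31 - 1)), **params
        )
        forest.fit(np.hstack([Xa, shadows]), y)
        imp = forest.feature_importances_
        real_imp = imp[: active.size]
        shadow_max = imp[active.size :].max()
        scored = active[real_imp > shadow_max]
        gained = np.intersect1d(scored, undecided, assume_unique=False)
        hits[gained] += 1
        runs_done[undecided] = run
        for k in undecided:
            if boruta_hit_test(int(hits[k]), run, alpha_confirm) == CONFIRMED:
                status[k] = CONFIRMED
            elif boruta_hit_test(int(hits[k]), run, alpha) == REJECTED:
                status[k] = REJECTED

    selected_mask = status == CONFIRMED
    if include_tentative:
        selected_mask |= status == TENTATIVE
    return SelectionOutcome(
        method="boruta",
        selected=np.flatnonzero(selected_mask),
        per_feature={
            "status": status.tolist(),
            "hits": hits,
            "runs": runs_done,
        },
        joint_space=joint_space,
    )
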